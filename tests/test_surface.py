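import numpy as np
import pytest

from ubrec.errors import UbrecError
from ubrec.structure import Atom, RadiusSet, Structure, merge
from ubrec.surface import (GXG_REFERENCE, burial_by_neighbours, exposure,
                           interface_area, sasa, sphere_points)

from conftest import make_chain, two_chain_structure

R_EXP = 1.7 + 1.4  # carbon + probe


def carbon(xyz, serial=1, chain="A", resseq=1):
    return Atom(serial, "CA", "C", "GLY", resseq, chain, tuple(map(float, xyz)))


class TestSasa:
    def test_isolated_sphere_analytic(self):
        s = Structure([carbon((0, 0, 0))])
        res = sasa(s)
        exact = 4 * np.pi * R_EXP ** 2
        assert res.total == pytest.approx(exact, rel=0.01)

    def test_two_distant_atoms_additive(self):
        s = Structure([carbon((0, 0, 0)), carbon((100, 0, 0), 2, resseq=2)])
        single = 4 * np.pi * R_EXP ** 2
        assert sasa(s).total == pytest.approx(2 * single, rel=0.01)

    @pytest.mark.parametrize("d", [2.0, 3.0, 4.0, 5.0])
    def test_two_sphere_overlap_matches_cap_formula(self, d):
        # closed-form buried cap: on sphere 1, the cap inside sphere 2 has
        # area 2*pi*R1^2*(1 - cos(theta)), cos(theta) = (d^2+R1^2-R2^2)/(2dR1)
        s = Structure([carbon((0, 0, 0)), carbon((d, 0, 0), 2, resseq=2)])
        res = sasa(s)
        cos_t = (d * d) / (2 * d * R_EXP)  # equal radii
        expected_each = 4 * np.pi * R_EXP ** 2 - 2 * np.pi * R_EXP ** 2 * (1 - cos_t)
        np.testing.assert_allclose(res.atom_areas, expected_each, rtol=0.02)

    def test_per_atom_bounded(self, rng):
        coords = rng.uniform(0, 12, size=(30, 3))
        s = Structure(make_chain(coords))
        res = sasa(s)
        assert (res.atom_areas >= 0).all()
        assert (res.atom_areas <= 4 * np.pi * R_EXP ** 2 + 1e-9).all()
        assert res.total == pytest.approx(res.atom_areas.sum())

    def test_monotonicity_adding_atoms_never_increases_area(self, rng):
        coords = rng.uniform(0, 10, size=(15, 3))
        s1 = Structure(make_chain(coords))
        extra = rng.uniform(0, 10, size=(5, 3))
        s2 = Structure(make_chain(np.vstack([coords, extra])))
        a1 = sasa(s1).atom_areas
        a2 = sasa(s2).atom_areas[:15]
        assert (a2 <= a1 + 1e-9).all()

    def test_unknown_radius_policy(self):
        s = Structure([Atom(1, "ZN", "ZN", "ZN", 1, "A", (0, 0, 0))])
        assert sasa(s).total > 0  # default radius applies
        with pytest.raises(KeyError):
            sasa(s, radii=RadiusSet(default=None))

    def test_agrees_with_biotite_oracle(self, rng):
        # independent Shrake-Rupley implementation as cross-check
        import biotite.structure as struc

        coords = rng.uniform(0, 12, size=(25, 3))
        arr = struc.AtomArray(25)
        arr.coord = coords.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, 26)
        arr.res_name[:] = "GLY"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        ref = np.nansum(struc.sasa(arr, probe_radius=1.4, point_number=1000,
                                   vdw_radii="Single"))
        mine = sasa(Structure(make_chain(coords)), n_points=1000).total
        assert mine == pytest.approx(ref, rel=0.02)

    def test_sphere_points_on_unit_sphere(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


class TestInterfaceArea:
    def test_distant_groups_zero(self):
        a = Structure(make_chain(np.zeros((3, 3)) + [[0, 0, 0], [4, 0, 0], [0, 4, 0]]))
        b = Structure(make_chain(np.array([[100, 0, 0], [104, 0, 0]]), "B"))
        ia = interface_area(a, b)
        assert ia.bsa_half == pytest.approx(0.0, abs=1e-9)

    def test_half_sum_consistency_and_symmetry(self, rng):
        ca = rng.uniform(0, 8, size=(10, 3))
        cb = rng.uniform(0, 8, size=(10, 3)) + np.array([6.0, 0, 0])
        a = Structure(make_chain(ca, "A"), label="A")
        b = Structure(make_chain(cb, "B"), label="B")
        ab = interface_area(a, b)
        ba = interface_area(b, a)
        assert ab.bsa_half > 0
        assert ab.bsa_half == pytest.approx((ab.bsa_side_a + ab.bsa_side_b) / 2)
        assert ab.bsa_half == pytest.approx(ba.bsa_half, abs=1e-9)
        assert ab.bsa_side_a == pytest.approx(ba.bsa_side_b, abs=1e-9)

    def test_overlapping_groups_rejected(self):
        a = Structure(make_chain(np.zeros((2, 3))))
        with pytest.raises(UbrecError):
            interface_area(a, a)

    def test_convergence_960_vs_4000(self, rng):
        ca = rng.uniform(0, 8, size=(12, 3))
        cb = ca + np.array([5.0, 0.5, 0])
        a = Structure(make_chain(ca, "A"), label="A")
        b = Structure(make_chain(cb, "B"), label="B")
        lo = interface_area(a, b, n_points=960).bsa_half
        hi = interface_area(a, b, n_points=4000).bsa_half
        assert lo == pytest.approx(hi, rel=0.03)

    def test_per_residue_contributions_sum_to_side(self, rng):
        ca = rng.uniform(0, 6, size=(6, 3))
        cb = ca + np.array([4.5, 0, 0])
        a = Structure(make_chain(ca, "A"), label="A")
        b = Structure(make_chain(cb, "B"), label="B")
        ia = interface_area(a, b)
        assert sum(ia.per_residue_a.values()) == pytest.approx(ia.bsa_side_a)


class TestBurial:
    def test_no_neighbours_zero(self):
        s = two_chain_structure([(0, 0, 0), (4, 0, 0)], [(100, 0, 0), (104, 0, 0)])
        total, pairwise = burial_by_neighbours(s, "A", ["B"])
        assert total == pytest.approx(0.0, abs=1e-9)
        assert pairwise["B"].bsa_half == pytest.approx(0.0, abs=1e-9)

    def test_three_body_brute_force_oracle(self, rng):
        # total burial equals independent SASA differencing at high point count
        ca = rng.uniform(0, 7, size=(6, 3))
        cb = ca + np.array([5.0, 0, 0])
        cc = ca + np.array([0, 5.0, 0])
        atoms = (make_chain(ca, "A") + make_chain(cb, "B", start_serial=7)
                 + make_chain(cc, "C", start_serial=13))
        s = Structure(atoms)
        n_pts = 4000
        total, pairwise = burial_by_neighbours(s, "A", ["B", "C"], n_points=n_pts)
        a = Structure(make_chain(ca, "A"))
        ctx = Structure(atoms)
        alone = sasa(a, n_points=n_pts).total
        in_ctx = sasa(ctx, n_points=n_pts).atom_areas[:6].sum()
        assert total == pytest.approx(alone - in_ctx, abs=1e-6)
        # additivity bounds: >= max pairwise per-side loss, <= sum of losses
        sides = [p.bsa_side_a for p in pairwise.values()]
        assert total >= max(sides) - 1e-6
        assert total <= sum(sides) + 1e-6


class TestExposure:
    def _gly_residue(self, center, resseq, chain="A"):
        offsets = np.array([[0, 0, 0], [1.5, 0, 0], [2.2, 1.3, 0], [3.4, 1.2, 0.4]])
        names = ["N", "CA", "C", "O"]
        els = ["N", "C", "C", "O"]
        return [Atom(resseq * 10 + i, n, e, "GLY", resseq, chain,
                     tuple(center + o))
                for i, (n, e, o) in enumerate(zip(names, els, offsets))]

    def test_isolated_residue_fully_exposed(self):
        s = Structure(self._gly_residue(np.zeros(3), 1))
        rel, cls_ = exposure(s, "A", 1)
        assert rel > 0.8
        assert cls_ == "exposed"

    def test_buried_residue_near_zero(self, rng):
        atoms = self._gly_residue(np.zeros(3), 1)
        # cage of carbons tightly surrounding the residue
        shell = []
        k = 100
        for i, p in enumerate(sphere_points(200) * 5.5):
            shell.append(Atom(k + i, "CA", "C", "GLY", 50 + i, "B",
                              tuple(p + np.array([1.7, 0.6, 0.1]))))
        s = Structure(atoms + shell)
        rel, cls_ = exposure(s, "A", 1)
        assert rel < 0.05
        assert cls_ == "buried"

    def test_unknown_residue_type_rejected(self):
        s = Structure([Atom(1, "C1", "C", "LIG", 1, "A", (0, 0, 0))])
        with pytest.raises(UbrecError):
            exposure(s, "A", 1)

    def test_reference_table_complete(self):
        assert set(GXG_REFERENCE) == {
            "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
            "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
            "TYR", "VAL"}
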