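"""Solvent-accessible surface area (SASA), buried interface area, and
residue exposure.

SASA uses the Shrake-Rupley method on a deterministic golden-spiral sphere
point set (no RNG), 960 points and a 1.4 A probe by default.  Buried
interface area is reported in the per-complex half-sum convention
bsa = 0.5 * [SASA(A) + SASA(B) - SASA(AB)], with per-side losses also
emitted; that convention matches the ~400 A^2 scale quoted for small
Ub-binding-domain interfaces.  Covalent links across the two groups (the
isopeptide bond between the conjugated Ub C-terminus and the receptor
lysine) are implicitly severed, because each group is evaluated as an
independent body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import UbrecError
from .structure import RadiusSet, Structure, merge, select

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

#: Total Gly-X-Gly reference SASA per residue type (A^2), theoretical
#: maximum-exposure values (Tien et al. convention).
GXG_REFERENCE = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

EXPOSURE_THRESHOLD = 0.25


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)))


@dataclass
class SasaResult:
    """Per-atom solvent-accessible areas for one structure."""

    atom_areas: np.ndarray  # A^2, aligned with structure.atoms
    probe: float
    n_points: int
    radius_set: str = "element-default"

    @property
    def total(self) -> float:
        return float(self.atom_areas.sum())

    def residue_areas(self, s: Structure) -> dict[tuple[str, int, str], float]:
        out: dict[tuple[str, int, str], float] = {}
        for a, area in zip(s.atoms, self.atom_areas):
            key = (a.chain, a.resseq, a.resname)
            out[key] = out.get(key, 0.0) + float(area)
        return out


def sasa(s: Structure, probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS,
         radii: RadiusSet | None = None) -> SasaResult:
    """Shrake-Rupley SASA, deterministic for a given point count."""
    radii = radii or RadiusSet()
    xyz = s.coords()
    r = radii.for_atoms(s.atoms) + probe
    pts = sphere_points(n_points)
    n = len(s.atoms)
    areas = np.empty(n)
    tree = cKDTree(xyz)
    max_r = r.max()
    for i in range(n):
        # neighbours whose expanded sphere can cover points of sphere i
        nbr = tree.query_ball_point(xyz[i], r[i] + max_r)
        nbr = [j for j in nbr if j != i]
        test = xyz[i] + r[i] * pts
        if nbr:
            d2 = ((test[:, None, :] - xyz[nbr][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (r[nbr] ** 2)[None, :]).any(axis=1)
            n_acc = int((~buried).sum())
        else:
            n_acc = n_points
        areas[i] = 4.0 * np.pi * r[i] ** 2 * n_acc / n_points
    return SasaResult(areas, probe, n_points)


@dataclass
class InterfaceArea:
    """Buried-surface bookkeeping for one pair of groups."""

    group_a: str
    group_b: str
    bsa_half: float
    bsa_side_a: float
    bsa_side_b: float
    per_residue_a: dict = field(default_factory=dict)
    per_residue_b: dict = field(default_factory=dict)
    probe: float = DEFAULT_PROBE
    n_points: int = DEFAULT_N_POINTS

    def __post_init__(self):
        if self.bsa_half < -1e-6:
            raise ValueError("negative buried area")


def _check_disjoint(a: Structure, b: Structure):
    keys_a = {(at.chain, at.resseq, at.name) for at in a.atoms}
    keys_b = {(at.chain, at.resseq, at.name) for at in b.atoms}
    if keys_a & keys_b:
        raise UbrecError("interface groups overlap; they must be disjoint atom sets")


def interface_area(group_a: Structure, group_b: Structure,
                   probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS,
                   radii: RadiusSet | None = None) -> InterfaceArea:
    """Buried surface area between two disjoint atom groups.

    Three SASA runs with identical parameters: A alone, B alone, and the
    A+B complex.  ``bsa_half`` is half the total SASA loss; per-side losses
    and per-residue contributions are also returned.
    """
    _check_disjoint(group_a, group_b)
    radii = radii or RadiusSet()
    sa = sasa(group_a, probe, n_points, radii)
    sb = sasa(group_b, probe, n_points, radii)
    ab = merge([group_a, group_b], label="complex")
    sab = sasa(ab, probe, n_points, radii)
    na = len(group_a.atoms)
    ab_a = sab.atom_areas[:na]
    ab_b = sab.atom_areas[na:]
    loss_a = sa.atom_areas - ab_a
    loss_b = sb.atom_areas - ab_b
    side_a = float(loss_a.sum())
    side_b = float(loss_b.sum())

    def _per_res(group: Structure, loss: np.ndarray):
        out: dict[tuple[str, int, str], float] = {}
        for at, v in zip(group.atoms, loss):
            key = (at.chain, at.resseq, at.resname)
            out[key] = out.get(key, 0.0) + float(v)
        return out

    return InterfaceArea(
        group_a=group_a.label, group_b=group_b.label,
        bsa_half=max(0.0, 0.5 * (side_a + side_b)),
        bsa_side_a=side_a, bsa_side_b=side_b,
        per_residue_a=_per_res(group_a, loss_a),
        per_residue_b=_per_res(group_b, loss_b),
        probe=probe, n_points=n_points,
    )


def burial_by_neighbours(s: Structure, chain: str, neighbour_chains: list[str],
                         probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS,
                         radii: RadiusSet | None = None):
    """Total area a chain buries against a set of neighbour chains, plus the
    pairwise interface with each neighbour.

    Total burial = SASA(chain alone) - SASA(chain in the context of all
    neighbours); this is a per-side quantity (the chain's own loss), which is
    what "subunit X buries N A^2" statements refer to.
    """
    radii = radii or RadiusSet()
    target = select(s, chains=[chain], label=chain)
    nbrs = [select(s, chains=[c], label=c) for c in neighbour_chains]
    alone = sasa(target, probe, n_points, radii).total
    context = merge([target] + nbrs, label="context")
    ctx_res = sasa(context, probe, n_points, radii)
    in_context = float(ctx_res.atom_areas[: len(target.atoms)].sum())
    total_buried = alone - in_context
    pairwise = {c: interface_area(target, nb, probe, n_points, radii)
                for c, nb in zip(neighbour_chains, nbrs)}
    return total_buried, pairwise


def exposure(s: Structure, chain: str, resseq: int,
             probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS,
             radii: RadiusSet | None = None,
             threshold: float = EXPOSURE_THRESHOLD):
    """Relative SASA of one residue in its structural context.

    Fraction of the Gly-X-Gly maximum-exposure reference for the residue
    type; values can slightly exceed 1 for unusually extended conformations.
    Returns ``(rel_sasa, classification)`` with classification ``"exposed"``
    when rel_sasa >= ``threshold`` (default 0.25), else ``"buried"``.
    """
    res = select(s, chains=[chain], resseq=[resseq])
    resname = res.atoms[0].resname.upper()
    if resname not in GXG_REFERENCE:
        raise UbrecError(f"no exposure reference area for residue type {resname!r}")
    full = sasa(s, probe, n_points, radii)
    area = sum(
        ar for at, ar in zip(s.atoms, full.atom_areas)
        if at.chain == chain and at.resseq == resseq
    )
    rel = float(area / GXG_REFERENCE[resname])
    return rel, ("exposed" if rel >= threshold else "buried")
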