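"""Protein structures: reading, selection, unit cells and symmetry mates.

Coordinates are kept in Angstrom with the 1-based residue numbering of the
source file (no renumbering).  File parsing is delegated to :mod:`gemmi`;
the in-memory model here is a deliberately small, flat list of atoms grouped
by chain, which is all the downstream surface/clash/superposition stages
need.
"""

from __future__ import annotations

import copy as _copy
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateGeometryError,
    EmptySelectionError,
    EmptyStructureError,
    FormatError,
    MissingMetadataError,
)

log = logging.getLogger(__name__)

WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}

#: Element-based van der Waals radii (A). Standard Lee-Richards-compatible set.
DEFAULT_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "D": 1.20,
    "P": 1.80,
    "SE": 1.90,
}

#: Fallback radius for elements absent from the table (ions etc.).
DEFAULT_UNKNOWN_RADIUS = 1.8


@dataclass(frozen=True)
class Atom:
    """One atom record.

    ``xyz`` is Cartesian, Angstrom.  ``resseq`` keeps the author numbering
    from the file.
    """

    serial: int
    name: str
    element: str
    resname: str
    resseq: int
    chain: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        if not all(math.isfinite(c) for c in self.xyz):
            raise ValueError(f"non-finite coordinate in atom {self.serial} {self.name}")
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name} has empty element")


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell (edges in Angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise DegenerateGeometryError(f"unit cell has non-positive edge: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise DegenerateGeometryError(f"unit cell angle out of (0,180): {ang}")

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix M with cartesian = M @ fractional (PDB convention:
        a along x, b in the xy plane)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if v <= 0 or sg == 0:
            raise DegenerateGeometryError(f"degenerate unit cell: {self}")
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * math.sqrt(v) / sg],
            ]
        )

    @property
    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization_matrix)

    @property
    def volume(self) -> float:
        """Cell volume in A^3 (determinant of the orthogonalization matrix)."""
        return float(np.linalg.det(self.orthogonalization_matrix))

    def orthogonalize(self, frac) -> np.ndarray:
        """Fractional -> Cartesian (A). Accepts a 3-vector or (N,3)."""
        frac = np.asarray(frac, dtype=float)
        return frac @ self.orthogonalization_matrix.T

    def fractionalize(self, xyz) -> np.ndarray:
        """Cartesian (A) -> fractional."""
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.fractionalization_matrix.T


@dataclass(frozen=True)
class SymOp:
    """Space-group operator in the fractional basis: x' = rot @ x + tran."""

    rotation: tuple  # 3x3 nested tuple
    translation: tuple  # 3-vector

    def __post_init__(self):
        r = np.asarray(self.rotation, float)
        if r.shape != (3, 3):
            raise ValueError("SymOp rotation must be 3x3")
        det = round(float(np.linalg.det(r)))
        if det not in (-1, 1):
            raise ValueError(f"SymOp rotation determinant {det}, expected +-1")

    @property
    def rot(self) -> np.ndarray:
        return np.asarray(self.rotation, float)

    @property
    def tran(self) -> np.ndarray:
        return np.asarray(self.translation, float)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rot, np.eye(3)) and np.allclose(self.tran % 1.0, 0.0)

    @classmethod
    def identity(cls) -> "SymOp":
        return cls(tuple(map(tuple, np.eye(3))), (0.0, 0.0, 0.0))


class RadiusSet:
    """Maps element symbols to van der Waals radii (A).

    Unknown elements resolve to ``default`` (1.8 A) with a logged warning,
    so metal ions in deposited files do not abort a surface calculation.
    """

    def __init__(self, radii: dict[str, float] | None = None,
                 default: float | None = DEFAULT_UNKNOWN_RADIUS):
        self.radii = dict(DEFAULT_RADII if radii is None else radii)
        self.default = default
        self._warned: set[str] = set()

    def get(self, element: str) -> float:
        el = element.upper()
        if el in self.radii:
            return self.radii[el]
        if self.default is None:
            raise KeyError(f"no van der Waals radius for element {element!r}")
        if el not in self._warned:
            log.warning("element %r not in radius table; using default %.2f A", element, self.default)
            self._warned.add(el)
        return self.default

    def for_atoms(self, atoms: Sequence[Atom]) -> np.ndarray:
        return np.array([self.get(a.element) for a in atoms])


@dataclass
class Structure:
    """A set of atoms with optional crystallographic metadata.

    Atom order is preserved from the source; chains are contiguous runs are
    not required — grouping is by the ``chain`` field.
    """

    atoms: list[Atom]
    cell: UnitCell | None = None
    symops: list[SymOp] = field(default_factory=list)
    label: str = ""
    spacegroup: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise EmptyStructureError(f"structure {self.label!r} has no atoms")
        # chain ids must be unique as groups; with a flat list this just means
        # the set of ids is well-defined, which it always is.

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def with_coords(self, xyz: np.ndarray, label: str | None = None) -> "Structure":
        """Copy with replaced coordinates (same atom metadata)."""
        xyz = np.asarray(xyz, float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, xyz=tuple(p)) for a, p in zip(self.atoms, xyz)]
        return Structure(atoms, cell=self.cell, symops=list(self.symops),
                         label=self.label if label is None else label,
                         spacegroup=self.spacegroup)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, resseq, resname) triples."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.resseq, a.resname), None)
        return list(seen)

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Reading / writing


def _apply_policy(atoms: list[Atom], *, keep_waters: bool, keep_hydrogens: bool,
                  altloc: str) -> list[Atom]:
    if not keep_waters:
        atoms = [a for a in atoms if a.resname not in WATER_RESNAMES]
    if not keep_hydrogens:
        atoms = [a for a in atoms if a.element.upper() not in ("H", "D")]
    if altloc == "all":
        return atoms
    # keep the highest-occupancy alternative per (chain, resseq, atom name);
    # ties resolve to the earlier record.
    best: dict[tuple[str, int, str], Atom] = {}
    order: list[tuple[str, int, str]] = []
    for a in atoms:
        key = (a.chain, a.resseq, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        elif a.occupancy > best[key].occupancy:
            best[key] = a
    return [best[k] for k in order]


def read_structure(path, *, keep_waters: bool = False, keep_hydrogens: bool = False,
                   altloc: str = "highest-occupancy", model: int = 0,
                   label: str | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Default hygiene: waters and hydrogens dropped, only the highest-occupancy
    altloc kept.  For multi-model (NMR ensemble) files only ``model`` is read
    (first model by default).  Unit cell and space-group operators are taken
    from CRYST1; operators come from gemmi's space-group table since
    deposited files carry the space-group name, not explicit operators.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models found")
    mdl = st[min(model, len(st) - 1)]

    atoms: list[Atom] = []
    for chain in mdl:
        for res in chain:
            for at in res:
                el = at.element.name if at.element else ""
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=el or _guess_element(at.name),
                        resname=res.name,
                        resseq=res.seqid.num,
                        chain=chain.name,
                        xyz=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=at.occ,
                        altloc=at.altloc if at.altloc != "\x00" else "",
                    )
                )
    atoms = _apply_policy(atoms, keep_waters=keep_waters,
                          keep_hydrogens=keep_hydrogens, altloc=altloc)
    if not atoms:
        raise EmptyStructureError(f"{path}: no atoms left after read policy")

    cell = None
    symops: list[SymOp] = []
    sg_name = st.spacegroup_hm or ""
    if st.cell is not None and st.cell.is_crystal():
        try:
            cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                            st.cell.alpha, st.cell.beta, st.cell.gamma)
        except DegenerateGeometryError:
            cell = None
    if cell is not None and sg_name:
        sg = gemmi.find_spacegroup_by_name(sg_name)
        if sg is not None:
            symops = [_symop_from_gemmi(op) for op in sg.operations()]
    return Structure(atoms, cell=cell, symops=symops,
                     label=label if label is not None else path.stem,
                     spacegroup=sg_name)


def _symop_from_gemmi(op) -> SymOp:
    den = float(op.DEN)
    rot = tuple(tuple(v / den for v in row) for row in op.rot)
    tran = tuple(v / den for v in op.tran)
    return SymOp(rot, tran)


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


_PDB_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n"
)


def write_pdb(s: Structure, path) -> None:
    """Write atoms (and CRYST1 when a cell is present) in PDB format."""
    lines = []
    if s.cell is not None:
        sg = s.spacegroup or "P 1"
        lines.append(
            f"CRYST1{s.cell.a:9.3f}{s.cell.b:9.3f}{s.cell.c:9.3f}"
            f"{s.cell.alpha:7.2f}{s.cell.beta:7.2f}{s.cell.gamma:7.2f} {sg:<11s}\n"
        )
    for a in s.atoms:
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(_PDB_ATOM_FMT.format(
            serial=a.serial % 100000, name=name, altloc=a.altloc or " ",
            resname=a.resname, chain=(a.chain or "A")[:1], resseq=a.resseq,
            x=a.xyz[0], y=a.xyz[1], z=a.xyz[2], occ=a.occupancy, b=0.0,
            el=a.element[:2],
        ))
    lines.append("END\n")
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# Selection


def select(s: Structure, *, chains: Iterable[str] | None = None,
           resseq: Iterable[int] | tuple[int, int] | None = None,
           resnames: Iterable[str] | None = None,
           atom_names: Iterable[str] | None = None,
           label: str | None = None) -> Structure:
    """Return the sub-structure matching all given predicates.

    ``resseq`` may be a ``(first, last)`` inclusive range or an explicit set
    of residue numbers.  The original structure is untouched.  A selection
    matching nothing raises :class:`EmptySelectionError`.
    """
    chains_set = set(chains) if chains is not None else None
    resnames_set = {r.upper() for r in resnames} if resnames is not None else None
    names_set = {n.upper() for n in atom_names} if atom_names is not None else None
    if resseq is None:
        res_pred = None
    elif isinstance(resseq, tuple) and len(resseq) == 2:
        lo, hi = resseq
        res_pred = lambda n: lo <= n <= hi  # noqa: E731
    else:
        res_set = set(resseq)
        res_pred = res_set.__contains__

    picked = [
        a for a in s.atoms
        if (chains_set is None or a.chain in chains_set)
        and (res_pred is None or res_pred(a.resseq))
        and (resnames_set is None or a.resname.upper() in resnames_set)
        and (names_set is None or a.name.upper() in names_set)
    ]
    if not picked:
        raise EmptySelectionError(
            f"selection matched no atoms (chains={chains}, resseq={resseq}, "
            f"resnames={resnames}, atom_names={atom_names})"
        )
    return Structure(picked, cell=s.cell, symops=list(s.symops),
                     label=label if label is not None else s.label,
                     spacegroup=s.spacegroup)


def parse_selection(expr: str) -> dict:
    """Parse a CLI selection like ``"A"``, ``"A:1-191"`` or ``"A:84"``.

    Returns keyword arguments for :func:`select`.
    """
    expr = expr.strip()
    if not expr:
        raise ValueError("empty selection expression")
    if ":" not in expr:
        return {"chains": [expr]}
    chain, rng = expr.split(":", 1)
    kwargs: dict = {"chains": [chain]} if chain else {}
    if "-" in rng:
        lo, hi = rng.split("-", 1)
        kwargs["resseq"] = (int(lo), int(hi))
    else:
        kwargs["resseq"] = [int(rng)]
    return kwargs


# ---------------------------------------------------------------------------
# Symmetry expansion


def expand_symmetry(s: Structure, contact_cutoff: float = 5.0):
    """Generate symmetry/lattice images with >= 1 atom within
    ``contact_cutoff`` A of the input molecule.

    Returns a list of ``(SymOp, lattice_shift, Structure)`` where
    ``lattice_shift`` is the integer unit-cell translation applied after the
    operator.  Each image is an isometric copy (crystallographic operators
    are orthogonal in the Cartesian basis).  The identity image with zero
    shift is excluded.
    """
    from scipy.spatial import cKDTree

    if s.cell is None:
        raise MissingMetadataError("structure has no unit cell; cannot expand symmetry")
    ops = s.symops or [SymOp.identity()]

    M = s.cell.orthogonalization_matrix
    xyz = s.coords()
    frac = s.cell.fractionalize(xyz)
    tree = cKDTree(xyz)

    # conservative fractional margin per axis for the Cartesian cutoff
    Minv = s.cell.fractionalization_matrix
    margin = contact_cutoff * np.linalg.norm(Minv, axis=1)

    fmin, fmax = frac.min(axis=0), frac.max(axis=0)
    out = []
    for op in ops:
        img_frac = frac @ op.rot.T + op.tran
        gmin, gmax = img_frac.min(axis=0), img_frac.max(axis=0)
        lo = np.floor(fmin - gmax - margin).astype(int)
        hi = np.ceil(fmax - gmin + margin).astype(int)
        for n0 in range(lo[0], hi[0] + 1):
            for n1 in range(lo[1], hi[1] + 1):
                for n2 in range(lo[2], hi[2] + 1):
                    shift = np.array([n0, n1, n2], float)
                    if op.is_identity and not shift.any():
                        continue
                    img_xyz = (img_frac + shift) @ M.T
                    d, _ = tree.query(img_xyz, k=1, distance_upper_bound=contact_cutoff)
                    if np.isfinite(d).any():
                        out.append((op, (n0, n1, n2), s.with_coords(
                            img_xyz, label=f"{s.label}|sym")))
    return out


def merge(structures: Sequence[Structure], label: str = "merged") -> Structure:
    """Concatenate structures into one, keeping each atom's chain id."""
    atoms: list[Atom] = []
    for st in structures:
        atoms.extend(st.atoms)
    first = structures[0]
    return Structure(atoms, cell=first.cell, symops=list(first.symops),
                     label=label, spacegroup=first.spacegroup)
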