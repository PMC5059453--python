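"""Residue correspondence, Kabsch superposition, and rigid transplant.

The Kabsch step is the standard SVD solution of the orthogonal Procrustes
problem with the determinant correction that excludes reflections.  The
cross-species comparison that motivates this module needs a sequence
alignment to pair residues, so correspondences can be built either by
residue number or by global alignment (BLOSUM62, gap open 10, extend 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, UbrecError
from .structure import Structure, select

#: 3-letter -> 1-letter amino-acid codes (X for anything else).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}

ALIGN_MATRIX = "BLOSUM62"
GAP_OPEN = 10.0
GAP_EXTEND = 0.5


class CorrespondenceError(UbrecError):
    """Too few matched residues for a superposition."""


@dataclass(frozen=True)
class Correspondence:
    """Ordered pairs of matched residue numbers between two structures."""

    pairs: tuple  # of (resseq_a, resseq_b)
    mode: str = "by-number"

    def __post_init__(self):
        a_col = [p[0] for p in self.pairs]
        b_col = [p[1] for p in self.pairs]
        if len(set(a_col)) != len(a_col) or len(set(b_col)) != len(b_col):
            raise ValueError("correspondence pairs must be unique in both columns")

    def __len__(self):
        return len(self.pairs)


@dataclass(frozen=True)
class Superposition:
    """Optimal proper rotation + translation mapping A onto B, with RMSD.

    ``transform(x) = rotation @ x + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is improper (det < 0)")
        if self.rmsd < 0:
            raise ValueError("negative rmsd")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ np.asarray(self.rotation).T + np.asarray(self.translation)

    def inverse(self) -> "Superposition":
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        return Superposition(R.T, -R.T @ t, self.rmsd, self.n_pairs, dict(self.metadata))


def _ca_table(s: Structure) -> dict[int, tuple[str, np.ndarray]]:
    """resseq -> (one-letter code, CA position); first chain's numbering wins."""
    table: dict[int, tuple[str, np.ndarray]] = {}
    for a in s.atoms:
        if a.name.strip().upper() == "CA" and a.resseq not in table:
            table[a.resseq] = (THREE_TO_ONE.get(a.resname.upper(), "X"),
                               np.array(a.xyz))
    if not table:
        raise UbrecError(f"structure {s.label!r} has no CA atoms")
    return table


def build_correspondence(a: Structure, b: Structure, mode: str = "by-number") -> Correspondence:
    """Pair residues of two structures.

    ``by-number`` pairs equal residue numbers (intersection).  ``by-alignment``
    globally aligns the one-letter sequences (BLOSUM62, gap open 10,
    extend 0.5) and keeps aligned non-gap positions — required whenever the
    two structures use different numbering, e.g. orthologues.
    """
    ta, tb = _ca_table(a), _ca_table(b)
    if mode == "by-number":
        common = sorted(set(ta) & set(tb))
        pairs = tuple((n, n) for n in common)
    elif mode == "by-alignment":
        from Bio import Align
        from Bio.Align import substitution_matrices

        nums_a, nums_b = sorted(ta), sorted(tb)
        seq_a = "".join(ta[n][0] for n in nums_a)
        seq_b = "".join(tb[n][0] for n in nums_b)
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load(ALIGN_MATRIX)
        aligner.open_gap_score = -GAP_OPEN
        aligner.extend_gap_score = -GAP_EXTEND
        aligner.mode = "global"
        aln = aligner.align(seq_a, seq_b)[0]
        pairs_list = []
        for (sa, ea), (sb, eb) in zip(*aln.aligned):
            for i, j in zip(range(sa, ea), range(sb, eb)):
                pairs_list.append((nums_a[i], nums_b[j]))
        pairs = tuple(pairs_list)
    else:
        raise ValueError(f"unknown correspondence mode {mode!r}")
    if len(pairs) < 3:
        raise CorrespondenceError(
            f"only {len(pairs)} residue pairs between {a.label!r} and {b.label!r}; need >= 3")
    return Correspondence(pairs, mode=mode)


def paired_ca_coords(a: Structure, b: Structure, corr: Correspondence):
    ta, tb = _ca_table(a), _ca_table(b)
    pa = np.array([ta[i][1] for i, _ in corr.pairs])
    pb = np.array([tb[j][1] for _, j in corr.pairs])
    return pa, pb


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray, metadata: dict | None = None) -> Superposition:
    """Least-squares optimal proper rigid transform mapping A onto B.

    Reflections are excluded by flipping the sign of the smallest singular
    vector when the raw solution is improper.  Collinear or degenerate input
    raises :class:`DegenerateGeometryError`.
    """
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (N,3)")
    n = A.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    # collinearity check: rank of the centred cloud
    if np.linalg.matrix_rank(A0, tol=1e-8) < 2 or np.linalg.matrix_rank(B0, tol=1e-8) < 2:
        raise DegenerateGeometryError("point set is collinear or degenerate")
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = A0 @ R.T - B0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return Superposition(R, t, rmsd, n, metadata or {})


def superpose_structures(mobile: Structure, target: Structure, mode: str = "by-alignment",
                         trim: bool = False, trim_sigma: float = 2.0,
                         max_trim_cycles: int = 5) -> Superposition:
    """Superpose on all aligned CA pairs; optionally iteratively discard
    pairs deviating > ``trim_sigma`` standard deviations (<= 5 cycles).

    The default (no trimming) uses every aligned pair; the trimmed variant
    reports the core RMSD, since superposition software differs in whether
    flexible termini/loops are excluded.
    """
    corr = build_correspondence(mobile, target, mode=mode)
    pa, pb = paired_ca_coords(mobile, target, corr)
    sup = kabsch(pa, pb, metadata={"mode": mode, "matrix": ALIGN_MATRIX,
                                   "gap_open": GAP_OPEN, "gap_extend": GAP_EXTEND,
                                   "trim": trim})
    if not trim:
        return sup
    keep = np.ones(len(pa), bool)
    for _ in range(max_trim_cycles):
        dev = np.linalg.norm(sup.apply(pa[keep]) - pb[keep], axis=1)
        thresh = dev.mean() + trim_sigma * dev.std()
        new_keep = keep.copy()
        new_keep[np.where(keep)[0][dev > thresh]] = False
        if new_keep.sum() < 3 or new_keep.sum() == keep.sum():
            break
        keep = new_keep
        sup = kabsch(pa[keep], pb[keep], metadata=dict(sup.metadata))
    return sup


def transplant(mobile_complex: Structure, anchor_sel: dict, target: Structure,
               target_sel: dict | None = None, mode: str = "by-alignment",
               trim: bool = False):
    """Superpose an anchor subunit onto a target subunit and carry the whole
    mobile complex along.

    ``anchor_sel``/``target_sel`` are :func:`ubrec.structure.select` keyword
    dicts picking the anchor within the mobile complex and the matching
    subunit within the target.  Returns ``(transformed_complex,
    Superposition)``; the transform is rigid, so every intra-complex distance
    is preserved.
    """
    anchor = select(mobile_complex, **anchor_sel)
    tgt = select(target, **target_sel) if target_sel else target
    sup = superpose_structures(anchor, tgt, mode=mode, trim=trim)
    moved = mobile_complex.with_coords(sup.apply(mobile_complex.coords()),
                                      label=f"{mobile_complex.label}|transplanted")
    return moved, sup
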