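"""Simplified hydrophobic surface-patch scan for candidate Ub-binding sites.

Known ubiquitin-binding domains engage the exposed I44 hydrophobic patch of
Ub through a small (~400 A^2) apolar surface.  This module scans every
exposed residue of a structure and scores the solvent-exposed hydrophobic
area clustered around its side chain, which is a deliberately simplified
stand-in for full geometric surface matching against UBD templates: no
geometric hashing, no docking refinement — just the physico-chemical
signature (exposed apolar area and the hydrophobic/polar/charged
composition of the patch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UbrecError
from .structure import RadiusSet, Structure
from .surface import GXG_REFERENCE, SasaResult, sasa

#: Residues whose side chains count as apolar.
APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "CYS"}
CHARGED_RESIDUES = {"ASP", "GLU", "LYS", "ARG", "HIS"}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

DEFAULT_RADIUS = 8.0
DEFAULT_MIN_REL_SASA = 0.2


@dataclass
class PatchScore:
    """Physico-chemical signature of the surface patch around one residue."""

    chain: str
    resseq: int
    resname: str
    hydrophobic_area: float  # exposed apolar area within the patch, A^2
    total_area: float        # all exposed area within the patch, A^2
    composition: tuple       # (hydrophobic, polar, charged) fractions, sum 1

    def __post_init__(self):
        if self.total_area > 0 and abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")


def _atom_class(atom) -> str:
    """hydrophobic: C/S atoms of apolar residues' side chains; charged:
    side-chain atoms of D/E/K/R/H; everything else polar."""
    resname = atom.resname.upper()
    name = atom.name.strip().upper()
    if name not in BACKBONE_ATOMS and resname in APOLAR_RESIDUES \
            and atom.element.upper() in ("C", "S"):
        return "hydrophobic"
    if name not in BACKBONE_ATOMS and resname in CHARGED_RESIDUES:
        return "charged"
    return "polar"


def _side_chain_centroids(s: Structure) -> dict[tuple[str, int], np.ndarray]:
    """Side-chain centroid per residue (CA fallback for glycine)."""
    sums: dict[tuple[str, int], list] = {}
    ca: dict[tuple[str, int], np.ndarray] = {}
    for a in s.atoms:
        key = (a.chain, a.resseq)
        name = a.name.strip().upper()
        if name == "CA":
            ca[key] = np.array(a.xyz)
        if name not in BACKBONE_ATOMS:
            sums.setdefault(key, []).append(np.array(a.xyz))
    out = {}
    for key in set(sums) | set(ca):
        pts = sums.get(key)
        out[key] = np.mean(pts, axis=0) if pts else ca[key]
    return out


def hydrophobic_patches(s: Structure, radius: float = DEFAULT_RADIUS,
                        min_rel_sasa: float = DEFAULT_MIN_REL_SASA,
                        sasa_result: SasaResult | None = None,
                        radii: RadiusSet | None = None) -> list[PatchScore]:
    """Rank candidate binding patches by exposed hydrophobic area.

    For every residue whose relative SASA is at least ``min_rel_sasa``, sums
    the solvent-exposed hydrophobic atom area within ``radius`` A of its
    side-chain centroid, plus the patch's composition vector.  Returns
    patches in descending hydrophobic-area order.
    """
    res = sasa_result or sasa(s, radii=radii)
    xyz = s.coords()
    areas = res.atom_areas
    classes = [_atom_class(a) for a in s.atoms]
    centroids = _side_chain_centroids(s)

    res_area = res.residue_areas(s)
    exposed_res = []
    for (chain, num, name), area in res_area.items():
        ref = GXG_REFERENCE.get(name.upper())
        if ref and area / ref >= min_rel_sasa and (chain, num) in centroids:
            exposed_res.append((chain, num, name))
    if not exposed_res:
        raise UbrecError("structure has no exposed residues to scan")

    patches = []
    for chain, num, name in exposed_res:
        center = centroids[(chain, num)]
        d = np.linalg.norm(xyz - center, axis=1)
        inside = d <= radius
        hydro = polar = charged = 0.0
        for k in np.where(inside)[0]:
            a = float(areas[k])
            if a <= 0:
                continue
            c = classes[k]
            if c == "hydrophobic":
                hydro += a
            elif c == "charged":
                charged += a
            else:
                polar += a
        total = hydro + polar + charged
        comp = (hydro / total, polar / total, charged / total) if total > 0 else (0.0, 0.0, 0.0)
        patches.append(PatchScore(chain, num, name, hydro, total, comp))
    patches.sort(key=lambda p: p.hydrophobic_area, reverse=True)
    return patches


def template_similarity(candidate: PatchScore, template: PatchScore) -> float:
    """Similarity in [0,1] between two patches: cosine similarity of the
    composition vectors, weighted by the exposed-area ratio min/max.
    Symmetric; zero-area patches are an error."""
    if candidate.total_area <= 0 or template.total_area <= 0:
        raise UbrecError("cannot compare zero-area patches")
    u = np.asarray(candidate.composition, float)
    v = np.asarray(template.composition, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UbrecError("patch composition vector is zero")
    cos = float(np.dot(u, v) / (nu * nv))
    ratio = min(candidate.total_area, template.total_area) / max(candidate.total_area,
                                                                 template.total_area)
    return max(0.0, min(1.0, cos * ratio))
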