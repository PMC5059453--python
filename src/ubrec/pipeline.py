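"""End-to-end report orchestration.

Two entry points: a structural report (superposition RMSDs, interface
areas, exposure, clash verdicts across supplied target models) and an assay
report (Kd/Ka table, growth efficiencies, wild-type-normalised relative
values and the efficiency-affinity Pearson correlation).  Every report
embeds the full parameter set so identical config + inputs give identical
numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assay import LogisticGrowth, SingleSiteBinding, correlate, growth_efficiency
from .clash import clash_report
from .errors import UbrecError
from .structure import expand_symmetry, parse_selection, read_structure, select
from .superpose import superpose_structures, transplant
from .surface import burial_by_neighbours, exposure, interface_area

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for the report commands.

    Selections are CLI-style strings ("A", "A:1-191").  ``targets`` maps a
    model name to a PDB path for clash assessment against multiple
    (e.g. cryo-EM) target models.
    """

    structure_path: str | None = None
    comparison_path: str | None = None
    ub_selection: str = "B"
    receptor_selection: str = "A"
    anchor_selection: str | None = None  # within structure, for transplants
    targets: dict = field(default_factory=dict)  # name -> path
    target_anchor_selection: str | None = None
    target_clash_selection: str | None = None
    neighbour_chains: list = field(default_factory=list)
    exposure_residues: list = field(default_factory=list)  # [(chain, resseq)]
    symmetry_cutoff: float = 5.0
    sasa_points: int = 960
    probe: float = 1.4
    clash_tolerance: float = 0.4
    binding_files: dict = field(default_factory=dict)  # construct -> CSV path
    growth_files: dict = field(default_factory=dict)   # construct -> CSV (time, density)
    wild_type: str = "wild_type"
    nb_handling: str = "exclude"  # or "floor"
    nb_floor_ka: float = 0.0
    bootstrap: int = 200
    seed: int = 0
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def params(self) -> dict:
        return {
            "version": __version__,
            "symmetry_cutoff": self.symmetry_cutoff,
            "sasa_points": self.sasa_points,
            "probe": self.probe,
            "clash_tolerance": self.clash_tolerance,
            "bootstrap": self.bootstrap,
            "seed": self.seed,
            "nb_handling": self.nb_handling,
        }


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""
    class _Ctx:
        def __init__(self, n):
            self.n = n

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, UbrecError):
                return False
            if exc is not None:
                raise UbrecError(f"stage {self.n!r}: {exc}") from exc
            return False
    return _Ctx(name)


def run_structure_report(config: PipelineConfig) -> dict:
    """Superposition, interface, burial/exposure and clash analyses in one
    JSON-serialisable report."""
    report: dict = {"parameters": config.params(), "stages": {}}
    if config.structure_path is None:
        raise UbrecError("structure_path is required for a structure report")
    with _stage("read"):
        s = read_structure(config.structure_path)
    ub_sel = parse_selection(config.ub_selection)
    rec_sel = parse_selection(config.receptor_selection)
    with _stage("conjugate-interface"):
        ub = select(s, **ub_sel, label="Ub")
        rec = select(s, **rec_sel, label="receptor")
        ia = interface_area(ub, rec, probe=config.probe, n_points=config.sasa_points)
        report["stages"]["conjugate_interface"] = {
            "bsa_half_A2": ia.bsa_half, "bsa_side_ub_A2": ia.bsa_side_a,
            "bsa_side_receptor_A2": ia.bsa_side_b,
        }
    if s.cell is not None and s.symops:
        with _stage("lattice-interface"):
            mates = expand_symmetry(s, contact_cutoff=config.symmetry_cutoff)
            lattice = []
            for op, shift, mate in mates:
                mate_ub = select(mate, **ub_sel, label="sym-Ub")
                ia_sym = interface_area(rec, mate_ub, probe=config.probe,
                                        n_points=config.sasa_points)
                lattice.append({"shift": list(shift), "bsa_half_A2": ia_sym.bsa_half})
            report["stages"]["lattice_interfaces"] = sorted(
                lattice, key=lambda x: -x["bsa_half_A2"])
    if config.comparison_path:
        with _stage("superposition"):
            other = read_structure(config.comparison_path)
            out = {}
            for trim in (False, True):
                sup = superpose_structures(rec, other, mode="by-alignment", trim=trim)
                out["trimmed" if trim else "all_pairs"] = {
                    "rmsd_A": sup.rmsd, "n_pairs": sup.n_pairs}
            report["stages"]["superposition"] = out
    if config.exposure_residues:
        with _stage("exposure"):
            report["stages"]["exposure"] = {}
            for chain, resseq in config.exposure_residues:
                rel, cls_ = exposure(s, chain, int(resseq),
                                     probe=config.probe, n_points=config.sasa_points)
                report["stages"]["exposure"][f"{chain}{resseq}"] = {
                    "rel_sasa": rel, "class": cls_}
    clash_out = {}
    for name, path in config.targets.items():
        with _stage(f"clash:{name}"):
            target = read_structure(path)
            anchor_sel = parse_selection(config.anchor_selection or config.receptor_selection)
            t_anchor = parse_selection(config.target_anchor_selection) \
                if config.target_anchor_selection else None
            moved, sup = transplant(s, anchor_sel, target, t_anchor)
            moved_ub = select(moved, **ub_sel)
            against = select(target, **parse_selection(config.target_clash_selection)) \
                if config.target_clash_selection else target
            rep = clash_report(moved_ub, against, tolerance=config.clash_tolerance)
            entry = {"anchor_rmsd_A": sup.rmsd, "clash_count": rep.clash_count,
                     "max_overlap_A": rep.max_overlap, "verdict": rep.verdict}
            if config.neighbour_chains:
                for ch in config.neighbour_chains:
                    others = [c for c in target.chains if c != ch]
                    buried, _ = burial_by_neighbours(target, ch, others,
                                                     probe=config.probe,
                                                     n_points=config.sasa_points)
                    entry[f"buried_{ch}_A2"] = buried
            clash_out[name] = entry
    if clash_out:
        report["stages"]["clash"] = clash_out
    return report


def run_assay_report(config: PipelineConfig, panel: list | None = None) -> dict:
    """Binding + growth analysis with wild-type-normalised relative values
    and the efficiency-affinity correlation.

    ``panel`` may supply in-memory entries (dicts with ``name``,
    ``binding_series``, ``growth_series``); otherwise series are read from
    the CSV paths in the config.
    """
    report: dict = {"parameters": config.params(), "constructs": {}, "notes": []}
    entries = []
    if panel is not None:
        entries = panel
    else:
        names = sorted(set(config.binding_files) | set(config.growth_files))
        for name in names:
            entry = {"name": name}
            if name in config.binding_files:
                df = pd.read_csv(config.binding_files[name])
                entry["binding_series"] = SingleSiteBinding.from_dataframe(df).series
            if name in config.growth_files:
                df = pd.read_csv(config.growth_files[name])
                entry["growth_series"] = LogisticGrowth.from_dataframe(df).series
            entries.append(entry)
    if not entries:
        raise UbrecError("assay report needs at least one construct")

    for entry in entries:
        name = entry["name"]
        row: dict = {}
        if entry.get("binding_series") is not None:
            with _stage(f"binding:{name}"):
                fit = SingleSiteBinding(entry["binding_series"]).fit(
                    bootstrap=config.bootstrap, seed=config.seed)
            row.update(kd_uM=fit.kd, rmax_RU=fit.rmax, ka_per_uM=(1.0 / fit.kd if fit.kd else np.nan),
                       classification=fit.classification)
        if entry.get("growth_series") is not None:
            with _stage(f"growth:{name}"):
                gfit = LogisticGrowth(entry["growth_series"]).fit()
            row.update(K_AU=gfit.K, r_per_h=gfit.r, t50_h=gfit.t50, nsg=gfit.nsg)
            if not gfit.nsg:
                row["efficiency_AU_per_h2"] = growth_efficiency(gfit)
                row["efficiency_plateau_AU_per_h"] = gfit.efficiency_plateau
        report["constructs"][name] = row

    wt = report["constructs"].get(config.wild_type)
    usable = []
    for name, row in report["constructs"].items():
        if row.get("classification") == "no-binding":
            if config.nb_handling == "floor":
                row["ka_rel"] = config.nb_floor_ka
            else:
                report["notes"].append(f"{name}: no-binding, excluded from correlation")
                continue
        if row.get("nsg"):
            report["notes"].append(f"{name}: NSG, excluded from correlation")
            continue
        if "ka_per_uM" in row and "efficiency_AU_per_h2" in row:
            usable.append(name)
    if wt and "ka_per_uM" in wt and "efficiency_AU_per_h2" in wt:
        for name in usable:
            row = report["constructs"][name]
            row["ka_rel"] = row["ka_per_uM"] / wt["ka_per_uM"]
            row["efficiency_rel"] = row["efficiency_AU_per_h2"] / wt["efficiency_AU_per_h2"]
    if len(usable) >= 3:
        x = [report["constructs"][n].get("efficiency_rel",
                                         report["constructs"][n]["efficiency_AU_per_h2"])
             for n in usable]
        y = [report["constructs"][n].get("ka_rel", report["constructs"][n]["ka_per_uM"])
             for n in usable]
        with _stage("correlation"):
            corr = correlate(x, y)
        report["correlation"] = {"pearson_r": corr.r, "p_value": corr.p_value,
                                 "n": corr.n}
    elif len(entries) < 2:
        raise UbrecError("correlation needs at least 3 usable constructs; got "
                         f"{len(usable)}")
    else:
        report["notes"].append(
            f"correlation skipped: only {len(usable)} usable constructs")
    return report


def write_report(report: dict, out_dir, stem: str) -> Path:
    """Write the report as JSON plus a small Markdown digest; returns the
    JSON path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jpath = out / f"{stem}.json"
    jpath.write_text(json.dumps(report, indent=2, default=float))
    md = [f"# {stem}", ""]
    for key, val in report.items():
        md.append(f"## {key}")
        md.append("```json")
        md.append(json.dumps(val, indent=2, default=float))
        md.append("```")
    (out / f"{stem}.md").write_text("\n".join(md))
    return jpath
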