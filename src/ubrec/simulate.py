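"""Seeded synthetic-data generators.

Every structural, binding and growth stage of the pipeline can be exercised
on generated inputs whose ground truth is known exactly: toy two-chain
complexes with a planted rigid relation and a planted number of van der
Waals clashes, Langmuir binding series with Gaussian noise, and logistic
colony-growth image stacks with background.  Each generator uses one
``numpy.random.default_rng(seed)`` stream (PCG64) and returns a
machine-readable ground-truth dict alongside the data, so identical
parameters and seed give bit-identical output.

Scenario presets mirror the experimental panels: strong wild-type-like
growth, reduced mutant growth, NSG (no significant growth) spots, and a
non-binding mutant series.
"""

from __future__ import annotations

import numpy as np

from .assay import BindingSeries, logistic, single_site
from .errors import UbrecError
from .structure import Atom, Structure, SymOp, UnitCell

DEFAULT_VDW = 1.7  # toy atoms are carbon-like
CLASH_TOLERANCE = 0.4


def rotation_from_euler(ax: float, ay: float, az: float) -> np.ndarray:
    """Proper rotation from XYZ Euler angles (radians)."""
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _grid_coords(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """n points on a jittered cubic grid; spacing keeps them mutually clear
    of van der Waals contact."""
    side = int(np.ceil(n ** (1.0 / 3.0)))
    idx = np.stack(np.meshgrid(*[np.arange(side)] * 3, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = idx[:n] * spacing
    jitter = rng.uniform(-0.05 * spacing, 0.05 * spacing, size=pts.shape)
    return pts + jitter


def make_toy_complex(n_atoms_per_chain: int = 60, separation: float = 30.0,
                     planted_transform: np.ndarray | None = None,
                     planted_clash_count: int = 0, seed: int = 0,
                     tolerance: float = CLASH_TOLERANCE):
    """Two-chain toy structure with known rigid relation and clash count.

    Chain B is chain A under ``planted_transform`` (identity rotation when
    None) plus a translation of ``separation`` A along x.  When
    ``planted_clash_count`` k > 0, the first k chain-B atoms are repositioned
    into unique clash contacts (overlap tolerance + 0.3 A) with the first k
    chain-A atoms; the ground truth lists which B atoms still obey the
    planted transform.  A P1 unit cell enclosing everything with margin is
    attached for symmetry tests.

    Returns ``(Structure, truth)`` where truth carries the transform, the
    planted clash pairs and the rigid atom indices.
    """
    if n_atoms_per_chain <= 0 or separation <= 0:
        raise ValueError("n_atoms_per_chain and separation must be positive")
    if planted_clash_count < 0 or planted_clash_count > n_atoms_per_chain:
        raise UbrecError(
            f"cannot plant {planted_clash_count} clashes with {n_atoms_per_chain} atoms per chain")
    rng = np.random.default_rng(seed)
    spacing = 8.0  # wide enough that a planted B atom can clash with one A atom only
    R = np.eye(3) if planted_transform is None else np.asarray(planted_transform, float)
    t = np.array([separation + spacing * np.ceil(n_atoms_per_chain ** (1 / 3)), 0.0, 0.0])

    xa = _grid_coords(n_atoms_per_chain, spacing, rng)
    xb = xa @ R.T + t

    clash_pairs = []
    clash_dist = 2 * DEFAULT_VDW - tolerance - 0.3  # overlap = tolerance + 0.3
    for k in range(planted_clash_count):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        xb[k] = xa[k] + clash_dist * direction
        clash_pairs.append((k, k))
    rigid_indices = list(range(planted_clash_count, n_atoms_per_chain))

    atoms = []
    serial = 1
    for chain, coords in (("A", xa), ("B", xb)):
        for i, p in enumerate(coords):
            atoms.append(Atom(serial=serial, name="CA", element="C", resname="GLY",
                              resseq=i + 1, chain=chain, xyz=tuple(p)))
            serial += 1
    all_xyz = np.vstack([xa, xb])
    span = all_xyz.max(axis=0) - all_xyz.min(axis=0)
    cell = UnitCell(*(span + 40.0), 90.0, 90.0, 90.0)
    s = Structure(atoms, cell=cell, symops=[SymOp.identity()],
                  label="toy-complex", spacegroup="P 1")
    truth = {
        "rotation": R.tolist(),
        "translation": t.tolist(),
        "clash_pairs": clash_pairs,
        "clash_tolerance": tolerance,
        "rigid_b_indices": rigid_indices,
        "seed": seed,
    }
    return s, truth


def make_binding_series(kd: float = 270.0, rmax: float = 50.0,
                        concentrations=None, noise_cv: float = 0.05,
                        noise_floor: float = 0.0, seed: int = 0):
    """Langmuir single-site responses with multiplicative Gaussian noise.

    Default Kd is in the weak-affinity regime typical of Ub-binding domains
    (hundreds of micromolar).  Default concentrations: 8 points spanning
    0.1x to 3x Kd, log-spaced.  Noise is iid Gaussian per point with
    SD = noise_cv x the model response at that point (a stated coefficient
    of variation), plus an optional absolute acquisition-noise floor
    (``noise_floor``, RU) — the component that dominates when a construct
    does not bind.
    """
    if kd <= 0 or rmax <= 0:
        raise ValueError("kd and rmax must be positive")
    if concentrations is None:
        concentrations = np.geomspace(0.1 * kd, 3.0 * kd, 8)
    conc = np.asarray(concentrations, float)
    rng = np.random.default_rng(seed)
    clean = single_site(conc, kd, rmax)
    sd = noise_cv * clean + noise_floor
    noisy = clean + rng.normal(0.0, 1.0, size=conc.size) * sd \
        if np.any(sd > 0) else clean
    series = BindingSeries(tuple(conc), tuple(noisy))
    truth = {"kd": kd, "rmax": rmax, "noise_cv": noise_cv,
             "noise_floor": noise_floor, "seed": seed,
             "clean_responses": clean.tolist()}
    return series, truth


def make_growth_stack(spot_params, frame_times, image_shape=(120, 200),
                      spot_sigma: float = 3.0, background_level: float = 10.0,
                      noise_sd: float = 0.0, seed: int = 0, min_spot_sep: float = 30.0):
    """Time-lapse plate-scan stack with logistic-growth spots.

    ``spot_params`` is a list of dicts with keys ``center`` (row, col),
    ``K``, ``r``, ``t50``; each spot is a Gaussian blob whose integrated
    intensity follows its logistic curve over ``frame_times`` (hours).
    Frames carry a uniform ``background_level`` plus optional Gaussian pixel
    noise.  Spots closer than ``min_spot_sep`` pixels are rejected.

    Returns ``(stack, truth)``; truth includes each spot's exact per-frame
    integral before background/noise.
    """
    frame_times = np.asarray(frame_times, float)
    h, w = image_shape
    centers = [np.asarray(p["center"], float) for p in spot_params]
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) < min_spot_sep:
                raise UbrecError(f"spots {i} and {j} overlap (closer than {min_spot_sep} px)")
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:h, 0:w]
    stack = np.full((frame_times.size, h, w), float(background_level))
    truth_integrals = []
    for p, center in zip(spot_params, centers):
        blob = np.exp(-(((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                        / (2.0 * spot_sigma ** 2)))
        blob_sum = blob.sum()
        amp = logistic(frame_times, p["K"], p["r"], p["t50"]) if p["K"] > 0 \
            else np.zeros(frame_times.size)
        truth_integrals.append(amp.tolist())
        for f in range(frame_times.size):
            stack[f] += (amp[f] / blob_sum) * blob
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
    truth = {
        "frame_times": frame_times.tolist(),
        "spots": [dict(p, center=list(map(float, p["center"]))) for p in spot_params],
        "integrals": truth_integrals,
        "background_level": background_level,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return stack, truth


#: Scenario presets mirroring the experimental panels: (K, r, t50) for
#: growth and (Kd, Rmax) for binding.  "nsg" and "no_binding" are the
#: negative controls.
SCENARIOS = {
    "wild_type": {"growth": {"K": 2000.0, "r": 0.35, "t50": 24.0},
                  "binding": {"kd": 270.0, "rmax": 50.0}},
    "mutant_reduced": {"growth": {"K": 1200.0, "r": 0.25, "t50": 36.0},
                       "binding": {"kd": 800.0, "rmax": 45.0}},
    "nsg": {"growth": {"K": 0.0, "r": 0.0, "t50": 0.0},
            "binding": {"kd": 500.0, "rmax": 40.0}},
    "no_binding": {"growth": {"K": 0.0, "r": 0.0, "t50": 0.0},
                   "binding": {"kd": 1e6, "rmax": 0.0}},
}


def make_construct_panel(n_constructs: int = 6, seed: int = 0,
                         kd_range=(150.0, 1500.0), rmax: float = 50.0,
                         noise_cv: float = 0.05, n_replicates: int = 3,
                         times=None):
    """A panel of constructs with a planted monotone affinity-growth
    relation, emulating a wild-type-plus-mutants comparison.

    Construct i gets Kd_i log-spaced over ``kd_range`` (the first entry is
    the highest-affinity, "wild-type-like" construct) and a growth
    efficiency proportional to its association constant Ka = 1/Kd, realised
    by scaling the logistic plateau K.  Binding is measured in triplicate
    (``n_replicates``), matching standard SPR practice; replicate series are
    concatenated for a joint fit.  Returns a list of dicts with ``name``,
    ``binding_series``, ``binding_replicates``, ``growth_series`` plus the
    ground-truth panel table.
    """
    if times is None:
        times = np.arange(0.0, 72.0, 0.5)  # 30-min scan cadence over 3 days
    times = np.asarray(times, float)
    kds = np.geomspace(kd_range[0], kd_range[1], n_constructs)
    panel = []
    truth = []
    for i, kd in enumerate(kds):
        rng_seed = seed * 10007 + i
        reps = [make_binding_series(kd=kd, rmax=rmax, noise_cv=noise_cv,
                                    seed=rng_seed * 3 + k)[0]
                for k in range(n_replicates)]
        # replicate-mean responses at the shared concentration grid
        mean_resp = np.mean([r.resp for r in reps], axis=0)
        b_series = BindingSeries(reps[0].concentrations, tuple(mean_resp))
        # efficiency target proportional to Ka: scale plateau, keep r, t50
        ka_rel = (kd_range[0] / kd)
        K = 2000.0 * ka_rel
        r, t50 = 0.35, 24.0
        clean = logistic(times, K, r, t50)
        rng = np.random.default_rng(rng_seed + 1)
        noisy = clean + rng.normal(0.0, 0.02 * K, size=times.size)
        from .assay import GrowthSeries
        g_series = GrowthSeries(tuple(times), tuple(noisy), spot=f"c{i}")
        panel.append({"name": "wild_type" if i == 0 else f"mutant_{i}",
                      "binding_series": b_series, "binding_replicates": reps,
                      "growth_series": g_series})
        truth.append({"name": panel[-1]["name"], "kd": float(kd), "ka": 1.0 / float(kd),
                      "K": K, "r": r, "t50": t50,
                      "efficiency": (r * K / 4.0) / t50})
    return panel, truth
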