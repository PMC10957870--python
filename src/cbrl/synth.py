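"""Seeded generators emulating the study's data-generating structure.

Three generators cover every analysis surface without any external data:

* paired saline/muscimol behavioral datasets produced by the race model itself
  (a library of symbol pairs with heterogeneous acquisition difficulty, >=3
  repetitions per pair, ~30 overtrained + ~100 learning trials per session,
  injected abort trials at the reported rates);
* peripheral traces (gaze samples, binary lick trains, hand-movement amplitude
  scalars) whose distributions encode the study's null findings across
  conditions;
* charted-neuron point clouds on abstract flattened-map coordinates with
  configurable region mixing proportions and dense clusters concentrated in
  the pre-dorsal premotor cortex (PrePMd).

All outputs are deterministic functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model import ModelParams, simulate_session

__all__ = [
    "SymbolPairSpec",
    "GeneratorConfig",
    "ChartedCellConfig",
    "params_for_difficulty",
    "make_symbol_library",
    "generate_behavior_dataset",
    "generate_peripheral_traces",
    "generate_charted_cells",
    "DEFAULT_REGION_PROPORTIONS",
    "DEFAULT_REGION_GROUPS",
]


@dataclass(frozen=True)
class SymbolPairSpec:
    """One pair of novel symbols and its presentation design."""

    pair_id: str
    difficulty: float                       # in [0, 1]; harder pairs learn slower
    association: Dict[int, int] = field(default_factory=lambda: {0: 0, 1: 1})
    inverted: bool = False                  # symbol-hand association reversed
    repetitions: int = 3                    # presented at least three times
    error_correction: bool = False          # repeat same symbol after a wrong trial

    def __post_init__(self) -> None:
        if not (0.0 <= self.difficulty <= 1.0):
            raise ValueError("difficulty must lie in [0, 1]")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if set(self.association.values()) != {0, 1} or len(self.association) != 2:
            raise ValueError("association must be a bijection of two symbols onto two hands")


def params_for_difficulty(base: ModelParams, difficulty: float) -> ModelParams:
    """Map acquisition difficulty onto model parameters.

    Difficulty scales the learning rate multiplicatively (harder pairs learn
    slower) and shifts the initial drift linearly (harder pairs start with a
    smaller drift gap to the overtrained rate, i.e. poorer discriminability
    against the never-updated incorrect hand).
    """
    m = base.m * (1.4 - 0.8 * difficulty)
    v_init = base.v_init + 0.04 * (difficulty - 0.5)
    return base.replace(m=min(max(m, 1e-4), 1.0), v_init=v_init)


def make_symbol_library(
    n: int = 16,
    difficulty_range: Tuple[float, float] = (0.0, 1.0),
    seed: int = 0,
    repetitions: int = 3,
    error_correction: bool = False,
) -> List[SymbolPairSpec]:
    """A library of ``n`` symbol pairs with difficulties spread over the range.

    Difficulties are evenly spaced (deterministic); the seed drives the random
    symbol-hand association and inversion flags.
    """
    if n < 1:
        raise ValueError("library needs at least one pair")
    lo, hi = difficulty_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"empty or invalid difficulty range {difficulty_range}")
    rng = np.random.default_rng(seed)
    diffs = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2])
    specs = []
    for k, d in enumerate(diffs):
        inverted = bool(rng.random() < 0.5)
        assoc = {0: 1, 1: 0} if inverted else {0: 0, 1: 1}
        specs.append(SymbolPairSpec(
            pair_id=f"P{k + 1:02d}", difficulty=float(d), association=assoc,
            inverted=inverted, repetitions=repetitions,
            error_correction=error_correction))
    return specs


@dataclass
class GeneratorConfig:
    """Study conditions for the paired saline/muscimol behavioral generator."""

    n_pairs: int = 16
    repetitions: int = 3
    n_ot: int = 30                          # overtrained trials per session
    n_learn: int = 100                      # learning trials per session
    sessions_per_day: Tuple[int, int] = (3, 10)
    abort_rate_saline: float = 0.06         # bounded by the reported <7%
    abort_rate_muscimol: float = 0.08       # bounded by the reported <9%
    difficulty_range: Tuple[float, float] = (0.0, 1.0)
    error_correction: bool = False
    region: str = "posterior_lateral"
    saline_params: ModelParams = field(default_factory=ModelParams)
    muscimol_params: ModelParams = field(
        default_factory=lambda: ModelParams(muscimol=True))
    # peripheral-trace parameters (condition-independent by design: the study's
    # null findings on kinematics, licking and gaze)
    eye_sigma_deg: float = 3.0
    eye_samples_per_trial: int = 480        # 2 s at 240 Hz
    lick_samples_per_trial: int = 3000      # 3 s at 1000 Hz
    lick_baseline_p: float = 0.01
    lick_burst_p: float = 0.35
    lick_burst_ms: int = 400
    amplitude_mean: float = 10.0
    amplitude_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("abort_rate_saline", "abort_rate_muscimol",
                     "lick_baseline_p", "lick_burst_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_pairs", "repetitions", "n_ot", "n_learn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.muscimol_params.muscimol:
            raise ValueError("muscimol_params must have muscimol=True")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


TRIAL_TABLE_COLUMNS = [
    "day_id", "session_id", "condition", "region", "phase", "pair_id",
    "repetition_index", "trial_index", "symbol", "correct_action",
    "chosen_action", "outcome", "rt", "abort_reason",
]

_INJECTED_REASONS = ("both_hands", "pre_symbol", "late")


def _inject_aborts(session: pd.DataFrame, rate: float,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Insert abort rows at random positions at the configured rate.

    The model's own deadline aborts are kept; injected aborts emulate
    both-hands releases, pre-symbol releases and late responses, which the
    race model does not produce.  Trial indices are renumbered within phase.
    """
    session = session.copy()
    if "abort_reason" not in session.columns:
        session["abort_reason"] = pd.Series(pd.NA, index=session.index, dtype=object)
    out_frames = []
    for phase, block in session.groupby("phase", sort=False, observed=True):
        n = len(block)
        k = int(rng.binomial(n, rate / (1.0 - rate))) if rate > 0 else 0
        rows = block.to_dict("records")
        for _ in range(k):
            pos = int(rng.integers(0, len(rows) + 1))
            reason = _INJECTED_REASONS[int(rng.integers(0, 3))]
            rt = 2800.0 + float(rng.exponential(100.0)) if reason == "late" else np.nan
            rows.insert(pos, {
                "phase": phase, "trial_index": -1, "symbol": "",
                "correct_action": -1, "chosen_action": None,
                "outcome": "abort", "rt": rt, "abort_reason": reason,
            })
        blk = pd.DataFrame(rows)
        blk["trial_index"] = np.arange(1, len(blk) + 1)
        out_frames.append(blk)
    return pd.concat(out_frames, ignore_index=True)


def generate_behavior_dataset(config: GeneratorConfig):
    """Paired saline/muscimol sessions for every pair and repetition.

    Each (pair, repetition) produces one saline and one muscimol session for
    the *same* symbol pair, matching the study's same-symbols comparison.
    Sessions are grouped into experimental days of 3-10 sessions.  Returns the
    trial table and a manifest of seeds and parameters.
    """
    root = np.random.SeedSequence(config.seed)
    lib_seed, sched_seed, *rest = root.generate_state(2).tolist() + [None]
    library = make_symbol_library(
        config.n_pairs, config.difficulty_range, seed=lib_seed,
        repetitions=config.repetitions, error_correction=config.error_correction)

    session_keys = []
    for pair in library:
        for rep in range(1, pair.repetitions + 1):
            for cond in ("saline", "muscimol"):
                session_keys.append((pair, rep, cond))
    children = root.spawn(len(session_keys))

    frames = []
    manifest_sessions = []
    for (pair, rep, cond), child in zip(session_keys, children):
        rng = np.random.default_rng(child)
        base = config.saline_params if cond == "saline" else config.muscimol_params
        params = params_for_difficulty(base, pair.difficulty)
        sess = simulate_session(params, pair, config.n_ot, config.n_learn, rng)
        rate = (config.abort_rate_saline if cond == "saline"
                else config.abort_rate_muscimol)
        sess = _inject_aborts(sess, rate, rng)
        sess.loc[sess["abort_reason"].isna(), "abort_reason"] = np.where(
            sess.loc[sess["abort_reason"].isna(), "outcome"] == "abort",
            "late", "none")
        sess["condition"] = cond
        sess["region"] = config.region
        sess["pair_id"] = pair.pair_id
        sess["repetition_index"] = rep
        frames.append(sess)
        manifest_sessions.append({
            "pair_id": pair.pair_id, "repetition": rep, "condition": cond,
            "difficulty": pair.difficulty, "spawn_index": len(manifest_sessions),
        })

    table = pd.concat(frames, ignore_index=True)
    table = _assign_days(table, config, np.random.default_rng(sched_seed))
    table = table[TRIAL_TABLE_COLUMNS]
    manifest = {
        "seed": config.seed,
        "config": _config_manifest(config),
        "library": [dataclasses.asdict(p) for p in library],
        "sessions": manifest_sessions,
        "n_trials": int(len(table)),
    }
    return table, manifest


def _assign_days(table: pd.DataFrame, config: GeneratorConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Group sessions into experimental days of 3-10 sessions per condition.

    Saline and muscimol sessions fall on alternating days, as in the paired
    infusion design (never both on the same day).
    """
    lo, hi = config.sessions_per_day
    table = table.copy()
    table["day_id"] = ""
    table["session_id"] = 0
    for cond, tag in (("saline", "S"), ("muscimol", "M")):
        mask = table["condition"] == cond
        keys = table.loc[mask, ["pair_id", "repetition_index"]].drop_duplicates()
        keys = keys.sample(frac=1.0, random_state=rng.integers(0, 2**31))
        day, slot = 1, 0
        day_size = int(rng.integers(lo, hi + 1))
        for _, row in keys.iterrows():
            if slot >= day_size:
                day += 1
                slot = 0
                day_size = int(rng.integers(lo, hi + 1))
            sel = (mask & (table["pair_id"] == row["pair_id"])
                   & (table["repetition_index"] == row["repetition_index"]))
            table.loc[sel, "day_id"] = f"{tag}{day:02d}"
            table.loc[sel, "session_id"] = slot + 1
            slot += 1
    return table


def _config_manifest(config: GeneratorConfig) -> dict:
    d = config.to_dict()
    return d


# ---------------------------------------------------------------------------
# Peripheral traces
# ---------------------------------------------------------------------------

def generate_peripheral_traces(table: pd.DataFrame, config: GeneratorConfig,
                               seed: Optional[int] = None):
    """Gaze, lick and hand-amplitude signals for the trials of ``table``.

    Gaze positions are drawn from an isotropic 2D Gaussian with a
    condition-independent spread; lick trains are Bernoulli at a baseline rate
    with a reward-locked burst after correct responses; hand-movement
    amplitudes share one distribution across conditions (the study's null
    findings).  Long-format outputs keyed by a running trial id.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    non_abort = table[table["outcome"] != "abort"].reset_index(drop=True)
    eye_rows, lick_rows, amp_rows = [], [], []
    ns_eye, ns_lick = config.eye_samples_per_trial, config.lick_samples_per_trial
    for tid, row in non_abort.iterrows():
        xy = rng.normal(0.0, config.eye_sigma_deg, size=(ns_eye, 2))
        eye_rows.append(pd.DataFrame({
            "trial_id": tid, "sample_index": np.arange(ns_eye),
            "x_deg": xy[:, 0], "y_deg": xy[:, 1]}))
        p = np.full(ns_lick, config.lick_baseline_p)
        if row["outcome"] == "correct" and np.isfinite(row["rt"]):
            start = int(min(max(row["rt"], 0), ns_lick - 1))
            p[start:start + config.lick_burst_ms] = config.lick_burst_p
        lick_rows.append(pd.DataFrame({
            "trial_id": tid, "sample_index": np.arange(ns_lick),
            "value": (rng.random(ns_lick) < p).astype(int)}))
        amp_rows.append((tid, row["condition"] if "condition" in row else "all",
                         float(rng.normal(config.amplitude_mean, config.amplitude_sd))))
    return {
        "eye": pd.concat(eye_rows, ignore_index=True) if eye_rows else pd.DataFrame(),
        "lick": pd.concat(lick_rows, ignore_index=True) if lick_rows else pd.DataFrame(),
        "amplitude": pd.DataFrame(amp_rows,
                                  columns=["trial_id", "condition", "amplitude"]),
    }


# ---------------------------------------------------------------------------
# Charted-cell maps
# ---------------------------------------------------------------------------

#: region mixing proportions for the default (cerebral, layer-5) map; the
#: prefrontal group totals 0.63 with half of it in the PrePMd.
DEFAULT_REGION_PROPORTIONS: Dict[str, float] = {
    "PrePMd": 0.315, "area8": 0.110, "area9l": 0.030, "area10l": 0.030,
    "area46": 0.030, "area12_45": 0.060, "medial_prefrontal": 0.055,
    "parietal": 0.120, "cingulate": 0.070, "retrosplenial": 0.050,
    "insula": 0.060, "temporal": 0.040, "orbital": 0.010, "motor": 0.020,
}

DEFAULT_REGION_GROUPS: Dict[str, str] = {
    "PrePMd": "prefrontal", "area8": "prefrontal", "area9l": "prefrontal",
    "area10l": "prefrontal", "area46": "prefrontal", "area12_45": "prefrontal",
    "medial_prefrontal": "prefrontal",
    "parietal": "parietal_cingulate_retrosplenial",
    "cingulate": "parietal_cingulate_retrosplenial",
    "retrosplenial": "parietal_cingulate_retrosplenial",
    "insula": "insula_temporal", "temporal": "insula_temporal",
    "orbital": "orbital", "motor": "motor",
}


@dataclass
class ChartedCellConfig:
    """Spatial layout of a synthetic charted-neuron flattened map.

    Each region occupies its own rectangular territory.  Scattered label is a
    hard-core background (at most one cell per grid bin, so isolated charted
    cells never mimic a dense patch); the patch-bearing region carries an
    elevated diffuse density (paired cells per bin) plus dense Gaussian
    patches, with a couple of stray patches in other regions so that a small
    minority of the densest bins falls outside it, as in the real maps.
    """

    case_id: str = "SYN1"
    n_cells: int = 4889                     # charted-neuron count of the reference case
    cell_class: str = "layer5_neuron"
    proportions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_PROPORTIONS))
    cluster_region: str = "PrePMd"
    cluster_count: int = 24
    cluster_sigma_um: float = 120.0
    cluster_fraction: float = 0.55          # of the cluster region's cells
    stray_cluster_regions: tuple = ("area8", "parietal")
    stray_cluster_cells: int = 45           # per stray patch
    background_density: float = 0.5         # occupied fraction of scattered bins
    cluster_region_diffuse_per_bin: int = 2
    bin_um: float = 200.0
    gap_um: float = 2000.0                  # spacing between region territories

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region proportions must sum to 1, got {total}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if not (0.0 < self.background_density <= 1.0):
            raise ValueError("background_density is an occupancy fraction in (0, 1]")


def _scatter_hardcore(n_cells, per_bin, occupancy, bin_um, rng):
    """Place cells with at most ``per_bin`` cells per grid bin.

    The territory is sized so that ``occupancy`` of its bins hold cells;
    returns (x, y, side) with uniform jitter inside each chosen bin.
    """
    n_bins_used = int(np.ceil(n_cells / per_bin))
    side_bins = max(int(np.ceil(np.sqrt(n_bins_used / occupancy))), 3)
    chosen = rng.choice(side_bins * side_bins, size=n_bins_used, replace=False)
    bins = np.repeat(chosen, per_bin)[:n_cells]
    bx, by = bins // side_bins, bins % side_bins
    x = (bx + rng.random(n_cells)) * bin_um
    y = (by + rng.random(n_cells)) * bin_um
    return x, y, side_bins * bin_um


def generate_charted_cells(config: Optional[ChartedCellConfig] = None,
                           seed: int = 0) -> pd.DataFrame:
    """Synthetic charted-cell table (case_id, x_um, y_um, region, cell_class)."""
    cfg = config or ChartedCellConfig()
    rng = np.random.default_rng(seed)
    regions = sorted(cfg.proportions)
    probs = np.array([cfg.proportions[r] for r in regions])
    labels = rng.choice(len(regions), size=cfg.n_cells, p=probs)

    x = np.empty(cfg.n_cells)
    y = np.empty(cfg.n_cells)
    x_offset = 0.0
    for ri, region in enumerate(regions):
        idx = np.flatnonzero(labels == ri)
        n = idx.size
        if n == 0:
            continue
        is_patch_region = region == cfg.cluster_region
        n_cluster = 0
        n_patches = 0
        if cfg.cluster_count > 0:
            if is_patch_region:
                n_cluster = int(round(cfg.cluster_fraction * n))
                n_patches = cfg.cluster_count
            elif region in cfg.stray_cluster_regions:
                n_cluster = min(cfg.stray_cluster_cells, n // 2)
                n_patches = 1
        n_diffuse = n - n_cluster
        per_bin = cfg.cluster_region_diffuse_per_bin if is_patch_region else 1
        xs, ys, side = _scatter_hardcore(max(n_diffuse, 1), per_bin,
                                         cfg.background_density, cfg.bin_um, rng)
        xr = np.empty(n)
        yr = np.empty(n)
        xr[:n_diffuse] = xs[:n_diffuse]
        yr[:n_diffuse] = ys[:n_diffuse]
        if n_cluster > 0:
            centers = rng.uniform(0.15 * side, 0.85 * side, (n_patches, 2))
            which = rng.integers(0, n_patches, n_cluster)
            pts = centers[which] + rng.normal(0, cfg.cluster_sigma_um,
                                              (n_cluster, 2))
            xr[n_diffuse:] = np.clip(pts[:, 0], 0, side)
            yr[n_diffuse:] = np.clip(pts[:, 1], 0, side)
        x[idx] = xr + x_offset
        y[idx] = yr
        x_offset += side + cfg.gap_um

    # pin the extreme cells to their bin corners so that a grid anchored at
    # the minimum coordinate aligns with the map's charting lattice (all
    # territory offsets are multiples of the bin size)
    i = int(np.argmin(x))
    x[i] = np.floor(x[i] / cfg.bin_um) * cfg.bin_um
    j = int(np.argmin(y))
    y[j] = np.floor(y[j] / cfg.bin_um) * cfg.bin_um

    return pd.DataFrame({
        "case_id": cfg.case_id,
        "x_um": x,
        "y_um": y,
        "region": [regions[i] for i in labels],
        "cell_class": cfg.cell_class,
    })
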