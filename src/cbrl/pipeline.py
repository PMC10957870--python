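"""Pipeline orchestration: configuration, dataset I/O, analysis reports.

Ties the generator, the behavioral metrics and the density quantification into
reproducible stages.  Every stage derives its randomness from the single root
seed in the configuration and records a manifest sufficient to regenerate its
outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import anatomy, behavior, synth
from .model import ModelParams
from .synth import ChartedCellConfig, GeneratorConfig

__all__ = [
    "PipelineConfig",
    "read_trial_table",
    "run_simulate",
    "run_analyze",
    "run_anatomy",
    "run_calibrate",
]

log = logging.getLogger("cbrl")


@dataclass
class PipelineConfig:
    """Full resolved configuration of a pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    charted: ChartedCellConfig = field(default_factory=ChartedCellConfig)
    window: int = 10
    step: int = 5
    acquisition_threshold: float = 90.0
    levels: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    density_percentile: float = 90.0
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        # one root seed; stage seeds derive from it
        self.generator.seed = self.seed

    @classmethod
    def from_file(cls, path: Union[str, Path], seed: Optional[int] = None):
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
        return cls.from_dict(data, seed=seed)

    @classmethod
    def from_dict(cls, data: dict, seed: Optional[int] = None):
        gen = dict(data.get("generator", {}))
        for key in ("saline_params", "muscimol_params"):
            if key in gen:
                gen[key] = ModelParams(**gen[key])
        charted = ChartedCellConfig(**data.get("charted", {}))
        kwargs = {k: v for k, v in data.items() if k not in ("generator", "charted")}
        cfg = cls(generator=GeneratorConfig(**gen), charted=charted, **kwargs)
        if seed is not None:
            cfg.seed = seed
            cfg.generator.seed = seed
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        return d


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------

_ENUM_DOMAINS = {
    "condition": {"saline", "muscimol"},
    "region": {"posterior_lateral", "anterior"},
    "phase": {"overtrained", "learning"},
    "outcome": behavior.OUTCOMES,
    "abort_reason": behavior.ABORT_REASONS,
}


def read_trial_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a trial table CSV (fixed, documented column order)."""
    df = pd.read_csv(path)
    validate_trial_table(df)
    return df


def validate_trial_table(df: pd.DataFrame) -> None:
    missing = [c for c in synth.TRIAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise behavior.TrialTableError(f"missing columns: {missing}")
    for col, domain in _ENUM_DOMAINS.items():
        bad = ~df[col].isin(domain)
        if bad.any():
            raise behavior.TrialTableError(
                f"column {col!r} holds values outside {sorted(domain)} "
                f"at rows {list(df.index[bad])[:10]}",
                bad_rows=df[bad])
    non_abort = df["outcome"] != "abort"
    bad_rt = non_abort & (~np.isfinite(pd.to_numeric(df["rt"], errors="coerce"))
                          | (df["rt"] > behavior.MAX_RT_MS))
    if bad_rt.any():
        raise behavior.TrialTableError(
            f"non-abort rows with missing or >2800 ms RT at rows "
            f"{list(df.index[bad_rt])[:10]}", bad_rows=df[bad_rt])


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, ModelParams):
        return dataclasses.asdict(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig, out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Generate the behavioral dataset and write trials.csv + manifest.json."""
    out = Path(out_dir)
    if not out.exists():
        out.mkdir(parents=True)
        log.info("created output directory %s", out)
    table, manifest = synth.generate_behavior_dataset(config.generator)
    trials_path = out / "trials.csv"
    table.to_csv(trials_path, index=False, float_format="%.6f")
    manifest["pipeline_config"] = config.to_dict()
    manifest_path = out / "manifest.json"
    _write_json(manifest, manifest_path)
    log.info("simulated %d trials over %d sessions", len(table),
             table.groupby(["condition", "pair_id", "repetition_index"]).ngroups)
    return {"trials": trials_path, "manifest": manifest_path}


def run_analyze(config: PipelineConfig, dataset: Union[str, Path, pd.DataFrame],
                out_path: Optional[Union[str, Path]] = None) -> dict:
    """Execute the full behavioral analysis and emit one structured report."""
    if isinstance(dataset, (str, Path)):
        table = read_trial_table(dataset)
    else:
        table = dataset
        validate_trial_table(table)
    n_input = len(table)
    clean, abort_frac = behavior.filter_aborts(table)
    log.info("input rows %d, removed %d aborts", n_input, n_input - len(clean))

    report: dict = {
        "n_trials_input": n_input,
        "n_trials_analyzed": len(clean),
        "abort_fraction": {k: float(v) for k, v in abort_frac.items()},
    }

    conds = sorted(clean["condition"].unique())
    curves_out, acq_out, wsls_out, bias_out = {}, {}, {}, {}
    for cond in conds:
        sub = clean[clean["condition"] == cond]
        pair_curves, acq = {}, {}
        for pid, pdf in sub.groupby("pair_id", observed=True):
            curve = behavior._pair_average_curve(pdf[pdf["phase"] == "learning"],
                                                 window=config.window,
                                                 step=config.step)
            pair_curves[pid] = {
                "bin_start_trials": curve.bin_start_trials.tolist(),
                "percent_correct": np.round(curve.percent_correct, 4).tolist(),
                "n_sessions": curve.n_sessions_averaged,
            }
            a = behavior.acquisition_trial(curve, config.acquisition_threshold)
            acq[pid] = a if a is not None else "not_acquired"
        curves_out[cond] = pair_curves
        acq_out[cond] = acq
        # strategy metrics over sessions
        wsls_vals, bias_vals = [], []
        for _, sess in sub[sub["phase"] == "learning"].groupby(
                ["pair_id", "repetition_index"], observed=True):
            wsls_vals.append(float(behavior.wsls_fraction(sess).mean()))
            bias_vals.append(behavior.choice_bias(sess))
        wsls_out[cond] = {"mean": float(np.mean(wsls_vals)), "n_sessions": len(wsls_vals)}
        bias_out[cond] = {"mean": float(np.mean(bias_vals)), "n_sessions": len(bias_vals)}
    report["learning_curves"] = curves_out
    report["acquisition_trials"] = acq_out
    report["wsls"] = wsls_out
    report["choice_bias"] = bias_out

    # conditional performance needs both conditions
    if {"saline", "muscimol"} <= set(conds):
        res = behavior.conditional_performance(
            clean[clean["condition"] == "saline"],
            clean[clean["condition"] == "muscimol"],
            levels=config.levels)
        report["conditional_performance"] = [
            {"level": float(r.level), "muscimol_pc_mean": _nan_none(r.muscimol_pc_mean),
             "muscimol_pc_sem": _nan_none(r.muscimol_pc_sem),
             "saline_pc_mean": _nan_none(r.saline_pc_mean), "n_pairs": int(r.n_pairs)}
            for r in res.summary.itertuples()
        ]
    else:
        report["conditional_performance"] = "unavailable: need both conditions"

    # RT epochs and the gated within-condition L_beg vs L_end comparison
    epochs = behavior.rt_epoch_summary(clean)
    report["rt_epochs"] = epochs.set_index("condition").round(2).to_dict("index")
    rt_tests = {}
    for cond in conds:
        sub = clean[(clean["condition"] == cond) & (clean["phase"] == "learning")]
        beg, end = [], []
        for _, sess in sub.groupby(["pair_id", "repetition_index"], observed=True):
            b = sess.loc[sess["trial_index"] <= 20, "rt"]
            e = sess.loc[(sess["trial_index"] > 80) & (sess["trial_index"] <= 100), "rt"]
            if len(b) and len(e):
                beg.append(float(b.mean()))
                end.append(float(e.mean()))
        if len(beg) >= 4:
            rt_tests[cond] = behavior.gated_location_test(
                np.array(beg), np.array(end), paired=True)
        else:
            rt_tests[cond] = "unavailable: fewer than 4 paired sessions"
    report["rt_l_beg_vs_l_end"] = rt_tests

    if out_path is not None:
        _write_json(report, Path(out_path))
    return report


def _nan_none(v):
    v = float(v)
    return None if np.isnan(v) else v


def run_anatomy(config: PipelineConfig,
                cell_tables: Union[pd.DataFrame, Sequence[Union[str, Path, pd.DataFrame]]],
                out_path: Optional[Union[str, Path]] = None) -> dict:
    """Per-case density quantification plus a pooled multi-case summary."""
    if isinstance(cell_tables, pd.DataFrame):
        cell_tables = [cell_tables]
    frames = []
    for item in cell_tables:
        if isinstance(item, (str, Path)):
            df = pd.read_csv(item)
            if len(df) == 0:
                raise ValueError(f"empty charted-cell file: {item}")
        else:
            df = item
        for col in ("case_id", "x_um", "y_um", "region", "cell_class"):
            if col not in df.columns:
                raise ValueError(f"charted-cell table lacks column {col!r}")
        frames.append(df)
    cells = pd.concat(frames, ignore_index=True)

    report: dict = {"cases": {}, "pooled": {}}
    for case, cdf in cells.groupby("case_id", observed=True):
        bw, bh = anatomy.default_bin_size(cdf["cell_class"].iloc[0])
        grid = anatomy.bin_cells(cdf, bin_w=bw, bin_h=bh)
        dense, threshold = anatomy.dense_bins(grid, config.density_percentile)
        per_region, per_group = anatomy.region_composition(
            cdf, synth.DEFAULT_REGION_GROUPS)
        dfrac = anatomy.dense_fraction_in_region(
            grid, cdf, config.charted.cluster_region, config.density_percentile)
        report["cases"][str(case)] = {
            "n_cells": int(len(cdf)),
            "bin_size_um": [bw, bh],
            "n_occupied_bins": int(len(grid.bins)),
            "dense_threshold": threshold,
            "n_dense_bins": int(len(dense)),
            "region_percent": per_region.round(3).to_dict(),
            "group_percent": per_group.round(3).to_dict(),
            "dense_fraction_region": config.charted.cluster_region,
            "dense_fraction_percent": _nan_none(dfrac["percent"]),
        }
    per_region, per_group = anatomy.region_composition(
        cells, synth.DEFAULT_REGION_GROUPS)
    report["pooled"] = {
        "n_cells": int(len(cells)),
        "region_percent": per_region.round(3).to_dict(),
        "group_percent": per_group.round(3).to_dict(),
    }
    if out_path is not None:
        _write_json(report, Path(out_path))
    return report


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def run_calibrate(config: PipelineConfig, n_sessions: int = 300,
                  out_path: Optional[Union[str, Path]] = None) -> dict:
    """Re-derive the default model parameters from the printed behavioral bands.

    Searches the learning rate so that the mean acquisition trial of saline
    sessions sits at the center of the 50-70 band, and the muscimol noise mean
    so that the conditional performance at the 100% saline level lands on the
    ~65% read-out, holding everything else at the configured values.
    """
    from .model import simulate_learning_batch

    base = config.generator.saline_params
    rng_seed = config.seed + 101

    def mean_acquisition(m):
        p = base.replace(m=m)
        c, _, ab = simulate_learning_batch(p, n_sessions, config.generator.n_learn,
                                           np.random.default_rng(rng_seed))
        acqs = []
        for row, abr in zip(c, ab):
            keep = row[~abr]
            if keep.size >= config.window:
                curve = behavior.learning_curve(keep)
                a = behavior.acquisition_trial(curve, config.acquisition_threshold)
                if a is not None:
                    acqs.append(a)
        return float(np.mean(acqs)) if acqs else np.inf

    m_grid = np.geomspace(0.004, 0.04, 13)
    acq_vals = [mean_acquisition(m) for m in m_grid]
    m_best = float(m_grid[int(np.argmin(np.abs(np.array(acq_vals) - 60.0)))])

    mus = config.generator.muscimol_params
    def late_performance(noise_mu):
        p = mus.replace(noise_mu=noise_mu)
        c, _, ab = simulate_learning_batch(p, n_sessions, config.generator.n_learn,
                                           np.random.default_rng(rng_seed + 1))
        late = c[:, 55:90][~ab[:, 55:90]]
        return float(late.mean() * 100)

    mu_grid = np.linspace(0.04, 0.3, 14)
    late_vals = [late_performance(mu) for mu in mu_grid]
    mu_best = float(mu_grid[int(np.argmin(np.abs(np.array(late_vals) - 65.0)))])

    result = {
        "seed": config.seed,
        "m": m_best,
        "mean_acquisition_at_m": mean_acquisition(m_best),
        "noise_mu": mu_best,
        "late_muscimol_percent_at_noise_mu": late_performance(mu_best),
        "target_bands": {"acquisition_trials": [50, 70],
                         "muscimol_at_full_saline_learning_percent": 65.0},
    }
    if out_path is not None:
        _write_json(result, Path(out_path))
    return result
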