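"""Study-scale replication runs on the calibrated synthetic generator.

These routines regenerate the headline behavioral quantities at the study's
own problem sizes: the mean acquisition trial of saline learning sessions,
the muscimol conditional performance at the saline-defined levels, and the
pooled overtrained accuracy.  They pool several independently seeded
replicate datasets of the default symbol-pair library so that the Monte-Carlo
standard error of each pooled read-out is about one percentage point.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import behavior
from .model import ModelParams, simulate_overtrained_batch
from .synth import GeneratorConfig, generate_behavior_dataset

__all__ = ["paired_library_study", "overtrained_study"]


def paired_library_study(seed: int = 0, n_datasets: int = 6,
                         config: Optional[GeneratorConfig] = None) -> dict:
    """Paired saline/muscimol simulation of the default library, pooled.

    Generates ``n_datasets`` replicate datasets (16 pairs x 3 repetitions,
    paired conditions), computes per-session acquisition trials on the saline
    learning curves and the conditional performance of the muscimol sessions
    at every saline level, and pools at the per-pair level.
    """
    base = config or GeneratorConfig()
    children = np.random.SeedSequence(seed).generate_state(n_datasets)
    acq_trials = []
    n_sessions = 0
    per_level_values: dict = {}
    ot_correct = 0
    ot_total = 0
    for child in children:
        cfg = GeneratorConfig(**{**base.to_dict(),
                                 "saline_params": base.saline_params,
                                 "muscimol_params": base.muscimol_params,
                                 "seed": int(child % (2**31))})
        table, _ = generate_behavior_dataset(cfg)
        clean, _ = behavior.filter_aborts(table)
        sal = clean[clean["condition"] == "saline"]
        mus = clean[clean["condition"] == "muscimol"]

        learn = sal[sal["phase"] == "learning"]
        for _, sess in learn.groupby(["pair_id", "repetition_index"], observed=True):
            n_sessions += 1
            a = behavior.acquisition_trial(behavior.learning_curve(sess))
            if a is not None:
                acq_trials.append(a)

        res = behavior.conditional_performance(sal, mus)
        pp = res.per_pair
        for level in res.levels:
            vals = pp.loc[(pp["level"] == level) & pp["muscimol_pc"].notna(),
                          "muscimol_pc"]
            per_level_values.setdefault(level, []).extend(vals.tolist())

        ot = clean[clean["phase"] == "overtrained"]
        ot_correct += int((ot["outcome"] == "correct").sum())
        ot_total += int(len(ot))

    conditional = {
        level: {
            "mean": float(np.mean(vals)) if vals else float("nan"),
            "sem": (float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1 else float("nan")),
            "n_pair_groups": len(vals),
        }
        for level, vals in per_level_values.items()
    }
    return {
        "mean_acquisition_trial": float(np.mean(acq_trials)),
        "n_sessions": n_sessions,
        "n_acquired": len(acq_trials),
        "conditional": conditional,
        "overtrained_percent_correct": 100.0 * ot_correct / ot_total,
    }


def overtrained_study(seed: int = 0, n_blocks: int = 100, n_trials: int = 30,
                      params: Optional[ModelParams] = None) -> dict:
    """Pooled percent correct over simulated overtrained blocks."""
    p = params or ModelParams()
    rng = np.random.default_rng(seed)
    correct, _, aborted = simulate_overtrained_batch(p, n_blocks, n_trials, rng)
    keep = ~aborted
    return {
        "percent_correct": float(correct[keep].mean() * 100.0),
        "n_trials": int(keep.sum()),
        "n_blocks": n_blocks,
    }
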