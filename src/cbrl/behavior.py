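"""Behavioral analysis of visuomotor association learning sessions.

Implements the full analysis stack applied to trial tables: abort filtering,
sliding-window learning curves, acquisition and learned criteria, the
conditional-probability bracketing comparison between saline and muscimol
sessions, win-stay/lose-switch and choice-bias strategy metrics, learning-curve
distances, reaction-time epoch summaries, a normality-gated location test, and
peripheral-signal metrics (lick rate, radius of visual exploration).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "LearningCurve",
    "ConditionalLearningResult",
    "TrialTableError",
    "filter_aborts",
    "learning_curve",
    "average_curves",
    "acquisition_trial",
    "is_learned",
    "bracket_trials",
    "curve_value_at",
    "conditional_performance",
    "wsls_fraction",
    "curve_distance",
    "rt_epoch_summary",
    "choice_bias",
    "gated_location_test",
    "lick_rate",
    "exploration_radius",
    "ExplorationRadius",
]

MAX_RT_MS = 2800.0
OUTCOMES = {"correct", "wrong", "abort"}
ABORT_REASONS = {"both_hands", "pre_symbol", "late", "none"}

#: only the first 100 learning trials are analyzed; performance beyond that is
#: dominated by fatigue/motivation effects, not learning.
MAX_LEARNING_TRIALS = 100


class TrialTableError(ValueError):
    """Schema violation in a trial table, with row-level diagnostics."""

    def __init__(self, message: str, bad_rows: Optional[pd.DataFrame] = None):
        super().__init__(message)
        self.bad_rows = bad_rows


@dataclass
class LearningCurve:
    """Sliding-window percent-correct series (window 10 trials, step 5)."""

    bin_start_trials: np.ndarray
    percent_correct: np.ndarray
    window: int = 10
    step: int = 5
    n_sessions_averaged: int = 1

    def __post_init__(self) -> None:
        self.bin_start_trials = np.asarray(self.bin_start_trials, dtype=int)
        self.percent_correct = np.asarray(self.percent_correct, dtype=float)
        if self.bin_start_trials.shape != self.percent_correct.shape:
            raise ValueError("bin starts and values must align")
        if np.any((self.percent_correct < 0) | (self.percent_correct > 100)):
            raise ValueError("percent correct must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.bin_start_trials)

    @property
    def trial_span(self) -> float:
        return float(self.bin_start_trials[-1] - self.bin_start_trials[0])


@dataclass
class ConditionalLearningResult:
    """Muscimol performance evaluated at saline-defined performance levels."""

    levels: tuple
    per_pair: pd.DataFrame          # pair_id, level, bracket trials, values
    summary: pd.DataFrame           # level, mean, sem, n_pairs

    def value(self, level: float) -> float:
        row = self.summary[self.summary["level"] == level]
        return float(row["muscimol_pc_mean"].iloc[0]) if len(row) else math.nan


# ---------------------------------------------------------------------------
# Abort filtering
# ---------------------------------------------------------------------------

def filter_aborts(table: pd.DataFrame):
    """Remove abort trials; report the removed fraction per condition.

    A trial is an abort if it is labeled so (both-hands release, pre-symbol
    release, late response) or if its recorded RT exceeds the 2800 ms response
    deadline.  Malformed rows (unknown outcome label, missing RT on a response
    trial) raise :class:`TrialTableError` carrying the offending rows.
    """
    if len(table) == 0:
        return table.copy(), {}
    if "outcome" not in table.columns:
        raise TrialTableError("trial table lacks an 'outcome' column")
    bad = ~table["outcome"].isin(OUTCOMES)
    if "rt" in table.columns:
        bad |= (table["outcome"] != "abort") & ~np.isfinite(
            pd.to_numeric(table["rt"], errors="coerce"))
    if bad.any():
        raise TrialTableError(
            f"{int(bad.sum())} malformed trial rows "
            f"(indices {list(table.index[bad])[:10]}...)",
            bad_rows=table[bad],
        )
    is_abort = table["outcome"] == "abort"
    if "rt" in table.columns:
        is_abort |= table["rt"] > MAX_RT_MS
    clean = table[~is_abort].copy()
    if "condition" in table.columns:
        frac = is_abort.groupby(table["condition"], observed=True).mean().to_dict()
    else:
        frac = {"all": float(is_abort.mean())}
    return clean, frac


# ---------------------------------------------------------------------------
# Learning curves
# ---------------------------------------------------------------------------

def _correct_sequence(trials) -> np.ndarray:
    if isinstance(trials, pd.DataFrame):
        df = trials
        if "phase" in df.columns:
            df = df[df["phase"] == "learning"]
        if (df["outcome"] == "abort").any():
            raise ValueError("remove abort trials before computing curves")
        if "trial_index" in df.columns:
            df = df.sort_values("trial_index")
        return (df["outcome"] == "correct").to_numpy()
    return np.asarray(trials, dtype=bool)


def learning_curve(trials, window: int = 10, step: int = 5,
                   max_trials: int = MAX_LEARNING_TRIALS) -> LearningCurve:
    """Sliding-window percent correct for one session's learning block.

    Accepts a trial table (learning-phase rows, aborts removed) or a boolean
    correctness sequence.  Only the first ``max_trials`` trials are used.
    """
    c = _correct_sequence(trials)[:max_trials]
    if c.size < window:
        raise ValueError(f"need at least {window} trials, got {c.size}")
    starts = np.arange(1, c.size - window + 2, step)
    vals = np.array([c[s - 1:s - 1 + window].mean() * 100 for s in starts])
    return LearningCurve(starts, vals, window=window, step=step)


def average_curves(curves: Sequence[LearningCurve]) -> LearningCurve:
    """Pointwise mean over repeated sessions, truncated to the shortest support."""
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    w, s = curves[0].window, curves[0].step
    if any(c.window != w or c.step != s for c in curves):
        raise ValueError("curves have mixed window/step conventions")
    n = min(len(c) for c in curves)
    vals = np.mean([c.percent_correct[:n] for c in curves], axis=0)
    return LearningCurve(curves[0].bin_start_trials[:n], vals, window=w, step=s,
                         n_sessions_averaged=sum(c.n_sessions_averaged for c in curves))


def acquisition_trial(curve: LearningCurve, threshold: float = 90.0):
    """First bin whose value exceeds ``threshold``; reported as its start trial.

    Returns ``None`` when the performance never exceeds the threshold
    (association not acquired within the analyzed block).
    """
    above = curve.percent_correct > threshold
    if not above.any():
        return None
    return int(curve.bin_start_trials[int(np.argmax(above))])


def is_learned(curve: LearningCurve, threshold: float = 90.0,
               hold_threshold: float = 80.0, hold_trials: int = 20) -> bool:
    """Learned criterion: exceeds 90% and stays strictly above 80% for the
    bins covering the subsequent 20 trials."""
    acq = acquisition_trial(curve, threshold)
    if acq is None:
        return False
    hold = (curve.bin_start_trials > acq) & (curve.bin_start_trials <= acq + hold_trials)
    if not hold.any():
        return False
    return bool(np.all(curve.percent_correct[hold] > hold_threshold))


def curve_value_at(curve: LearningCurve, trials) -> np.ndarray:
    """Linear interpolation of the curve at (fractional) trial positions.

    Positions outside the bin-start support clamp to the end values.
    """
    return np.interp(np.asarray(trials, float),
                     curve.bin_start_trials.astype(float), curve.percent_correct)


def bracket_trials(curve: LearningCurve, p: float):
    """Three consecutive trials bracketing performance level ``p``.

    The curve is linearly interpolated to trial resolution over its bin-start
    support.  The bracket is centered on the first trial whose interpolated
    performance reaches ``100 p`` (the crossing trial with its two
    neighbors), so the triplet surrounds the crossing and its average tracks
    the level itself; when the level is already met at the first supported
    trial the bracket is that trial and its two successors.  Returns ``None``
    if the level is never reached.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"level p must be in (0, 1], got {p}")
    grid = np.arange(curve.bin_start_trials[0], curve.bin_start_trials[-1] + 1)
    vals = curve_value_at(curve, grid)
    hit = vals >= 100.0 * p
    if not hit.any():
        return None
    t = int(grid[int(np.argmax(hit))])
    t0 = max(t - 1, int(grid[0]))
    return (t0, t0 + 1, t0 + 2)


# ---------------------------------------------------------------------------
# Conditional performance (saline-bracketed muscimol read-out)
# ---------------------------------------------------------------------------

DEFAULT_LEVELS = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def _pair_average_curve(df: pd.DataFrame, window=10, step=5) -> LearningCurve:
    curves = []
    keys = [c for c in ("day_id", "session_id", "repetition_index") if c in df.columns]
    groups = df.groupby(keys, observed=True) if keys else [(None, df)]
    for _, sess in groups:
        curves.append(learning_curve(sess, window=window, step=step))
    return average_curves(curves)


def conditional_performance(
    saline: pd.DataFrame,
    muscimol: pd.DataFrame,
    levels: Iterable[float] = DEFAULT_LEVELS,
) -> ConditionalLearningResult:
    """Muscimol performance at the trials where saline performance reached p.

    For each symbol pair: average the saline learning curves over repetitions,
    find the three trials bracketing each level on that averaged curve, then
    read the pair's muscimol averaged curve at those same trials.  Aggregates
    across pairs as mean +/- s.e.m. per level.  Pairs present in only one
    condition are excluded with a warning.
    """
    levels = tuple(levels)
    sal_pairs = set(saline["pair_id"].unique())
    mus_pairs = set(muscimol["pair_id"].unique())
    common = sorted(sal_pairs & mus_pairs)
    skipped = (sal_pairs | mus_pairs) - set(common)
    if skipped:
        warnings.warn(f"pairs present in only one condition excluded: {sorted(skipped)}")
    if not common:
        raise ValueError("no symbol pair present in both conditions")

    rows = []
    for pid in common:
        sal_curve = _pair_average_curve(saline[saline["pair_id"] == pid])
        mus_curve = _pair_average_curve(muscimol[muscimol["pair_id"] == pid])
        for p in levels:
            trip = bracket_trials(sal_curve, p)
            if trip is None:
                rows.append((pid, p, None, math.nan, math.nan))
            else:
                mus_pc = float(np.mean(curve_value_at(mus_curve, trip)))
                sal_pc = float(np.mean(curve_value_at(sal_curve, trip)))
                rows.append((pid, p, trip, mus_pc, sal_pc))
    per_pair = pd.DataFrame(
        rows, columns=["pair_id", "level", "bracket", "muscimol_pc", "saline_pc"])

    summ = []
    for p in levels:
        sub = per_pair[(per_pair["level"] == p) & per_pair["muscimol_pc"].notna()]
        n = len(sub)
        mean = float(sub["muscimol_pc"].mean()) if n else math.nan
        sem = float(sub["muscimol_pc"].std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        summ.append((p, mean, sem, float(sub["saline_pc"].mean()) if n else math.nan, n))
    summary = pd.DataFrame(
        summ, columns=["level", "muscimol_pc_mean", "muscimol_pc_sem",
                       "saline_pc_mean", "n_pairs"])
    return ConditionalLearningResult(levels=levels, per_pair=per_pair, summary=summary)


# ---------------------------------------------------------------------------
# Strategy metrics
# ---------------------------------------------------------------------------

def wsls_fraction(trials: pd.DataFrame, window: int = 10, step: int = 5) -> pd.Series:
    """Windowed fraction of win-stay/lose-switch consistent trials.

    Trial t is WSLS-consistent iff the previous trial was rewarded and the
    same hand was chosen, or the previous trial was unrewarded and the other
    hand was chosen.  Defined on hands irrespective of symbol identity; the
    first trial has no predecessor and is excluded.
    """
    df = trials[trials["outcome"] != "abort"]
    if "trial_index" in df.columns:
        df = df.sort_values("trial_index")
    if len(df) < 2:
        raise ValueError("need at least two non-abort trials")
    chosen = df["chosen_action"].to_numpy()
    rewarded = (df["outcome"] == "correct").to_numpy()
    stay = chosen[1:] == chosen[:-1]
    consistent = np.where(rewarded[:-1], stay, ~stay)
    if consistent.size < window:
        starts = np.array([1])
        vals = np.array([consistent.mean()])
    else:
        starts = np.arange(1, consistent.size - window + 2, step)
        vals = np.array([consistent[s - 1:s - 1 + window].mean() for s in starts])
    return pd.Series(vals, index=pd.Index(starts, name="window_start"), name="wsls_fraction")


def choice_bias(trials: pd.DataFrame) -> float:
    """Hand-choice bias 2*|P(left) - 0.5|, in [0, 1]."""
    df = trials[trials["outcome"] != "abort"]
    if len(df) == 0:
        raise ValueError("need at least one non-abort trial")
    p_left = float((df["chosen_action"] == 0).mean())
    return 2.0 * abs(p_left - 0.5)


# ---------------------------------------------------------------------------
# Curve distance and RT epochs
# ---------------------------------------------------------------------------

def curve_distance(a: LearningCurve, b: LearningCurve) -> float:
    """Area between two curves over their common support, normalized by the
    shortest curve's trial span."""
    if a.window != b.window or a.step != b.step:
        raise ValueError("curves must share window/step conventions")
    n = min(len(a), len(b))
    if n < 2 or not np.array_equal(a.bin_start_trials[:n], b.bin_start_trials[:n]):
        raise ValueError("curves have no common trial support")
    x = a.bin_start_trials[:n].astype(float)
    diff = np.abs(a.percent_correct[:n] - b.percent_correct[:n])
    span = min(a.trial_span, b.trial_span)
    return float(np.trapezoid(diff, x) / span)


def rt_epoch_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean RT in the overtrained block, first 20 and last 20 learning trials.

    The learning epochs are taken within the analyzed 100-trial block; a
    missing epoch yields NaN.  One row per condition when the column exists.
    """
    if (table["outcome"] == "abort").any():
        raise ValueError("remove abort trials before RT summaries")
    groups = (table.groupby("condition", observed=True)
              if "condition" in table.columns else [("all", table)])
    rows = []
    for cond, df in groups:
        learn = df[df["phase"] == "learning"]
        ot = df.loc[df["phase"] == "overtrained", "rt"]
        beg = learn.loc[learn["trial_index"] <= 20, "rt"]
        end = learn.loc[(learn["trial_index"] > 80)
                        & (learn["trial_index"] <= MAX_LEARNING_TRIALS), "rt"]
        rows.append((cond,
                     float(ot.mean()) if len(ot) else math.nan,
                     float(beg.mean()) if len(beg) else math.nan,
                     float(end.mean()) if len(end) else math.nan))
    return pd.DataFrame(rows, columns=["condition", "rt_ot", "rt_l_beg", "rt_l_end"])


# ---------------------------------------------------------------------------
# Gated statistics
# ---------------------------------------------------------------------------

def gated_location_test(x, y, paired: bool = False, alpha: float = 0.05) -> dict:
    """Location test gated by a Lilliefors normality check.

    Normality is tested on the paired differences (paired) or on both samples
    (unpaired) at level ``alpha``; if not rejected the appropriate t-test is
    used, otherwise the Wilcoxon signed-rank / Mann-Whitney U alternative.
    All p-values are two-tailed.  Reports which branch fired.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 4:
        raise ValueError("Lilliefors requires at least 4 observations per sample")
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.ptp(d) == 0:
            # zero-variance differences: no location shift, branch-independent
            return {"test": "degenerate", "statistic": 0.0, "pvalue": 1.0,
                    "normal": True, "normality_pvalues": (1.0,)}
        _, p_norm = lilliefors(d, dist="norm")
        if p_norm >= alpha:
            stat, p = stats.ttest_rel(x, y)
            name = "paired t-test"
        else:
            stat, p = stats.wilcoxon(x, y)
            name = "Wilcoxon signed-rank"
        return {"test": name, "statistic": float(stat), "pvalue": float(p),
                "normal": bool(p_norm >= alpha), "normality_pvalues": (float(p_norm),)}
    p_norms = []
    for s in (x, y):
        if np.ptp(s) == 0:
            p_norms.append(0.0)  # constant sample: treat as non-normal
        else:
            p_norms.append(float(lilliefors(s, dist="norm")[1]))
    normal = all(p >= alpha for p in p_norms)
    if normal:
        stat, p = stats.ttest_ind(x, y)
        name = "two-sample t-test"
    else:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        name = "Mann-Whitney U"
    return {"test": name, "statistic": float(stat), "pvalue": float(p),
            "normal": normal, "normality_pvalues": tuple(p_norms)}


# ---------------------------------------------------------------------------
# Peripheral signals
# ---------------------------------------------------------------------------

def lick_rate(traces, sigma: float = 20.0) -> np.ndarray:
    """Trial-averaged lick rate smoothed with a unit-area Gaussian kernel.

    ``traces`` is (n_trials, n_samples) of binary contact at 1000 Hz; ``sigma``
    is the kernel width in samples.  Edges are handled by nearest-value
    extension so a constant input stays constant.
    """
    arr = np.atleast_2d(np.asarray(traces, dtype=float))
    mean = arr.mean(axis=0)
    return ndimage.gaussian_filter1d(mean, sigma=sigma, mode="nearest")


@dataclass(frozen=True)
class ExplorationRadius:
    r_exp: float            # degrees, FWHM of the fitted 2D Gaussian
    sigma_x: float
    sigma_y: float
    degenerate: bool = False


_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


def exploration_radius(samples, bin_width: float = 0.5,
                       min_samples: int = 500) -> ExplorationRadius:
    """Radius of visual exploration from overlaid gaze positions.

    Builds a 2D spatial density histogram (bin width matching the 0.5 deg
    tracker accuracy), fits a 2D Gaussian surface by least squares and returns
    the full-width-at-half-maximum; for anisotropic fits the geometric mean of
    the two axis FWHMs.  An all-identical sample set is flagged degenerate and
    bounded below by one bin width.
    """
    xy = np.asarray(samples, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("samples must be (n, 2) gaze positions")
    if xy.shape[0] < min_samples:
        raise ValueError(f"need at least {min_samples} gaze samples, got {xy.shape[0]}")
    if np.ptp(xy[:, 0]) == 0 and np.ptp(xy[:, 1]) == 0:
        return ExplorationRadius(r_exp=bin_width, sigma_x=0.0, sigma_y=0.0,
                                 degenerate=True)
    x, y = xy[:, 0], xy[:, 1]
    edges = [np.arange(v.min() - bin_width, v.max() + 2 * bin_width, bin_width)
             for v in (x, y)]
    hist, ex, ey = np.histogram2d(x, y, bins=edges)
    cx = 0.5 * (ex[:-1] + ex[1:])
    cy = 0.5 * (ey[:-1] + ey[1:])
    gx, gy = np.meshgrid(cx, cy, indexing="ij")

    def gauss2d(coords, amp, x0, y0, sx, sy):
        xx, yy = coords
        return amp * np.exp(-((xx - x0) ** 2 / (2 * sx**2)
                              + (yy - y0) ** 2 / (2 * sy**2)))

    p0 = (hist.max(), float(x.mean()), float(y.mean()),
          max(float(x.std()), bin_width / 2), max(float(y.std()), bin_width / 2))
    try:
        popt, _ = optimize.curve_fit(
            gauss2d, (gx.ravel(), gy.ravel()), hist.ravel(), p0=p0, maxfev=20000)
        sx, sy = abs(popt[3]), abs(popt[4])
    except RuntimeError:
        sx, sy = p0[3], p0[4]  # fall back to moment estimates
    r_exp = _FWHM * math.sqrt(sx * sy)
    if r_exp < bin_width:
        return ExplorationRadius(r_exp=bin_width, sigma_x=sx, sigma_y=sy,
                                 degenerate=True)
    return ExplorationRadius(r_exp=float(r_exp), sigma_x=float(sx),
                             sigma_y=float(sy))
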