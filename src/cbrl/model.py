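"""Drift-diffusion reinforcement-learning race model with a cerebellar error signal.

Action selection in the two-alternative symbol-to-hand task is modeled as a race
between two independent evidence accumulators, one per hand.  Each accumulator is
a Wiener process with unit diffusion coefficient and a single absorbing boundary,
so its first-passage time follows a Wald (inverse-Gaussian) distribution.  The
earlier passage determines the chosen hand and the reaction time; if neither
accumulator reaches the boundary before the response deadline the trial is an
abort.

Learning operates on the accumulation rates.  After every correct trial the
chosen hand's drift moves a fraction ``m`` of the way toward its overtrained
asymptote, driven by a cerebellar error signal

    delta_i(t) = r * (v_ot_i - v_i(t))            (correct trial, chosen hand)
    delta_i(t) = delta_i(t-1)                     (wrong trial, or unchosen hand)

and the drift update

    v_i(t+1) = v_i(t) + (m / r) * delta_i(t)      (correct trials, chosen hand only).

Under cerebellar inactivation (muscimol) the error signal is replaced by fresh
Gaussian noise on every trial; the update gating is unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd
from scipy import optimize

if TYPE_CHECKING:  # pragma: no cover
    from .synth import SymbolPairSpec

__all__ = [
    "ModelParams",
    "ModelState",
    "TrialOutcome",
    "WaldSpec",
    "FitResult",
    "wfpt_density",
    "wald_mean",
    "sample_wald",
    "simulate_race_trial",
    "compute_delta_cb",
    "update_drift",
    "simulate_session",
    "simulate_learning_batch",
    "simulate_overtrained_batch",
    "rt_decile_objective",
    "fit_model",
]

#: floor applied to drift rates; the Wald sampler requires strictly positive
#: drift (absorption is otherwise not certain), and the muscimol noise can
#: otherwise random-walk a rate below zero.
DRIFT_FLOOR = 1e-4


@dataclass
class ModelParams:
    """Parameters of the race model and its reinforcement-learning updates.

    Drift rates are in evidence units per ms with the diffusion coefficient
    fixed at 1 (standard identifiability convention).  Defaults are the
    calibrated saline values used by the synthetic generator: they yield
    >95% overtrained accuracy, ~500 ms overtrained RTs and acquisition of a
    novel association in 50-70 trials.
    """

    v_ot_correct: float = 0.4       # overtrained drift, correct hand
    v_ot_incorrect: float = 0.02    # overtrained drift, incorrect hand
    v_init: float = 0.12            # symmetric drift at learning onset
    m: float = 0.012                # learning rate, in (0, 1]
    r: float = 2.0                  # error-signal scale factor, > 0
    boundary: float = 100.0         # absorbing boundary height
    ndt: float = 250.0              # non-decision time, ms
    max_rt: float = 2800.0          # response deadline, ms
    muscimol: bool = False          # inactivation mode flag
    noise_mu: float = 0.14          # mean of the muscimol error-signal noise
    noise_sigma: float = 0.5        # s.d. of the muscimol error-signal noise
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.m <= 1.0):
            raise ValueError(f"learning rate m must be in (0, 1], got {self.m}")
        if self.r <= 0:
            raise ValueError(f"scale factor r must be positive, got {self.r}")
        if self.boundary <= 0:
            raise ValueError(f"boundary must be positive, got {self.boundary}")
        if self.ndt < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.ndt}")
        if self.max_rt <= self.ndt:
            raise ValueError("max_rt must exceed the non-decision time")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("v_ot_correct", "v_ot_incorrect", "v_init"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class ModelState:
    """Per-trial state of one symbol's pair of accumulators.

    ``v`` holds the drift rates for the two hands (index 0 = left, 1 = right);
    ``delta_prev`` the previous trial's error signal per hand.
    """

    v: np.ndarray
    delta_prev: np.ndarray = field(default_factory=lambda: np.zeros(2))
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.delta_prev = np.asarray(self.delta_prev, dtype=float)
        if self.v.shape != (2,) or self.delta_prev.shape != (2,):
            raise ValueError("ModelState holds exactly two actions")

    @classmethod
    def initial(cls, params: ModelParams) -> "ModelState":
        return cls(v=np.full(2, params.v_init))


@dataclass(frozen=True)
class TrialOutcome:
    """Outcome of one simulated race trial."""

    chosen: Optional[int]   # 0 = left, 1 = right, None on abort
    correct: bool
    rt: float               # ms from symbol onset; deadline value on abort
    aborted: bool

    def __post_init__(self) -> None:
        if self.aborted and self.chosen is not None:
            raise ValueError("aborted trials have no chosen action")
        if self.aborted and self.correct:
            raise ValueError("aborted trials cannot be correct")


@dataclass(frozen=True)
class WaldSpec:
    """Single-accumulator first-passage parameterization (drift, boundary, ndt)."""

    drift: float
    boundary: float
    ndt: float = 0.0

    def __post_init__(self) -> None:
        if self.boundary <= 0:
            raise ValueError(f"boundary must be positive, got {self.boundary}")
        if self.ndt < 0:
            raise ValueError(f"ndt must be >= 0, got {self.ndt}")


# ---------------------------------------------------------------------------
# First-passage density and sampling
# ---------------------------------------------------------------------------

def wfpt_density(t, spec: WaldSpec):
    """Wiener first-passage density at time ``t`` (ms) for one accumulator.

    With unit diffusion, drift ``v`` and boundary ``a`` the density of the
    passage time ``s = t - ndt`` is the Wald form

        f(s) = a / sqrt(2 pi s^3) * exp(-(a - v s)^2 / (2 s)).

    Returns 0 for ``t <= ndt``.  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    s = t - spec.ndt
    out = np.zeros_like(s)
    pos = s > 0
    sp = s[pos] if s.ndim else (s if pos else None)
    if s.ndim == 0:
        if not pos:
            return 0.0
        a, v = spec.boundary, spec.drift
        return float(a / math.sqrt(2 * math.pi * s**3) * math.exp(-((a - v * s) ** 2) / (2 * s)))
    a, v = spec.boundary, spec.drift
    out[pos] = a / np.sqrt(2 * np.pi * sp**3) * np.exp(-((a - v * sp) ** 2) / (2 * sp))
    return out


def wald_mean(spec: WaldSpec) -> float:
    """Mean response time boundary/drift + ndt (finite for positive drift)."""
    if spec.drift <= 0:
        return math.inf
    return spec.boundary / spec.drift + spec.ndt


def _wald_transform(mu, lam, y, u):
    """Michael-Schucany-Haas transformation: chi-square draw ``y`` and uniform
    ``u`` into an inverse-Gaussian(mean mu, shape lam) variate."""
    x = mu + mu * mu * y / (2.0 * lam) - mu / (2.0 * lam) * np.sqrt(
        4.0 * mu * lam * y + (mu * y) ** 2
    )
    return np.where(u <= mu / (mu + x), x, mu * mu / x)


def sample_wald(spec: WaldSpec, size, rng: np.random.Generator):
    """Exact first-passage-time samples (incl. ndt) via the MSH transformation."""
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if spec.drift <= 0:
        raise ValueError("sampling requires positive drift (certain absorption)")
    mu = spec.boundary / spec.drift
    lam = spec.boundary**2
    y = rng.standard_normal(size) ** 2
    u = rng.random(size)
    return _wald_transform(mu, lam, y, u) + spec.ndt


def _race_passages(v: np.ndarray, boundary: float, rng: np.random.Generator):
    """Vectorized passage times for an array of drift rates (no ndt)."""
    v = np.maximum(v, DRIFT_FLOOR)
    mu = boundary / v
    lam = boundary**2
    y = rng.standard_normal(v.shape) ** 2
    u = rng.random(v.shape)
    return _wald_transform(mu, lam, y, u)


# ---------------------------------------------------------------------------
# Single-trial dynamics
# ---------------------------------------------------------------------------

def simulate_race_trial(
    state: ModelState,
    params: ModelParams,
    correct_action: int,
    rng: np.random.Generator,
) -> TrialOutcome:
    """Race the two accumulators once; the earlier passage decides the trial.

    A trial whose winning passage (plus non-decision time) exceeds the
    response deadline is an abort, mirroring the behavioral late-release rule.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if not np.all(np.isfinite(state.v)):
        raise ValueError("drift rates must be finite")
    passages = _race_passages(state.v, params.boundary, rng)
    winner = int(np.argmin(passages))
    rt = float(passages[winner]) + params.ndt
    if rt > params.max_rt:
        return TrialOutcome(chosen=None, correct=False, rt=params.max_rt, aborted=True)
    return TrialOutcome(
        chosen=winner,
        correct=(winner == correct_action),
        rt=rt,
        aborted=False,
    )


def compute_delta_cb(
    state: ModelState,
    outcome: TrialOutcome,
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Per-hand cerebellar error signal for the current trial.

    Saline: the chosen hand on a correct trial receives a fresh teaching term
    r*(v_ot - v); every other hand/trial combination carries over the previous
    trial's signal unchanged.  Muscimol: both hands receive fresh draws from
    Normal(noise_mu, noise_sigma) and the carryover structure is bypassed.
    """
    if outcome.aborted:
        raise ValueError("aborted trials carry no error signal and are not analyzed")
    if params.muscimol:
        if rng is None:
            raise ValueError("muscimol mode draws noise and requires a Generator")
        return rng.normal(params.noise_mu, params.noise_sigma, size=2)
    delta = state.delta_prev.copy()
    if outcome.correct:
        i = outcome.chosen
        delta[i] = params.r * (params.v_ot_correct - state.v[i])
    return delta


def update_drift(
    state: ModelState,
    delta: np.ndarray,
    outcome: TrialOutcome,
    params: ModelParams,
) -> ModelState:
    """Apply the gated drift update: chosen hand, correct trials only."""
    v = state.v.copy()
    if outcome.correct:
        i = outcome.chosen
        v[i] = max(v[i] + (params.m / params.r) * delta[i], DRIFT_FLOOR)
    return ModelState(v=v, delta_prev=np.asarray(delta, float).copy(),
                      trial_index=state.trial_index + 1)


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "phase", "trial_index", "symbol", "correct_action", "chosen_action",
    "outcome", "rt",
]


def simulate_session(
    params: ModelParams,
    pair: "SymbolPairSpec",
    n_ot: int = 30,
    n_learn: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate one behavioral session: an overtrained block then a learning block.

    The overtrained block uses fixed drifts (v_ot_correct for the hand the
    symbol maps to, v_ot_incorrect for the other; no updates).  The learning
    block starts both hands at v_init for each of the pair's two symbols and
    applies the error-signal update after every non-abort trial.  Symbols are
    scheduled with equal probability, or with the error-correction rule
    (repeat the same symbol after a wrong trial) if the pair requests it.
    """
    if rng is None:
        if params.seed is None:
            raise ValueError("provide rng or set params.seed")
        rng = np.random.default_rng(params.seed)
    if n_ot <= 0 or n_learn <= 0:
        raise ValueError("n_ot and n_learn must be positive")
    association = dict(pair.association)
    if set(association.values()) != {0, 1} or len(association) != 2:
        raise ValueError(f"pair {pair.pair_id!r} association must map two symbols onto both hands")
    symbols = sorted(association)

    rows = []
    # -- overtrained block: constant drifts, green/pink square symbols 0 -> L, 1 -> R
    for t in range(1, n_ot + 1):
        sym = int(rng.integers(0, 2))
        v = np.empty(2)
        v[sym] = params.v_ot_correct
        v[1 - sym] = params.v_ot_incorrect
        out = simulate_race_trial(ModelState(v=v), params, sym, rng)
        rows.append(("overtrained", t, f"OT{sym}", sym, out.chosen,
                     _outcome_label(out), out.rt))

    # -- learning block: one accumulator-pair state per symbol
    states = {s: ModelState.initial(params) for s in symbols}
    prev_sym = None
    prev_wrong = False
    for t in range(1, n_learn + 1):
        if pair.error_correction and prev_wrong and prev_sym is not None:
            sym = prev_sym
        else:
            sym = symbols[int(rng.integers(0, 2))]
        c_act = association[sym]
        state = states[sym]
        out = simulate_race_trial(state, params, c_act, rng)
        if not out.aborted:
            delta = compute_delta_cb(state, out, params, rng)
            states[sym] = update_drift(state, delta, out, params)
        rows.append(("learning", t, str(sym), c_act, out.chosen,
                     _outcome_label(out), out.rt))
        prev_sym, prev_wrong = sym, (not out.correct and not out.aborted)

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _outcome_label(out: TrialOutcome) -> str:
    if out.aborted:
        return "abort"
    return "correct" if out.correct else "wrong"


# ---------------------------------------------------------------------------
# Vectorized many-session engines (used by fitting and calibration)
# ---------------------------------------------------------------------------

def simulate_learning_batch(
    params: ModelParams,
    n_sessions: int,
    n_trials: int,
    rng: np.random.Generator,
):
    """Simulate learning blocks for many sessions in lock-step.

    Returns ``(correct, rt, aborted)`` arrays of shape (n_sessions, n_trials).
    Uses the same per-trial dynamics as :func:`simulate_session` (equal-probability
    symbol schedule, no injected aborts; deadline aborts only).
    """
    v = np.full((n_sessions, 2, 2), params.v_init)  # [session, symbol, hand]
    correct = np.zeros((n_sessions, n_trials), dtype=bool)
    rt = np.zeros((n_sessions, n_trials))
    aborted = np.zeros((n_sessions, n_trials), dtype=bool)
    idx = np.arange(n_sessions)
    max_dec = params.max_rt - params.ndt
    for t in range(n_trials):
        sym = rng.integers(0, 2, n_sessions)
        c_act = sym  # identity association; relabeling is immaterial in aggregate
        drifts = v[idx[:, None], sym[:, None], np.arange(2)[None, :]]
        passages = _race_passages(drifts, params.boundary, rng)
        ch = np.argmin(passages, axis=1)
        win = passages[idx, ch]
        ab = win > max_dec
        ok = (ch == c_act) & ~ab
        correct[:, t] = ok
        rt[:, t] = np.where(ab, params.max_rt, win + params.ndt)
        aborted[:, t] = ab
        if params.muscimol:
            delta = rng.normal(params.noise_mu, params.noise_sigma, n_sessions)
        else:
            delta = params.r * (params.v_ot_correct - v[idx, sym, ch])
        upd = ok
        v[idx[upd], sym[upd], ch[upd]] = np.maximum(
            v[idx[upd], sym[upd], ch[upd]] + (params.m / params.r) * delta[upd],
            DRIFT_FLOOR,
        )
    return correct, rt, aborted


def simulate_overtrained_batch(
    params: ModelParams,
    n_sessions: int,
    n_trials: int,
    rng: np.random.Generator,
):
    """Simulate overtrained blocks (fixed drifts) for many sessions at once."""
    shape = (n_sessions, n_trials)
    tc = _race_passages(np.full(shape, params.v_ot_correct), params.boundary, rng)
    tw = _race_passages(np.full(shape, params.v_ot_incorrect), params.boundary, rng)
    win = np.minimum(tc, tw)
    aborted = win > params.max_rt - params.ndt
    correct = (tc < tw) & ~aborted
    rt = np.where(aborted, params.max_rt, win + params.ndt)
    return correct, rt, aborted


# ---------------------------------------------------------------------------
# Fitting to reaction-time distributions
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: ModelParams
    objective: float
    n_ot: int
    n_learn_beg: int
    seed: Optional[int] = None


_DECILES = np.arange(0.1, 1.0, 0.1)


def _simulated_race_deciles(vc, vw, params, y, u):
    """Deciles of the race-minimum RT under pre-drawn noise (common random numbers)."""
    lam = params.boundary**2
    tc = _wald_transform(params.boundary / max(vc, DRIFT_FLOOR), lam, y[0], u[0])
    tw = _wald_transform(params.boundary / max(vw, DRIFT_FLOOR), lam, y[1], u[1])
    rt = np.minimum(tc, tw) + params.ndt
    rt = rt[rt <= params.max_rt]
    if rt.size < 10:
        return None
    return np.quantile(rt, _DECILES)


def rt_decile_objective(
    rts: np.ndarray,
    v_correct: float,
    v_incorrect: float,
    params: Optional[ModelParams] = None,
    n_sim: int = 8000,
    seed: int = 0,
) -> float:
    """Sum of squared differences between empirical and simulated RT deciles.

    The simulated distribution is the race minimum of two Wald accumulators at
    the given drifts, generated under common random numbers so the objective
    is a deterministic function of the parameters.
    """
    params = params or ModelParams()
    rng = np.random.default_rng(seed)
    y = rng.standard_normal((2, n_sim)) ** 2
    u = rng.random((2, n_sim))
    emp = np.quantile(np.asarray(rts, float), _DECILES)
    sim = _simulated_race_deciles(v_correct, v_incorrect, params, y, u)
    return np.inf if sim is None else float(np.sum((sim - emp) ** 2))


def fit_model(
    trials: pd.DataFrame,
    base_params: Optional[ModelParams] = None,
    n_sim: int = 8000,
    n_restarts: int = 10,
    min_rts: int = 20,
    learn_beg_trials: int = 20,
    n_sim_sessions: int = 400,
    n_sweeps: int = 2,
    seed: int = 0,
) -> FitResult:
    """Estimate (v_ot_correct, v_init, m) from a table of non-abort trials.

    Stage 1 fits the overtrained drift by minimizing the sum of squared
    differences between empirical and simulated RT deciles of the overtrained
    block (derivative-free simplex with restarts, common random numbers).
    Stages 2 and 3 alternate: the initial drift is fitted to the deciles of
    the first ``learn_beg_trials`` learning-trial RTs simulated from the full
    learning process (so the early within-block drift growth is accounted
    for), then the learning rate is fitted by least squares between the
    empirical mean learning curve and the simulated one.  Boundary,
    non-decision time and the overtrained drift of the losing hand are taken
    from ``base_params`` (weakly identified from RT deciles and held fixed).
    """
    base = base_params or ModelParams()
    df = trials[trials["outcome"] != "abort"]
    ot_rts = df.loc[df["phase"] == "overtrained", "rt"].to_numpy(float)
    learn = df[df["phase"] == "learning"]
    beg_rts = learn.loc[learn["trial_index"] <= learn_beg_trials, "rt"].to_numpy(float)
    if ot_rts.size < min_rts or beg_rts.size < min_rts:
        raise ValueError(
            f"need at least {min_rts} usable RTs per block "
            f"(got {ot_rts.size} overtrained, {beg_rts.size} early-learning)"
        )

    rng = np.random.default_rng(seed)
    y = rng.standard_normal((2, n_sim)) ** 2
    u = rng.random((2, n_sim))
    emp_ot = np.quantile(ot_rts, _DECILES)
    emp_beg = np.quantile(beg_rts, _DECILES)
    emp_curve = _mean_learning_curve(learn)

    def obj_ot(log_vc):
        sim = _simulated_race_deciles(
            math.exp(log_vc[0]), base.v_ot_incorrect, base, y, u)
        return np.inf if sim is None else float(np.sum((sim - emp_ot) ** 2))

    vc_start = base.boundary / max(np.median(ot_rts) - base.ndt, 1.0)
    vc_hat = _restarted_simplex(obj_ot, math.log(vc_start), rng, n_restarts)
    obj_rt = obj_ot([math.log(vc_hat)])

    def beg_deciles(v0, mval):
        p = base.replace(v_ot_correct=vc_hat, v_init=v0,
                         m=min(max(mval, 1e-4), 1.0))
        _, rt, ab = simulate_learning_batch(
            p, n_sim_sessions, learn_beg_trials, np.random.default_rng(seed + 1))
        keep = rt[~ab]
        return np.quantile(keep, _DECILES) if keep.size >= 10 else None

    def obj_beg(log_v0, mval):
        sim = beg_deciles(math.exp(log_v0[0]), mval)
        return np.inf if sim is None else float(np.sum((sim - emp_beg) ** 2))

    def obj_m(mval, v0):
        if not (0.0 < mval <= 1.0):
            return np.inf
        p = base.replace(v_ot_correct=vc_hat, v_init=v0, m=mval)
        c, _, ab = simulate_learning_batch(
            p, n_sim_sessions, emp_curve["n_trials"],
            np.random.default_rng(seed + 2))
        sim_curve = _window_percent(c, ~ab, emp_curve["starts"])
        return float(np.sum((sim_curve - emp_curve["values"]) ** 2))

    v0_hat = base.boundary / max(np.median(beg_rts) - base.ndt, 1.0)
    m_hat = base.m
    for _ in range(n_sweeps):
        v0_hat = _restarted_simplex(
            lambda lv: obj_beg(lv, m_hat), math.log(v0_hat), rng, n_restarts)
        res = optimize.minimize_scalar(
            lambda mv: obj_m(mv, v0_hat), bounds=(1e-3, 0.5), method="bounded",
            options={"xatol": 1e-4})
        m_hat = float(res.x)

    return FitResult(
        params=base.replace(v_ot_correct=vc_hat, v_init=v0_hat, m=m_hat),
        objective=obj_rt + obj_beg([math.log(v0_hat)], m_hat) + float(res.fun),
        n_ot=int(ot_rts.size),
        n_learn_beg=int(beg_rts.size),
        seed=seed,
    )


def _restarted_simplex(obj, log_start, rng, n_restarts):
    best_x, best_f = None, np.inf
    for k in range(n_restarts):
        x0 = log_start + (0.0 if k == 0 else rng.normal(0, 0.4))
        res = optimize.minimize(obj, [x0], method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-8})
        if res.fun < best_f:
            best_x, best_f = float(res.x[0]), float(res.fun)
    return math.exp(best_x)


def _iter_sessions(learn: pd.DataFrame):
    keys = [c for c in ("day_id", "session_id", "pair_id", "repetition_index", "condition")
            if c in learn.columns]
    if not keys:
        yield None, learn
    else:
        yield from learn.groupby(keys, observed=True)


def _window_percent(correct, usable, starts, window=10):
    """Percent correct over usable trials per sliding window, averaged over sessions."""
    vals = np.empty(len(starts))
    for i, s in enumerate(starts):
        c = correct[:, s - 1:s - 1 + window]
        n = usable[:, s - 1:s - 1 + window]
        with np.errstate(invalid="ignore"):
            per = np.where(n.sum(1) > 0, c.sum(1) / np.maximum(n.sum(1), 1) * 100, np.nan)
        vals[i] = np.nanmean(per)
    return vals


def _mean_learning_curve(learn: pd.DataFrame, window=10, step=5, max_trials=100):
    """Empirical mean sliding-window curve across sessions, on the common support."""
    per_session = []
    n_min = max_trials
    for _, sess in _iter_sessions(learn):
        c = (sess.sort_values("trial_index")["outcome"] == "correct").to_numpy()
        c = c[:max_trials]
        if c.size >= window:
            per_session.append(c)
            n_min = min(n_min, c.size)
    if not per_session:
        raise ValueError("no session with enough learning trials")
    starts = np.arange(1, n_min - window + 2, step)
    curves = np.stack([
        [c[s - 1:s - 1 + window].mean() * 100 for s in starts] for c in per_session
    ])
    return {"starts": starts, "values": curves.mean(0), "n_trials": int(n_min)}
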