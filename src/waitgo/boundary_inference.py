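"""Recovering decision boundaries from trial records.

The pipeline mirrors how an experimenter would treat real data:

1. estimate the nondecision lag from the response-locked cue/response
   correlation and strip those cues from every trial;
2. expand each trial into per-stimulus (T, X, A) triplets — the running
   time and evidence at every opportunity to act, with A = wait for every
   intermediate state and A = go at the decision state;
3. fit the wait/go logistic regression
   ``logit P(go) = beta0 + betaT * T + betaX * X``;
4. convert the fit into a *line of indifference* (where wait and go are
   equally likely), whose slope in degrees proxies the boundary slope;
5. compare conditions through the circular slope difference, with
   percentile-bootstrap confidence intervals, and screen participants
   with an exact binomial test against chance accuracy.

Evidence in the triplets is aligned with the trial's final response
(``X = x * sign(response)``), so that boundary crossings sit at positive
X for both response directions and the two symmetric boundaries collapse
onto one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "WAITGO_COLUMNS",
    "LogisticFit",
    "SlopeEstimate",
    "NondecisionEstimate",
    "ExclusionResult",
    "estimate_nondecision",
    "strip_nondecision",
    "build_wait_go_table",
    "fit_waitgo_logistic",
    "line_of_indifference",
    "circular_slope_difference",
    "bootstrap_slope_ci",
    "binomial_exclusion_test",
]

WAITGO_COLUMNS = ["participant", "trial", "T", "X", "A"]  # A: 1 = go, 0 = wait

_BETA_X_TOL = 1e-8
_RIDGE = 1e-4  # weak penalty on betaT, betaX used only on separable data


@dataclass(frozen=True)
class NondecisionEstimate:
    """Result of the response-locked nondecision-lag estimate."""

    p_series: np.ndarray  # p_t for t = 1 ... max_lag (reversed stimulus index)
    nd: int
    threshold: float
    saturated: bool = False  # no index exceeded the threshold within max_lag


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood wait/go logistic coefficients."""

    beta0: float
    betaT: float
    betaX: float
    log_likelihood: float
    n_obs: int
    converged: bool
    penalized: bool = False  # ridge fallback used (separable data)
    include_time: bool = True


@dataclass(frozen=True)
class SlopeEstimate:
    """Line of indifference of a wait/go fit."""

    gradient: float  # evidence units per ISI unit
    intercept: float  # evidence units at T = 0
    slope_deg: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    time_dominated: bool = False  # |betaX| ~ 0: boundary is a deadline


@dataclass(frozen=True)
class ExclusionResult:
    """Exact binomial screen of accuracy against chance."""

    n_trials: int
    n_correct: int
    p_value: float
    alpha: float
    excluded: bool  # True when accuracy is indistinguishable from chance


def _cues_array(cue_string: str) -> np.ndarray:
    # '+' -> +1, '-' -> -1
    a = np.frombuffer(cue_string.encode(), dtype=np.uint8)
    return np.where(a == ord("+"), 1, -1)


def estimate_nondecision(
    trials: pd.DataFrame,
    threshold: float = 0.75,
    max_lag: int = 10,
    min_trials: int = 20,
) -> NondecisionEstimate:
    """Estimate the nondecision lag in cue counts.

    Cue sequences are reversed and aligned on the response; ``p_t`` is the
    fraction of trials (among those with at least ``t`` cues) whose cue at
    reversed index ``t`` points in the response direction.  Cues inside
    the nondecision window are uncorrelated with the response, so the lag
    is one less than the first index where ``p_t`` exceeds ``threshold``.
    If no index within ``max_lag`` exceeds it, ``nd = max_lag`` is
    returned with a saturation flag.
    """
    usable = trials[trials["decision_t"] >= 1]
    if len(usable) < min_trials:
        raise ValueError(
            f"need at least {min_trials} trials with one or more cues "
            f"to estimate the nondecision lag (got {len(usable)})"
        )
    hits = np.zeros(max_lag)
    counts = np.zeros(max_lag)
    for cues, response in zip(usable["cues"], usable["response"]):
        arr = _cues_array(cues)[::-1]
        sign = 1 if response == "up" else -1
        upto = min(max_lag, len(arr))
        hits[:upto] += arr[:upto] == sign
        counts[:upto] += 1
    with np.errstate(invalid="ignore"):
        p_series = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    above = np.nonzero(p_series > threshold)[0]
    if above.size:
        return NondecisionEstimate(
            p_series=p_series, nd=int(above[0]), threshold=threshold
        )
    warnings.warn(
        f"no reversed stimulus index exceeded p > {threshold} within "
        f"max_lag={max_lag}; nondecision estimate saturated",
        stacklevel=2,
    )
    return NondecisionEstimate(
        p_series=p_series, nd=max_lag, threshold=threshold, saturated=True
    )


def strip_nondecision(trials: pd.DataFrame, nd: int) -> tuple[pd.DataFrame, int]:
    """Remove the last ``nd`` cues from every trial.

    The decision state is thereby recomputed at ``decision_t - nd``.
    Trials too short to survive the strip are dropped; the drop count is
    returned alongside the stripped table.  ``nd = 0`` is the identity.
    """
    if nd < 0:
        raise ValueError("nd must be nonnegative")
    if nd == 0:
        return trials.copy(), 0
    keep = trials["decision_t"] > nd
    dropped = int((~keep).sum())
    out = trials[keep].copy()
    out["cues"] = out["cues"].str[:-nd]
    out["decision_t"] = out["decision_t"] - nd
    return out, dropped


def build_wait_go_table(
    trials: pd.DataFrame,
    condition: str | None = None,
    keep_difficulty: float | None = None,
) -> pd.DataFrame:
    """Per-stimulus (T, X, A) triplets from (stripped) trials.

    Each trial contributes a wait row at every intermediate state
    ``t = 1 ... decision_t - 1`` and exactly one go row at its final
    state; an immediate guess contributes a lone ``(0, 0, go)`` row.
    Evidence is aligned with the trial's response.  ``keep_difficulty``
    restricts mixed-condition trials to one generating drift (the
    like-for-like comparison against a single-difficulty game).
    """
    df = trials
    if condition is not None:
        df = df[df["condition"] == condition]
    if keep_difficulty is not None:
        df = df[np.isclose(df["difficulty"], keep_difficulty)]
    part = df["participant"] if "participant" in df.columns else pd.Series(0, index=df.index)
    rows_t: list[np.ndarray] = []
    rows_x: list[np.ndarray] = []
    rows_a: list[np.ndarray] = []
    rows_p: list[np.ndarray] = []
    rows_id: list[np.ndarray] = []
    for idx, (p, cues, response) in enumerate(
        zip(part, df["cues"], df["response"])
    ):
        sign = 1 if response == "up" else -1
        arr = _cues_array(cues)
        L = len(arr)
        if L == 0:
            t = np.array([0])
            x = np.array([0])
        else:
            t = np.arange(1, L + 1)
            x = np.cumsum(arr) * sign
        a = np.zeros(len(t), dtype=int)
        a[-1] = 1
        rows_t.append(t)
        rows_x.append(x)
        rows_a.append(a)
        rows_p.append(np.full(len(t), p))
        rows_id.append(np.full(len(t), idx))
    if not rows_t:
        return pd.DataFrame(columns=WAITGO_COLUMNS)
    return pd.DataFrame(
        {
            "participant": np.concatenate(rows_p),
            "trial": np.concatenate(rows_id),
            "T": np.concatenate(rows_t),
            "X": np.concatenate(rows_x),
            "A": np.concatenate(rows_a),
        }
    )


def _penalized_fit(
    y: np.ndarray, design: np.ndarray, ridge: float
) -> tuple[np.ndarray, float, bool]:
    """Ridge-penalized logistic MLE (penalty on non-intercept terms only)."""
    pen = np.full(design.shape[1], ridge)
    pen[0] = 0.0

    def nll(beta: np.ndarray) -> float:
        z = design @ beta
        # log(1 + exp(z)) - y*z, numerically stable
        ll = y * z - np.logaddexp(0.0, z)
        return -ll.sum() + 0.5 * float(pen @ beta**2)

    def grad(beta: np.ndarray) -> np.ndarray:
        z = design @ beta
        return design.T @ (expit(z) - y) + pen * beta

    res = optimize.minimize(
        nll, np.zeros(design.shape[1]), jac=grad, method="L-BFGS-B"
    )
    beta = res.x
    z = design @ beta
    loglik = float((y * z - np.logaddexp(0.0, z)).sum())
    return beta, loglik, bool(res.success)


def fit_waitgo_logistic(
    table: pd.DataFrame,
    include_time: bool = True,
    ridge: float = _RIDGE,
) -> LogisticFit:
    """Maximum-likelihood fit of the wait/go logistic regression.

    When ``include_time`` is false, the time coefficient is fixed at zero
    (the fixed-boundary model).  Perfectly separable tables (noiseless
    agents) have no finite MLE; those fall back to a weakly
    ridge-penalized fit on the slope coefficients and are flagged.
    """
    if len(table) == 0:
        raise ValueError("empty wait/go table")
    y = table["A"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("wait/go table contains a single action; cannot fit")
    if include_time:
        design = np.column_stack(
            [np.ones(len(table)), table["T"].to_numpy(float), table["X"].to_numpy(float)]
        )
    else:
        design = np.column_stack([np.ones(len(table)), table["X"].to_numpy(float)])

    params = None
    loglik = None
    converged = False
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            params = np.asarray(res.params)
            loglik = float(res.llf)
        except Exception:
            params = None
    # separation shows up as an exception, non-convergence or exploding betas
    if params is None or not converged or not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e3:
        params, loglik, converged = _penalized_fit(y, design, ridge)
        penalized = True

    if include_time:
        beta0, beta_t, beta_x = params
    else:
        beta0, beta_x = params
        beta_t = 0.0
    return LogisticFit(
        beta0=float(beta0),
        betaT=float(beta_t),
        betaX=float(beta_x),
        log_likelihood=float(loglik),
        n_obs=len(table),
        converged=converged,
        penalized=penalized,
        include_time=include_time,
    )


def line_of_indifference(fit: LogisticFit, betax_tol: float = _BETA_X_TOL) -> SlopeEstimate:
    """Locus where wait and go are equally likely:
    ``X = -(betaT/betaX) * T - beta0/betaX``.

    When ``|betaX|`` is negligible the boundary is a pure deadline; the
    slope is then saturated just inside +/-90 degrees and flagged as
    time-dominated.
    """
    if abs(fit.betaX) < betax_tol:
        slope_deg = -np.sign(fit.betaT) * (90.0 - 1e-6)
        if fit.betaT == 0.0:
            slope_deg = 0.0
        return SlopeEstimate(
            gradient=float(np.tan(np.radians(slope_deg))),
            intercept=np.nan,
            slope_deg=float(slope_deg),
            time_dominated=True,
        )
    gradient = -fit.betaT / fit.betaX
    intercept = -fit.beta0 / fit.betaX
    return SlopeEstimate(
        gradient=float(gradient),
        intercept=float(intercept),
        slope_deg=float(np.degrees(np.arctan(gradient))),
    )


def circular_slope_difference(m_e: float, m_m: float) -> float:
    """Circular difference of two slopes in degrees, wrapped into [-90, 90).

    Steeply increasing and steeply decreasing boundaries both indicate a
    time-based (rather than evidence-based) boundary, so their slopes are
    treated as close: ``delta = ((m_e - m_m + 90) mod 180) - 90``.
    """
    return float(((m_e - m_m + 90.0) % 180.0) - 90.0)


def estimate_slope(
    trials: pd.DataFrame,
    condition: str | None = None,
    keep_difficulty: float | None = None,
    include_time: bool = True,
) -> SlopeEstimate:
    """Convenience: table -> fit -> line of indifference."""
    table = build_wait_go_table(trials, condition=condition, keep_difficulty=keep_difficulty)
    fit = fit_waitgo_logistic(table, include_time=include_time)
    return line_of_indifference(fit)


def bootstrap_slope_ci(
    trials: pd.DataFrame,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    condition: str | None = None,
    keep_difficulty: float | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the indifference slope (degrees).

    Whole trials are the resampling unit.  Replicates whose fit fails are
    dropped; more than half failing raises.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    df = trials
    if condition is not None:
        df = df[df["condition"] == condition]
    if keep_difficulty is not None:
        df = df[np.isclose(df["difficulty"], keep_difficulty)]
    if len(df) < 2:
        raise ValueError("need at least 2 trials to bootstrap")
    rng = np.random.default_rng() if rng is None else rng
    slopes = []
    failed = 0
    for _ in range(n_boot):
        sample = df.iloc[rng.integers(0, len(df), size=len(df))]
        try:
            table = build_wait_go_table(sample)
            fit = fit_waitgo_logistic(table)
            slopes.append(line_of_indifference(fit).slope_deg)
        except ValueError:
            failed += 1
    if failed > n_boot / 2:
        raise RuntimeError(
            f"{failed}/{n_boot} bootstrap replicates failed to fit"
        )
    lo, hi = np.percentile(slopes, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(lo), float(hi)


def binomial_exclusion_test(trials: pd.DataFrame, alpha: float = 0.05) -> ExclusionResult:
    """Two-sided exact binomial test of accuracy against chance.

    A participant is *excluded* when the test fails to reject chance at
    ``alpha`` — their responses are indistinguishable from guessing.
    """
    n = len(trials)
    if n < 1:
        raise ValueError("need at least one trial")
    k = int(trials["correct"].sum())
    p = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
    return ExclusionResult(
        n_trials=n, n_correct=k, p_value=float(p), alpha=alpha, excluded=p >= alpha
    )
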