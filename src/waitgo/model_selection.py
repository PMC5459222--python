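"""BIC comparison of fixed versus time-varying boundary models.

The time-varying model is the wait/go logistic regression with both time
and evidence as predictors; the fixed-boundary model drops the time
term.  Models are compared by the Bayesian Information Criterion
``BIC = k ln(n) - 2 log L`` with n the number of per-stimulus wait/go
observations, and summarized as a posterior model probability under
equal model priors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .boundary_inference import fit_waitgo_logistic

__all__ = ["ModelComparison", "bic", "compare_boundary_models"]

#: |delta BIC| below this counts as ambiguous evidence
DEFAULT_MARGIN = 2.0


@dataclass(frozen=True)
class ModelComparison:
    bic_fixed: float
    bic_varying: float
    delta_bic: float  # bic_fixed - bic_varying; positive favors the varying model
    post_prob_varying: float
    winner: str  # "fixed" | "varying" | "ambiguous"


def bic(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, ``k ln(n) - 2 log L``."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if k < 0:
        raise ValueError("k must be nonnegative")
    return k * float(np.log(n)) - 2.0 * log_likelihood


def compare_boundary_models(
    table: pd.DataFrame,
    margin: float = DEFAULT_MARGIN,
    n_obs: str = "rows",
) -> ModelComparison:
    """Fit both boundary models to a wait/go table and compare by BIC.

    ``n_obs`` selects the observation count entering the BIC penalty:
    ``"rows"`` counts every per-stimulus wait/go opportunity (default),
    ``"trials"`` counts decisions (one go row each) for sensitivity
    analysis.
    """
    fit_var = fit_waitgo_logistic(table, include_time=True)
    fit_fix = fit_waitgo_logistic(table, include_time=False)
    if n_obs == "rows":
        n = len(table)
    elif n_obs == "trials":
        n = int(table["A"].sum())
    else:
        raise ValueError("n_obs must be 'rows' or 'trials'")
    bic_var = bic(fit_var.log_likelihood, 3, n)
    bic_fix = bic(fit_fix.log_likelihood, 2, n)
    delta = bic_fix - bic_var
    # exp(-bic_var/2) / (exp(-bic_var/2) + exp(-bic_fix/2)), via the delta
    post_var = float(expit(delta / 2.0))
    if abs(delta) < margin:
        winner = "ambiguous"
    else:
        winner = "varying" if delta > 0 else "fixed"
    return ModelComparison(
        bic_fixed=bic_fix,
        bic_varying=bic_var,
        delta_bic=delta,
        post_prob_varying=post_var,
        winner=winner,
    )
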