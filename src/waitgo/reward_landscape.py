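"""Exact reward rates of linear (slope, intercept) boundary policies.

A linear boundary ``theta(t) = max(0, intercept + tan(slope_deg) * t)``
defines a symmetric wait/go policy: *go* whenever ``|x| >= theta(t)``.
Slopes are expressed in degrees, ``slope_deg = arctan(g)`` for a gradient
``g`` in evidence units per ISI unit — the same convention used when
inferring boundaries from behavior.  The reward rate of such a policy is
computed exactly by forward propagation of the random-walk occupancy, and
a grid of (slope, intercept) cells forms the reward-rate landscape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _lattice
from .optimal_policy import PolicyGrid
from .task import TaskConfig

__all__ = [
    "LinearBoundary",
    "LandscapeGrid",
    "policy_from_linear_boundary",
    "evaluate_reward_rate",
    "landscape",
    "DEFAULT_SLOPES_DEG",
    "DEFAULT_INTERCEPTS",
]

# Integer evidence lattice: non-integer intercepts only matter through the
# states they cut off, so an integer grid already distinguishes every
# constant-boundary policy.
DEFAULT_SLOPES_DEG = np.arange(-80.0, 80.0 + 1e-9, 2.0)
DEFAULT_INTERCEPTS = np.arange(0.0, 15.0 + 1e-9, 1.0)


@dataclass(frozen=True)
class LinearBoundary:
    """Symmetric linear boundary in (time, evidence) space."""

    intercept: float
    slope_deg: float

    def __post_init__(self) -> None:
        if not -90.0 < self.slope_deg < 90.0:
            raise ValueError("slope_deg must lie in (-90, 90)")

    @property
    def gradient(self) -> float:
        """Evidence units per ISI unit."""
        return float(np.tan(np.radians(self.slope_deg)))

    def theta(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.maximum(0.0, self.intercept + self.gradient * np.asarray(t, dtype=float))


def policy_from_linear_boundary(b: LinearBoundary, t_max: int = 100) -> PolicyGrid:
    """Action map of a linear boundary: go iff ``|x| >= theta(t)``.

    ``theta(t) <= 0`` forces an immediate guess at the trial center; the
    horizon ``t_max`` forces go everywhere on its row.
    """
    if t_max < 1:
        raise ValueError("t_max must be at least 1")
    t = np.arange(t_max + 1)
    theta = np.asarray(b.theta(t))
    x = np.arange(-t_max, t_max + 1)
    go = np.abs(x)[None, :] >= theta[:, None]
    go[t_max, :] = True
    return PolicyGrid(t_max=t_max, go=go)


def evaluate_reward_rate(policy: PolicyGrid, task: TaskConfig) -> float:
    """Exact reward rate of a policy under the task (renewal-reward).

    Per difficulty level the probability of a correct choice ``P_c`` and
    the expected cue count at decision ``E[T]`` are obtained by exact
    forward propagation; the rate is the mixture-averaged reward divided
    by the mixture-averaged cycle time
    ``E[T] + P_c * D_C + (1 - P_c) * D_I``.
    """
    p_c, e_t = _lattice.policy_components(policy.go, task, policy.t_max)
    return _lattice.reward_rate_from_components(p_c, e_t, task)


@dataclass
class LandscapeGrid:
    """Reward rate per (slope, intercept) cell plus the argmax cell."""

    slopes_deg: np.ndarray
    intercepts: np.ndarray
    rate: np.ndarray  # shape (len(slopes), len(intercepts))
    argmax: tuple[float, float]  # (slope_deg, intercept)

    @property
    def max_rate(self) -> float:
        return float(self.rate.max())

    def to_frame(self) -> pd.DataFrame:
        """Long-format (slope_deg, intercept, reward_rate) table."""
        s, i = np.meshgrid(self.slopes_deg, self.intercepts, indexing="ij")
        return pd.DataFrame(
            {
                "slope_deg": s.ravel(),
                "intercept": i.ravel(),
                "reward_rate": self.rate.ravel(),
            }
        )


def landscape(
    task: TaskConfig,
    slopes_deg: np.ndarray | None = None,
    intercepts: np.ndarray | None = None,
    t_max: int = 100,
) -> LandscapeGrid:
    """Reward-rate landscape over a grid of linear boundaries.

    The argmax cell is recorded with a deterministic tie-break: among
    cells attaining the grid maximum, the lowest intercept wins, then the
    slope nearest zero (negative first on a residual tie).
    """
    slopes = np.asarray(DEFAULT_SLOPES_DEG if slopes_deg is None else slopes_deg, dtype=float)
    icepts = np.asarray(DEFAULT_INTERCEPTS if intercepts is None else intercepts, dtype=float)
    if slopes.size == 0 or icepts.size == 0:
        raise ValueError("slope and intercept grids must be nonempty")

    rate = np.empty((slopes.size, icepts.size))
    for si, s in enumerate(slopes):
        for ii, c in enumerate(icepts):
            pol = policy_from_linear_boundary(LinearBoundary(c, s), t_max=t_max)
            rate[si, ii] = evaluate_reward_rate(pol, task)

    best = rate.max()
    cand = np.argwhere(rate == best)
    order = sorted(
        map(tuple, cand),
        key=lambda c: (icepts[c[1]], abs(slopes[c[0]]), slopes[c[0]]),
    )
    si, ii = order[0]
    return LandscapeGrid(
        slopes_deg=slopes,
        intercepts=icepts,
        rate=rate,
        argmax=(float(slopes[si]), float(icepts[ii])),
    )


def export_landscape(
    grid: LandscapeGrid, task: TaskConfig, path: str | Path, t_max: int | None = None
) -> None:
    """Write the landscape as long-format CSV plus a JSON metadata sidecar."""
    path = Path(path)
    grid.to_frame().to_csv(path.with_suffix(".csv"), index=False)
    meta = {
        "task": task.to_dict(),
        "argmax_slope_deg": grid.argmax[0],
        "argmax_intercept": grid.argmax[1],
        "max_rate": grid.max_rate,
    }
    if t_max is not None:
        meta["t_max"] = t_max
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def plot_landscape(grid: LandscapeGrid, ax=None):
    """Basic heat-map of the landscape (intercept on y, slope on x)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        grid.rate.T,
        origin="lower",
        aspect="auto",
        extent=(
            grid.slopes_deg[0],
            grid.slopes_deg[-1],
            grid.intercepts[0],
            grid.intercepts[-1],
        ),
    )
    ax.set_xlabel("boundary slope (deg)")
    ax.set_ylabel("boundary intercept (evidence units)")
    ax.figure.colorbar(im, ax=ax, label="reward rate")
    return ax
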