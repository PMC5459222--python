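"""Reward-rate-optimal wait/go policies by average-reward dynamic programming.

Within a trial the decision maker occupies lattice states ``(t, x)`` (cue
count, accumulated evidence) and chooses between *wait* (observe another
cue, costing one ISI unit) and *go* (commit to the more likely world
state).  A correct *go* earns the task reward and is followed by the delay
``d_correct``; an incorrect one by ``d_incorrect``.  Trials renew at
``(0, 0)``, so maximizing long-run reward per unit time is an
average-reward Markov decision problem.  The optimal differential value
``h`` and gain ``rho`` satisfy

    h(t, x) = max{ -rho + E[h(t+1, x +/- 1)],
                   R * P_c - rho * (P_c * D_C + (1 - P_c) * D_I) + h(0, 0) }

with ``h(0, 0) = 0`` and ``P_c`` the posterior probability of being
correct at ``(t, x)``.  We solve it by policy iteration: backward
induction of ``h`` under the current gain gives a greedy policy, whose
gain is then recomputed exactly by forward propagation of the random-walk
occupancy.  Ties between wait and go are broken toward *go*, which yields
the lowest boundary consistent with optimality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _lattice
from .task import EvidenceState, TaskConfig

__all__ = [
    "BeliefSummary",
    "PolicyGrid",
    "BoundaryTrace",
    "PolicyConvergenceError",
    "belief_at",
    "solve_optimal_policy",
    "extract_boundary",
]


class PolicyConvergenceError(RuntimeError):
    """Raised when policy iteration fails to converge; carries the last gain."""

    def __init__(self, message: str, last_gain: float):
        super().__init__(message)
        self.last_gain = last_gain


@dataclass(frozen=True)
class BeliefSummary:
    """Posterior summaries at one evidence state."""

    p_up: float
    p_difficulty: tuple[float, ...]
    p_step_up: float

    @property
    def p_down(self) -> float:
        return 1.0 - self.p_up

    @property
    def p_world(self) -> dict[str, float]:
        return {"up": self.p_up, "down": self.p_down}

    @property
    def p_correct(self) -> float:
        """Probability that responding with the more likely world is correct."""
        return max(self.p_up, self.p_down)


def belief_at(state: EvidenceState, task: TaskConfig) -> BeliefSummary:
    """Exact posterior at ``state`` under the task's cue model.

    The posterior over (difficulty level j, world s) is proportional to
    ``w_j * prior(s) * u_{j,s}^{n+} * (1 - u_{j,s})^{n-}`` where
    ``u_{j,up} = 1/2 + eps_j``, ``u_{j,down} = 1/2 - eps_j`` and ``n+``,
    ``n-`` count up/down cues on the path to ``(t, x)``.
    """
    n_pos, n_neg = state.n_up, state.n_down
    joint = np.empty((task.n_levels, 2))
    u_comp = np.empty((task.n_levels, 2))
    for j, eps in enumerate(task.drifts):
        for s, (u, pw) in enumerate(
            [(0.5 + eps, task.prior_up), (0.5 - eps, 1.0 - task.prior_up)]
        ):
            u_comp[j, s] = u
            joint[j, s] = task.weights[j] * pw * u**n_pos * (1.0 - u) ** n_neg
    total = joint.sum()
    if total <= 0.0:
        raise ValueError(f"state ({state.t}, {state.x}) is impossible under the task")
    post = joint / total
    return BeliefSummary(
        p_up=float(post[:, 0].sum()),
        p_difficulty=tuple(post.sum(axis=1)),
        p_step_up=float((post * u_comp).sum()),
    )


@dataclass
class PolicyGrid:
    """Wait/go action map over the parity lattice.

    ``go`` has shape ``(t_max+1, 2*t_max+1)``; column ``x + t_max`` holds
    the action at evidence ``x``.  All states at ``t = t_max`` are *go*
    (horizon truncation).  ``gain`` is the reward rate the policy achieves
    on the task it was solved or evaluated for (None until evaluated).
    """

    t_max: int
    go: np.ndarray
    gain: float | None = None

    def __post_init__(self) -> None:
        self.go = np.asarray(self.go, dtype=bool)
        expected = (self.t_max + 1, 2 * self.t_max + 1)
        if self.go.shape != expected:
            raise ValueError(f"action map must have shape {expected}")
        mask = _lattice.valid_mask(self.t_max)
        if not self.go[self.t_max][mask[self.t_max]].all():
            raise ValueError("all states at t = t_max must be go")
        self._mask = mask

    def is_valid_state(self, t: int, x: int) -> bool:
        return (
            0 <= t <= self.t_max
            and abs(x) <= min(t, self.t_max)
            and (t + x) % 2 == 0
        )

    def action(self, t: int, x: int) -> str:
        if not self.is_valid_state(t, x):
            raise ValueError(f"({t}, {x}) is not a valid lattice state")
        return "go" if self.go[t, x + self.t_max] else "wait"

    def to_frame(self) -> pd.DataFrame:
        """Tidy (t, x, action) table over valid states."""
        ts, xis = np.nonzero(self._mask)
        return pd.DataFrame(
            {
                "t": ts,
                "x": xis - self.t_max,
                "action": np.where(self.go[ts, xis], "go", "wait"),
            }
        )


@dataclass
class BoundaryTrace:
    """Go-frontier of a policy: theta[t] is the smallest nonnegative
    evidence at which the policy goes around time t.

    ``theta[t] = 0`` means guess immediately at time t.  Because the
    lattice alternates parity, the frontier at ``t`` is read off the pair
    ``{t, t+1}`` (which covers both parities); if neither time has a go
    state within reach, the scan continues forward.
    """

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)

    @property
    def t_max(self) -> int:
        return len(self.theta) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": np.arange(len(self.theta)), "theta": self.theta})


def solve_optimal_policy(
    task: TaskConfig,
    t_max: int = 100,
    tol: float = 1e-10,
    max_iter: int = 200,
    tie_tol: float = 1e-9,
) -> PolicyGrid:
    """Solve the average-reward MDP for the reward-rate-optimal policy.

    Policy iteration with exact gain evaluation: given the current gain
    ``rho``, one backward-induction sweep computes the differential value
    and its greedy policy (ties broken toward go); the greedy policy's
    gain is then recomputed exactly and the loop repeats until the policy
    and gain are stable to ``tol``.

    Raises
    ------
    PolicyConvergenceError
        If the iteration cap is reached; carries the last gain.
    """
    if t_max < 1:
        raise ValueError("t_max must be at least 1")
    if tol <= 0:
        raise ValueError("tol must be positive")

    grids = _lattice.belief_grids(task, t_max)
    mask = _lattice.valid_mask(t_max)
    p_c = grids["p_correct"]
    p_up = grids["p_step_up"]
    go_payoff = task.reward * p_c
    go_delay = p_c * task.d_correct + (1.0 - p_c) * task.d_incorrect

    # start from the immediate-guess policy
    go = np.ones_like(mask, dtype=bool)
    rho = _evaluate_gain(go, task, t_max)

    for _ in range(max_iter):
        go_value = go_payoff - rho * go_delay  # + h(0,0) = 0
        value = np.where(mask, go_value, 0.0)
        new_go = np.ones_like(go)
        for t in range(t_max - 1, -1, -1):
            nxt = value[t + 1]
            wait_value = -rho + p_up[t] * np.roll(nxt, -1) + (1.0 - p_up[t]) * np.roll(nxt, 1)
            row_go = go_value[t] >= wait_value - tie_tol
            new_go[t] = np.where(mask[t], row_go, True)
            value[t] = np.where(
                mask[t], np.maximum(go_value[t], wait_value), 0.0
            )
        new_rho = _evaluate_gain(new_go, task, t_max)
        if np.array_equal(new_go, go) and abs(new_rho - rho) < tol:
            return PolicyGrid(t_max=t_max, go=new_go, gain=new_rho)
        go, rho = new_go, new_rho

    raise PolicyConvergenceError(
        f"policy iteration did not converge in {max_iter} sweeps", last_gain=rho
    )


def _evaluate_gain(go: np.ndarray, task: TaskConfig, t_max: int) -> float:
    p_c, e_t = _lattice.policy_components(go, task, t_max)
    return _lattice.reward_rate_from_components(p_c, e_t, task)


def extract_boundary(policy: PolicyGrid) -> BoundaryTrace:
    """Read the go-frontier theta(t) off a policy's action map."""
    t_max = policy.t_max
    mask = _lattice.valid_mask(t_max)
    # smallest nonnegative go evidence per time, or None
    frontier: list[int | None] = []
    for t in range(t_max + 1):
        row = policy.go[t] & mask[t]
        xs = np.nonzero(row[t_max:])[0]  # x >= 0
        frontier.append(int(xs[0]) if xs.size else None)

    theta = np.empty(t_max + 1)
    for t in range(t_max + 1):
        found = None
        for t2 in range(t, t_max + 1):
            cands = [
                frontier[t2],
                frontier[t2 + 1] if t2 + 1 <= t_max else None,
            ]
            cands = [c for c in cands if c is not None]
            if cands:
                found = min(cands)
                break
        theta[t] = found if found is not None else t_max
    return BoundaryTrace(theta=theta)


def export_policy(
    policy: PolicyGrid,
    task: TaskConfig,
    path: str | Path,
    tol: float | None = None,
) -> None:
    """Write a policy as tidy CSVs plus a JSON metadata sidecar.

    Produces ``<path>.policy.csv`` (t, x, action), ``<path>.boundary.csv``
    (t, theta) and ``<path>.meta.json``.
    """
    path = Path(path)
    policy.to_frame().to_csv(path.with_suffix(".policy.csv"), index=False)
    extract_boundary(policy).to_frame().to_csv(
        path.with_suffix(".boundary.csv"), index=False
    )
    meta = {
        "task": task.to_dict(),
        "t_max": policy.t_max,
        "gain": policy.gain,
    }
    if tol is not None:
        meta["tol"] = tol
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
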