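"""Synthetic expanded-judgment cohorts.

Generates trial records with the statistical structure the boundary
analysis assumes: Bernoulli cue streams (+1 with probability
``u = 1/2 +/- eps``), fixed-duration blocks in which the agent completes
as many trials as time allows, and two agent families:

- *threshold* agents integrate (possibly noisy, possibly lossy) evidence
  and respond when the internal total reaches a boundary ``theta(t)``;
- *probabilistic* agents emit *go* at each step with a logistic
  probability of time and evidence magnitude, mirroring the wait/go
  regression used for inference.

Degradations studied with these agents: Gaussian internal noise added per
sample (``sigma_internal``), trial-to-trial drift perturbation
(``sigma_drift``), binomial information loss (each cue registered with
probability ``p_attend``) and an integer nondecision lag (``nd_samples``
cues pass between the internal decision and the recorded response).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .optimal_policy import BoundaryTrace
from .reward_landscape import LinearBoundary
from .task import TaskConfig

__all__ = [
    "CueSequence",
    "AgentSpec",
    "TrialRecord",
    "BlockPlan",
    "generate_cues",
    "simulate_trial",
    "simulate_trials",
    "simulate_block",
    "simulate_cohort",
    "write_trials",
    "read_trials",
]

_CHUNK = 64
# keep Bernoulli draws valid when sigma_drift pushes u past its range
_U_CLIP = (0.02, 0.98)

TRIAL_COLUMNS = [
    "participant",
    "condition",
    "block",
    "trial",
    "difficulty",
    "world",
    "response",
    "correct",
    "decision_t",
    "forced",
    "cues",
]


@dataclass(frozen=True)
class CueSequence:
    """An ordered +/-1 cue stream and the up-probability that generated it."""

    steps: tuple[int, ...]
    u: float

    def __post_init__(self) -> None:
        if any(s not in (-1, 1) for s in self.steps):
            raise ValueError("cue steps must be +1 or -1")

    def __len__(self) -> int:
        return len(self.steps)

    def to_string(self) -> str:
        return "".join("+" if s > 0 else "-" for s in self.steps)

    @classmethod
    def from_string(cls, s: str, u: float = 0.5) -> "CueSequence":
        return cls(steps=tuple(1 if c == "+" else -1 for c in s), u=u)


def generate_cues(u: float, n: int, rng: np.random.Generator) -> CueSequence:
    """i.i.d. +/-1 cues, +1 with probability ``u``."""
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must be a probability")
    if n < 0:
        raise ValueError("n must be nonnegative")
    steps = np.where(rng.random(n) < u, 1, -1)
    return CueSequence(steps=tuple(int(s) for s in steps), u=u)


@dataclass(frozen=True)
class AgentSpec:
    """One simulated decision maker.

    ``kind`` is ``"threshold"`` (rise-to-boundary, needs ``boundary``) or
    ``"probabilistic"`` (logistic wait/go, needs ``betas =
    (beta0, betaT, betaX)`` applied to time and evidence magnitude).
    """

    kind: str
    boundary: BoundaryTrace | LinearBoundary | None = None
    betas: tuple[float, float, float] | None = None
    sigma_internal: float = 0.0
    sigma_drift: float = 0.0
    p_attend: float = 1.0
    nd_samples: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("threshold", "probabilistic"):
            raise ValueError("kind must be 'threshold' or 'probabilistic'")
        if self.kind == "threshold" and self.boundary is None:
            raise ValueError("threshold agents need a boundary")
        if self.kind == "probabilistic" and self.betas is None:
            raise ValueError("probabilistic agents need betas")
        if not 0.0 < self.p_attend <= 1.0:
            raise ValueError("p_attend must be in (0, 1]")
        if self.sigma_internal < 0 or self.sigma_drift < 0:
            raise ValueError("noise magnitudes must be nonnegative")
        if self.nd_samples < 0:
            raise ValueError("nd_samples must be nonnegative")

    def theta(self, t: np.ndarray) -> np.ndarray:
        if isinstance(self.boundary, LinearBoundary):
            return np.asarray(self.boundary.theta(t), dtype=float)
        trace = self.boundary.theta
        t = np.asarray(t)
        return trace[np.minimum(t, len(trace) - 1)]


@dataclass(frozen=True)
class TrialRecord:
    """One completed decision."""

    condition: str
    difficulty: float
    world: str  # generating world state, "up" or "down"
    cues: CueSequence  # as presented, including the nondecision window
    decision_t: int  # cue count at the recorded response
    response: str  # "up" or "down"
    correct: bool
    forced: bool = False  # hit the hard cue cap
    block_id: int = 0
    trial_id: int = 0

    def __post_init__(self) -> None:
        if self.decision_t != len(self.cues):
            raise ValueError("decision_t must equal the presented cue count")
        if self.correct != (self.response == self.world):
            raise ValueError("correct flag inconsistent with response and world")


def _trial_u(agent: AgentSpec, difficulty: float, world: str, rng: np.random.Generator) -> float:
    eps_eff = difficulty
    if agent.sigma_drift > 0:
        eps_eff = difficulty + rng.normal(0.0, agent.sigma_drift)
    u = 0.5 + eps_eff if world == "up" else 0.5 - eps_eff
    return float(np.clip(u, *_U_CLIP))


def simulate_trial(
    agent: AgentSpec,
    task: TaskConfig,
    difficulty: float,
    world: str,
    rng: np.random.Generator,
    max_cues: int = 500,
    condition: str = "",
    block_id: int = 0,
    trial_id: int = 0,
) -> TrialRecord:
    """Simulate a single decision.

    Internal evidence after t cues is the sum of registered cues (each
    registered with probability ``p_attend``) plus accumulated Gaussian
    noise of per-sample SD ``sigma_internal``.  The effective drift of
    the trial is perturbed by ``sigma_drift`` (the resulting cue
    probability is clipped to keep Bernoulli draws valid).  The response
    is recorded ``nd_samples`` cues after the internal decision; cues
    presented during that lag are appended to the record but never
    influence the choice.  A trial exceeding ``max_cues`` is forced to
    respond and flagged.
    """
    if world not in ("up", "down"):
        raise ValueError("world must be 'up' or 'down'")
    u = _trial_u(agent, difficulty, world, rng)

    cues: list[int] = []
    evidence = 0.0
    t = 0
    decided = False
    forced = False

    if agent.kind == "threshold":
        theta0 = float(agent.theta(np.array([0]))[0])
        if theta0 <= 0.0:
            decided = True
    else:
        b0, _, _ = agent.betas
        if rng.random() < expit(b0):
            decided = True

    while not decided:
        n = min(_CHUNK, max_cues - t)
        if n <= 0:
            forced = True
            break
        chunk = np.where(rng.random(n) < u, 1, -1)
        registered = chunk.astype(float)
        if agent.p_attend < 1.0:
            registered = registered * (rng.random(n) < agent.p_attend)
        if agent.sigma_internal > 0.0:
            registered = registered + rng.normal(0.0, agent.sigma_internal, size=n)
        path = evidence + np.cumsum(registered)
        ts = np.arange(t + 1, t + n + 1)
        if agent.kind == "threshold":
            hit = np.abs(path) >= agent.theta(ts)
        else:
            b0, bt, bx = agent.betas
            p_go = expit(b0 + bt * ts + bx * np.abs(path))
            hit = rng.random(n) < p_go
        idx = int(np.argmax(hit)) if hit.any() else None
        if idx is None:
            cues.extend(int(c) for c in chunk)
            evidence = float(path[-1])
            t += n
        else:
            cues.extend(int(c) for c in chunk[: idx + 1])
            evidence = float(path[idx])
            t += idx + 1
            decided = True

    if evidence > 0:
        response = "up"
    elif evidence < 0:
        response = "down"
    else:
        response = "up" if rng.random() < 0.5 else "down"

    if agent.nd_samples > 0:
        lag = np.where(rng.random(agent.nd_samples) < u, 1, -1)
        cues.extend(int(c) for c in lag)
        t += agent.nd_samples

    return TrialRecord(
        condition=condition,
        difficulty=difficulty,
        world=world,
        cues=CueSequence(steps=tuple(cues), u=u),
        decision_t=t,
        response=response,
        correct=response == world,
        forced=forced,
        block_id=block_id,
        trial_id=trial_id,
    )


def simulate_block(
    agent: AgentSpec,
    task: TaskConfig,
    condition: str,
    duration: float,
    rng: np.random.Generator,
    max_cues: int = 500,
    block_id: int = 0,
) -> list[TrialRecord]:
    """Trials of one fixed-duration block.

    Trials accumulate while the clock (cues consumed plus the realized
    intertrial delay of each completed trial) is below ``duration``; a
    trial still in progress when time expires is discarded, since only
    completed choices are recorded.
    """
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    trials: list[TrialRecord] = []
    clock = 0.0
    trial_id = 0
    weights = np.asarray(task.weights)
    while clock < duration:
        world = "up" if rng.random() < task.prior_up else "down"
        difficulty = float(task.drifts[rng.choice(len(weights), p=weights)])
        rec = simulate_trial(
            agent,
            task,
            difficulty,
            world,
            rng,
            max_cues=max_cues,
            condition=condition,
            block_id=block_id,
            trial_id=trial_id,
        )
        if clock + rec.decision_t > duration:
            break  # trial in progress at block end: discarded
        trials.append(rec)
        clock += rec.decision_t + (task.d_correct if rec.correct else task.d_incorrect)
        trial_id += 1
    return trials


def simulate_trials(
    agent: AgentSpec,
    task: TaskConfig,
    n_trials: int,
    rng: np.random.Generator,
    condition: str = "",
    participant: int = 0,
    max_cues: int = 500,
) -> pd.DataFrame:
    """A fixed number of trials as a tidy table (no block clock).

    Worlds are drawn from the task prior and difficulties from the
    mixture weights.  Used by recovery studies where the trial count,
    not the session duration, is controlled.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be nonnegative")
    weights = np.asarray(task.weights)
    rows = []
    for i in range(n_trials):
        world = "up" if rng.random() < task.prior_up else "down"
        difficulty = float(task.drifts[rng.choice(len(weights), p=weights)])
        rec = simulate_trial(
            agent,
            task,
            difficulty,
            world,
            rng,
            max_cues=max_cues,
            condition=condition,
            trial_id=i,
        )
        rows.append(
            {
                "participant": participant,
                "condition": condition,
                "block": 0,
                "trial": i,
                "difficulty": difficulty,
                "world": world,
                "response": rec.response,
                "correct": rec.correct,
                "decision_t": rec.decision_t,
                "forced": rec.forced,
                "cues": rec.cues.to_string(),
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


class BlockPlan(NamedTuple):
    """One block type of a session: condition name, task, duration, count."""

    condition: str
    task: TaskConfig
    duration: float
    n_blocks: int = 1


AgentSampler = Callable[[int, str, np.random.Generator], AgentSpec]


def simulate_cohort(
    n_participants: int,
    agent_sampler: AgentSpec | AgentSampler,
    plans: Sequence[BlockPlan],
    seed: int | np.random.SeedSequence = 0,
    max_cues: int = 500,
) -> pd.DataFrame:
    """Simulate a cohort and return one tidy row per trial.

    ``agent_sampler`` is either a single :class:`AgentSpec` used for
    everyone, or a callable ``(participant, condition, rng) -> AgentSpec``
    that injects heterogeneity.  Each participant gets an independent
    child seed of ``seed``, so identical inputs reproduce identical
    tables.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = root.spawn(n_participants)
    rows: list[dict] = []
    for p, child in enumerate(children):
        rng = np.random.default_rng(child)
        for plan in plans:
            for b in range(plan.n_blocks):
                if callable(agent_sampler):
                    agent = agent_sampler(p, plan.condition, rng)
                else:
                    agent = agent_sampler
                recs = simulate_block(
                    agent,
                    plan.task,
                    plan.condition,
                    plan.duration,
                    rng,
                    max_cues=max_cues,
                    block_id=b,
                )
                for rec in recs:
                    rows.append(
                        {
                            "participant": p,
                            "condition": rec.condition,
                            "block": rec.block_id,
                            "trial": rec.trial_id,
                            "difficulty": rec.difficulty,
                            "world": rec.world,
                            "response": rec.response,
                            "correct": rec.correct,
                            "decision_t": rec.decision_t,
                            "forced": rec.forced,
                            "cues": rec.cues.to_string(),
                        }
                    )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(
    df: pd.DataFrame, path: str | Path, metadata: Mapping | None = None
) -> None:
    """Write a trial table as CSV with a JSON metadata sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = dict(metadata or {})
    sidecar.setdefault("columns", list(df.columns))
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table and validate its invariants."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False, dtype={"cues": str})
    df["correct"] = df["correct"].astype(bool)
    df["forced"] = df["forced"].astype(bool)
    bad_len = df["decision_t"] != df["cues"].str.len()
    if bad_len.any():
        raise ValueError("decision_t does not match cue-string length on some rows")
    bad_cues = ~df["cues"].str.fullmatch(r"[+-]*")
    if bad_cues.any():
        raise ValueError("cue strings may contain only '+' and '-'")
    bad_correct = df["correct"] != (df["response"] == df["world"])
    if bad_correct.any():
        raise ValueError("correct flag inconsistent with response and world")
    return df
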