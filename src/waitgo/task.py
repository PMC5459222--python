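"""Task configuration for the Bernoulli-cue expanded-judgment game.

A trial presents a stream of binary cues, each +1 with probability
``u = 1/2 + eps`` when the hidden world state is *up* and ``u = 1/2 - eps``
when it is *down*.  The drift magnitude ``eps`` sets the difficulty of a
trial (``eps = 0`` is pure noise, ``eps = 1/2`` is deterministic).  Time is
measured in interstimulus-interval (ISI) units: one unit per cue.  After a
choice the next trial starts following a delay of ``d_correct`` units when
the choice was correct and ``d_incorrect`` units when it was wrong.

A task may mix several drift levels (the decision maker knows the levels
and their mixture weights but not which level the current trial has).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["TaskConfig", "EvidenceState"]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class TaskConfig:
    """Generative description of one game condition.

    Parameters
    ----------
    drifts
        Drift magnitudes ``eps_j`` in ``[0, 1/2]``, one per difficulty level.
    weights
        Mixture probability of each difficulty level; defaults to equal
        weights. Must sum to 1.
    d_correct, d_incorrect
        Intertrial delays (ISI units) after correct / incorrect choices.
    reward
        Reward delivered for a correct choice (arbitrary units).
    prior_up
        Prior probability that the world state is *up*.
    """

    drifts: tuple[float, ...]
    d_correct: float
    d_incorrect: float
    weights: tuple[float, ...] = ()
    reward: float = 1.0
    prior_up: float = 0.5

    def __post_init__(self) -> None:
        drifts = tuple(float(e) for e in self.drifts)
        if not drifts:
            raise ValueError("at least one drift level is required")
        for eps in drifts:
            if not 0.0 <= eps <= 0.5:
                raise ValueError(f"drift {eps} outside [0, 1/2]")
        weights = tuple(float(w) for w in self.weights)
        if not weights:
            weights = tuple(1.0 / len(drifts) for _ in drifts)
        if len(weights) != len(drifts):
            raise ValueError("weights and drifts must have equal length")
        if any(w < 0 for w in weights):
            raise ValueError("mixture weights must be nonnegative")
        if abs(sum(weights) - 1.0) > _WEIGHT_TOL:
            raise ValueError("mixture weights must sum to 1")
        if self.d_correct < 0 or self.d_incorrect < 0:
            raise ValueError("intertrial delays must be nonnegative")
        if not 0.0 <= self.prior_up <= 1.0:
            raise ValueError("prior_up must be a probability")
        object.__setattr__(self, "drifts", drifts)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def single(
        cls,
        drift: float,
        d_correct: float,
        d_incorrect: float,
        reward: float = 1.0,
        prior_up: float = 0.5,
    ) -> "TaskConfig":
        """A single-difficulty task."""
        return cls(
            drifts=(drift,),
            d_correct=d_correct,
            d_incorrect=d_incorrect,
            reward=reward,
            prior_up=prior_up,
        )

    @classmethod
    def mixed(
        cls,
        drifts: Sequence[float],
        d_correct: float,
        d_incorrect: float,
        weights: Sequence[float] = (),
        reward: float = 1.0,
        prior_up: float = 0.5,
    ) -> "TaskConfig":
        """A mixed-difficulty task (equal weights unless given)."""
        return cls(
            drifts=tuple(drifts),
            d_correct=d_correct,
            d_incorrect=d_incorrect,
            weights=tuple(weights),
            reward=reward,
            prior_up=prior_up,
        )

    @property
    def n_levels(self) -> int:
        return len(self.drifts)

    def up_probabilities(self, world_up: bool = True) -> np.ndarray:
        """Per-level cue up-probability given the world state."""
        eps = np.asarray(self.drifts)
        return 0.5 + eps if world_up else 0.5 - eps

    def to_dict(self) -> dict:
        return {
            "drifts": list(self.drifts),
            "weights": list(self.weights),
            "d_correct": self.d_correct,
            "d_incorrect": self.d_incorrect,
            "reward": self.reward,
            "prior_up": self.prior_up,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        return cls(
            drifts=tuple(d["drifts"]),
            weights=tuple(d.get("weights", ())),
            d_correct=d["d_correct"],
            d_incorrect=d["d_incorrect"],
            reward=d.get("reward", 1.0),
            prior_up=d.get("prior_up", 0.5),
        )


@dataclass(frozen=True)
class EvidenceState:
    """A lattice point ``(t, x)``: cue count and accumulated evidence.

    Because evidence is a +/-1 random walk started at 0, ``|x| <= t`` and
    ``t + x`` must be even.
    """

    t: int
    x: int

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("cue count t must be nonnegative")
        if abs(self.x) > self.t:
            raise ValueError(f"|x|={abs(self.x)} exceeds t={self.t}")
        if (self.t + self.x) % 2 != 0:
            raise ValueError(f"state ({self.t}, {self.x}) violates walk parity")

    @property
    def n_up(self) -> int:
        """Number of +1 cues consistent with this state."""
        return (self.t + self.x) // 2

    @property
    def n_down(self) -> int:
        return (self.t - self.x) // 2
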