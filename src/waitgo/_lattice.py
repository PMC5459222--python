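"""Internal lattice machinery shared by the policy solver and the
reward-rate evaluator.

States live on the parity lattice ``(t, x)`` with ``0 <= t <= t_max``,
``|x| <= min(t, t_max)`` and ``t + x`` even.  Arrays are indexed
``[t, x + t_max]``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp, xlogy

from .task import TaskConfig


def valid_mask(t_max: int) -> np.ndarray:
    """Boolean mask of reachable parity-valid states, shape (t_max+1, 2*t_max+1)."""
    t = np.arange(t_max + 1)[:, None]
    x = np.arange(-t_max, t_max + 1)[None, :]
    return (np.abs(x) <= t) & ((t + x) % 2 == 0)


def belief_grids(task: TaskConfig, t_max: int) -> dict[str, np.ndarray]:
    """Posterior summaries at every lattice state.

    Returns arrays of shape ``(t_max+1, 2*t_max+1)``:

    - ``p_up``: posterior probability the world is up,
    - ``p_correct``: posterior probability that responding with the more
      likely world state is correct (``max(p_up, 1 - p_up)``),
    - ``p_step_up``: predictive probability that the next cue is +1,
    - plus ``p_difficulty`` of shape ``(n_levels, t_max+1, 2*t_max+1)``.

    States that are impossible under every difficulty level (e.g. an
    imbalanced path when all drifts are 1/2) fall back to the prior.
    """
    t = np.arange(t_max + 1)[:, None]
    x = np.arange(-t_max, t_max + 1)[None, :]
    n_pos = (t + x) / 2.0
    n_neg = (t - x) / 2.0

    drifts = np.asarray(task.drifts)
    weights = np.asarray(task.weights)
    n_lev = len(drifts)

    # joint components (level j, world s in {up, down})
    log_joint = np.empty((n_lev, 2) + n_pos.shape)
    u_comp = np.empty((n_lev, 2))
    priors = np.empty((n_lev, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        for j, eps in enumerate(drifts):
            for s, (u, pw) in enumerate(
                [(0.5 + eps, task.prior_up), (0.5 - eps, 1.0 - task.prior_up)]
            ):
                u_comp[j, s] = u
                priors[j, s] = weights[j] * pw
                log_prior = np.log(priors[j, s]) if priors[j, s] > 0 else -np.inf
                log_joint[j, s] = log_prior + xlogy(n_pos, u) + xlogy(n_neg, 1.0 - u)

    flat = log_joint.reshape(n_lev * 2, *n_pos.shape)
    norm = logsumexp(flat, axis=0)
    reachable = np.isfinite(norm)
    with np.errstate(invalid="ignore"):
        post = np.exp(flat - norm)
    # unreachable states: fall back to the prior over (level, world)
    prior_flat = priors.reshape(-1) / priors.sum()
    post[:, ~reachable] = prior_flat[:, None]
    post = post.reshape(n_lev, 2, *n_pos.shape)

    p_up = post[:, 0].sum(axis=0)
    p_correct = np.maximum(p_up, 1.0 - p_up)
    p_step_up = np.tensordot(u_comp, post, axes=([0, 1], [0, 1]))
    p_difficulty = post.sum(axis=1)
    return {
        "p_up": p_up,
        "p_correct": p_correct,
        "p_step_up": p_step_up,
        "p_difficulty": p_difficulty,
    }


def policy_components(
    go: np.ndarray, task: TaskConfig, t_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-difficulty accuracy and decision time of a policy.

    Propagates the occupancy of the +/-1 random walk (conditioned on the
    world being up; symmetric policies make the down world a mirror image)
    through the wait region of ``go`` and accumulates, per difficulty level
    ``j``, the probability of a correct choice ``P_c[j]`` and the expected
    cue count at decision ``E_T[j]``.  A decision at ``x > 0`` is correct,
    at ``x < 0`` incorrect, and at ``x = 0`` correct with probability 1/2
    (fair guess).
    """
    nx = 2 * t_max + 1
    center = t_max
    mask = valid_mask(t_max)
    n_lev = task.n_levels
    p_c = np.zeros(n_lev)
    e_t = np.zeros(n_lev)
    for j, u in enumerate(task.up_probabilities(world_up=True)):
        occ = np.zeros(nx)
        occ[center] = 1.0
        for t in range(t_max + 1):
            g = go[t] & mask[t] if t < t_max else mask[t]
            m = np.where(g, occ, 0.0)
            tot = m.sum()
            if tot > 0.0:
                p_c[j] += m[center + 1 :].sum() + 0.5 * m[center]
                e_t[j] += t * tot
            if t == t_max:
                break
            w = np.where(mask[t] & ~g, occ, 0.0)
            nxt = np.zeros(nx)
            nxt[1:] += u * w[:-1]
            nxt[:-1] += (1.0 - u) * w[1:]
            occ = nxt
            if occ.sum() < 1e-300:
                break
    return p_c, e_t


def reward_rate_from_components(
    p_c: np.ndarray, e_t: np.ndarray, task: TaskConfig
) -> float:
    """Renewal-reward rate: mixture-averaged reward over mixture-averaged cycle time."""
    w = np.asarray(task.weights)
    numer = task.reward * float(w @ p_c)
    denom = float(
        w @ (e_t + p_c * task.d_correct + (1.0 - p_c) * task.d_incorrect)
    )
    if denom <= 0.0:
        raise ValueError(
            "expected cycle time is zero; the task needs a positive delay "
            "or a policy that samples at least one cue"
        )
    return numer / denom
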