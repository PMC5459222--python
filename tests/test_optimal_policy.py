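"""Average-reward DP solver: optimal boundary shapes and an enumeration oracle."""

import itertools

import numpy as np
import pytest

from waitgo import (
    LinearBoundary,
    PolicyGrid,
    TaskConfig,
    evaluate_reward_rate,
    extract_boundary,
    solve_optimal_policy,
)


def wait_region_times(policy):
    """Times that still contain a reachable wait state."""
    from waitgo._lattice import valid_mask

    mask = valid_mask(policy.t_max)
    has_wait = (~policy.go & mask).any(axis=1)
    return np.nonzero(has_wait)[0]


def test_zero_drift_guesses_immediately():
    task = TaskConfig.single(0.0, 70, 70)
    policy = solve_optimal_policy(task)
    theta = extract_boundary(policy).theta
    assert np.all(theta == 0)
    # immediate guessing earns half the reward per average delay
    assert policy.gain == pytest.approx(0.5 / 70)


def test_single_difficulty_boundary_constant():
    task = TaskConfig.single(0.2, 70, 70)
    policy = solve_optimal_policy(task)
    theta = extract_boundary(policy).theta
    ts = wait_region_times(policy)
    # ignore the tail where horizon truncation forces early commitment
    core = ts[ts <= policy.t_max - 20]
    assert core.size > 0
    vals = np.unique(theta[core])
    assert vals.size == 1 and vals[0] > 0


def test_mixed_with_impossible_level_decreases_to_zero():
    task = TaskConfig.mixed((0.2, 0.0), 70, 70)
    theta = extract_boundary(solve_optimal_policy(task)).theta
    assert np.all(np.diff(theta) <= 0)
    assert theta[0] > 0
    zero_at = np.nonzero(theta == 0)[0]
    assert zero_at.size > 0 and zero_at[0] < 100


def test_mixed_moderate_drifts_boundary_increases():
    task = TaskConfig.mixed((0.4, 0.1), 50, 50)
    policy = solve_optimal_policy(task)
    theta = extract_boundary(policy).theta
    # ignore the tail where horizon truncation pulls the frontier down
    core = theta[: policy.t_max - 10]
    assert np.all(np.diff(core) >= 0)
    assert core[-1] > core[0]


def test_boundary_height_nonmonotonic_in_difficulty():
    heights = {}
    for eps in (0.0, 0.05, 0.2, 0.45):
        task = TaskConfig.single(eps, 70, 70)
        heights[eps] = extract_boundary(solve_optimal_policy(task)).theta[0]
    assert heights[0.0] == 0
    assert heights[0.05] >= heights[0.45]
    assert heights[0.2] > heights[0.45]


def test_dc_invariance_of_mixed_policy():
    """For mixed tasks the optimal action map depends only on D_I while D_C < D_I."""
    ref = None
    for d_c in (10, 25, 40):
        task = TaskConfig.mixed((0.22, 0.0), d_c, 50)
        policy = solve_optimal_policy(task)
        if ref is None:
            ref = policy.go
        else:
            assert np.array_equal(policy.go, ref)


def test_horizon_invariance():
    task = TaskConfig.mixed((0.22, 0.0), 50 / 3, 50)
    p1 = solve_optimal_policy(task, t_max=60)
    p2 = solve_optimal_policy(task, t_max=120)
    # action maps agree on the shared lattice away from each horizon
    from waitgo._lattice import valid_mask

    mask = valid_mask(60)
    for t in range(50):
        row1 = p1.go[t][mask[t]]
        row2 = p2.go[t][60:181][mask[t]]
        assert np.array_equal(row1, row2)
    assert p1.gain == pytest.approx(p2.gain, abs=1e-8)


@pytest.mark.parametrize(
    "drifts,weights,d_c,d_i",
    [
        ((0.3,), (1.0,), 4, 8),
        ((0.4, 0.0), (0.5, 0.5), 3, 6),
        ((0.25, 0.1), (0.5, 0.5), 5, 5),
    ],
)
def test_tiny_horizon_gain_matches_exhaustive_enumeration(drifts, weights, d_c, d_i):
    """Oracle: enumerate every boundary-shaped policy on a 4-step horizon and
    evaluate each exactly; the DP gain must equal the enumeration maximum."""
    t_max = 4
    task = TaskConfig(drifts=drifts, weights=weights, d_correct=d_c, d_incorrect=d_i)
    best = -np.inf
    x = np.arange(-t_max, t_max + 1)
    for thetas in itertools.product(range(t_max + 2), repeat=t_max):
        go = np.empty((t_max + 1, 2 * t_max + 1), dtype=bool)
        for t in range(t_max):
            go[t] = np.abs(x) >= thetas[t]
        go[t_max] = True
        rate = evaluate_reward_rate(PolicyGrid(t_max=t_max, go=go), task)
        best = max(best, rate)
    policy = solve_optimal_policy(task, t_max=t_max)
    assert policy.gain == pytest.approx(best, abs=1e-10)


def test_optimality_equation_residual():
    """The returned policy satisfies the average-reward optimality equations."""
    from waitgo import _lattice

    task = TaskConfig.mixed((0.22, 0.0), 50 / 3, 50)
    t_max = 60
    policy = solve_optimal_policy(task, t_max=t_max)
    rho = policy.gain
    grids = _lattice.belief_grids(task, t_max)
    mask = _lattice.valid_mask(t_max)
    p_c, p_up = grids["p_correct"], grids["p_step_up"]
    go_value = task.reward * p_c - rho * (
        p_c * task.d_correct + (1 - p_c) * task.d_incorrect
    )
    value = np.where(mask, go_value, 0.0)
    for t in range(t_max - 1, -1, -1):
        nxt = value[t + 1]
        wait = -rho + p_up[t] * np.roll(nxt, -1) + (1 - p_up[t]) * np.roll(nxt, 1)
        value[t] = np.where(mask[t], np.maximum(go_value[t], wait), 0.0)
        # the policy's action must attain the max at every valid state
        chosen = np.where(policy.go[t], go_value[t], wait)
        assert np.all(np.abs((chosen - value[t])[mask[t]]) < 1e-8)
    assert abs(value[0, t_max]) < 1e-8  # h(0, 0) = 0 at the fixed point


def test_extract_boundary_degenerate_policies():
    t_max = 6
    all_go = PolicyGrid(t_max=t_max, go=np.ones((t_max + 1, 2 * t_max + 1), bool))
    assert np.all(extract_boundary(all_go).theta == 0)

    x = np.arange(-t_max, t_max + 1)
    go = np.abs(x)[None, :] >= 3
    go = np.repeat(go, t_max + 1, axis=0)
    go[t_max] = True
    theta = extract_boundary(PolicyGrid(t_max=t_max, go=go)).theta
    assert np.all(theta[:4] == 3)


def test_policy_export_round_trip(tmp_path):
    from waitgo.optimal_policy import export_policy

    task = TaskConfig.single(0.2, 15, 50)
    policy = solve_optimal_policy(task, t_max=30)
    export_policy(policy, task, tmp_path / "pol", tol=1e-10)
    import json

    import pandas as pd

    frame = pd.read_csv(tmp_path / "pol.policy.csv")
    assert set(frame.columns) == {"t", "x", "action"}
    assert set(frame["action"].unique()) <= {"wait", "go"}
    meta = json.loads((tmp_path / "pol.meta.json").read_text())
    assert meta["gain"] == pytest.approx(policy.gain)
    assert TaskConfig.from_dict(meta["task"]) == task
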