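"""Nondecision stripping, wait/go regression, indifference lines, slope
differences, bootstrap CIs and the chance-accuracy screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waitgo import (
    AgentSpec,
    LinearBoundary,
    TaskConfig,
    binomial_exclusion_test,
    bootstrap_slope_ci,
    build_wait_go_table,
    circular_slope_difference,
    estimate_nondecision,
    fit_waitgo_logistic,
    line_of_indifference,
    simulate_trials,
    strip_nondecision,
)
from waitgo.boundary_inference import LogisticFit


def make_trials(rows):
    defaults = dict(
        participant=0, condition="easy", block=0, difficulty=0.2, world="up", forced=False
    )
    out = []
    for i, r in enumerate(rows):
        d = dict(defaults, trial=i, **r)
        d.setdefault("decision_t", len(d["cues"]))
        d.setdefault("correct", d["response"] == d["world"])
        out.append(d)
    return pd.DataFrame(out)


# ---------------------------------------------------------------- nondecision


@pytest.fixture(scope="module")
def easy_task():
    return TaskConfig.single(0.2, 15, 50)


@pytest.mark.parametrize("nd_true", [0, 2, 4])
def test_nondecision_recovery(nd_true, easy_task):
    agent = AgentSpec(
        kind="threshold", boundary=LinearBoundary(3, 0.0), nd_samples=nd_true
    )
    df = simulate_trials(agent, easy_task, 400, np.random.default_rng(10 + nd_true))
    est = estimate_nondecision(df)
    assert est.nd == nd_true
    assert not est.saturated


def test_nondecision_requires_enough_trials():
    df = make_trials([{"cues": "+++", "response": "up"} for _ in range(5)])
    with pytest.raises(ValueError):
        estimate_nondecision(df)


def test_nondecision_saturates_with_warning():
    # responses unrelated to cues: p_t hovers near 1/2 everywhere
    rng = np.random.default_rng(0)
    rows = [
        {
            "cues": "".join(rng.choice(["+", "-"], size=8)),
            "response": rng.choice(["up", "down"]),
            "correct": True,
            "world": "up",
        }
        for _ in range(100)
    ]
    for r in rows:
        r["correct"] = r["response"] == r["world"]
    df = make_trials(rows)
    with pytest.warns(UserWarning):
        est = estimate_nondecision(df, max_lag=6)
    assert est.saturated and est.nd == 6


def test_strip_recomputes_decision_state():
    df = make_trials([{"cues": "+++", "response": "up"}])
    out, dropped = strip_nondecision(df, 1)
    assert dropped == 0
    assert out.iloc[0]["cues"] == "++" and out.iloc[0]["decision_t"] == 2
    # identity at nd = 0
    same, dropped0 = strip_nondecision(df, 0)
    pd.testing.assert_frame_equal(same, df)
    assert dropped0 == 0


def test_strip_drops_too_short_trials():
    df = make_trials([{"cues": "+", "response": "up"} for _ in range(4)])
    out, dropped = strip_nondecision(df, 1)
    assert len(out) == 0 and dropped == 4


# ------------------------------------------------------------- wait/go table


def test_table_rows_for_single_trial():
    df = make_trials([{"cues": "+-+", "response": "up"}])
    table = build_wait_go_table(df)
    assert table[["T", "X", "A"]].values.tolist() == [[1, 1, 0], [2, 0, 0], [3, 1, 1]]


def test_table_aligns_evidence_with_response():
    # a "down" decision at x = -3 appears at aligned evidence +3
    df = make_trials([{"cues": "---", "response": "down", "world": "down"}])
    table = build_wait_go_table(df)
    assert table[["T", "X", "A"]].values.tolist() == [[1, 1, 0], [2, 2, 0], [3, 3, 1]]


def test_immediate_guess_contributes_single_go_row():
    df = make_trials([{"cues": "", "response": "up", "decision_t": 0}])
    table = build_wait_go_table(df)
    assert table[["T", "X", "A"]].values.tolist() == [[0, 0, 1]]


def test_mixed_easy_only_filter():
    task = TaskConfig.mixed((0.2, 0.0), 15, 50)
    agent = AgentSpec(kind="threshold", boundary=LinearBoundary(3, -20.0))
    df = simulate_trials(agent, task, 300, np.random.default_rng(11), condition="mixed")
    table = build_wait_go_table(df, condition="mixed", keep_difficulty=0.2)
    n_kept_trials = int(table["A"].sum())
    assert n_kept_trials == (df["difficulty"] > 0).sum()
    assert 0.35 < n_kept_trials / len(df) < 0.65


# ------------------------------------------------------------- logistic fit


def test_logistic_recovers_generating_betas(easy_task):
    true = (-4.0, 0.2, 1.0)
    agent = AgentSpec(kind="probabilistic", betas=true)
    df = simulate_trials(agent, easy_task, 4000, np.random.default_rng(12))
    fit = fit_waitgo_logistic(build_wait_go_table(df))
    assert fit.converged and not fit.penalized
    assert fit.beta0 == pytest.approx(true[0], abs=0.6)
    assert fit.betaT == pytest.approx(true[1], abs=0.1)
    assert fit.betaX == pytest.approx(true[2], abs=0.25)


def test_null_time_coefficient_covered(easy_task):
    agent = AgentSpec(kind="probabilistic", betas=(-3.0, 0.0, 1.0))
    df = simulate_trials(agent, easy_task, 2000, np.random.default_rng(13))
    fit = fit_waitgo_logistic(build_wait_go_table(df))
    assert abs(fit.betaT) < 0.05


def test_nested_model_likelihood_ordering(easy_task):
    agent = AgentSpec(
        kind="threshold", boundary=LinearBoundary(4, -30.0), sigma_internal=0.5
    )
    df = simulate_trials(agent, easy_task, 400, np.random.default_rng(14))
    table = build_wait_go_table(df)
    full = fit_waitgo_logistic(table, include_time=True)
    reduced = fit_waitgo_logistic(table, include_time=False)
    assert full.log_likelihood >= reduced.log_likelihood
    assert full.log_likelihood <= 0 and reduced.log_likelihood <= 0
    assert reduced.betaT == 0.0


def test_separable_table_falls_back_to_ridge(easy_task):
    # noiseless threshold agent: wait/go is perfectly separable in (T, X)
    agent = AgentSpec(kind="threshold", boundary=LinearBoundary(3, 0.0))
    df = simulate_trials(agent, easy_task, 200, np.random.default_rng(15))
    fit = fit_waitgo_logistic(build_wait_go_table(df))
    assert fit.penalized
    slope = line_of_indifference(fit)
    assert abs(slope.slope_deg) < 15  # constant boundary: near-zero slope


def test_single_action_table_rejected():
    table = pd.DataFrame({"participant": [0], "trial": [0], "T": [1], "X": [1], "A": [1]})
    with pytest.raises(ValueError):
        fit_waitgo_logistic(table)


# ------------------------------------------------------- line of indifference


def test_indifference_line_constant_and_diagonal():
    flat = line_of_indifference(
        LogisticFit(-3.0, 0.0, 1.0, -10.0, 100, True)
    )
    assert flat.slope_deg == pytest.approx(0.0)
    assert flat.intercept == pytest.approx(3.0)
    diag = line_of_indifference(
        LogisticFit(0.0, 1.0, 1.0, -10.0, 100, True)
    )
    assert diag.slope_deg == pytest.approx(-45.0)


def test_time_dominated_fit_saturates():
    est = line_of_indifference(LogisticFit(-2.0, 0.5, 1e-12, -10.0, 100, True))
    assert est.time_dominated
    assert est.slope_deg == pytest.approx(-90.0, abs=1e-3)


# --------------------------------------------------- circular slope difference


@pytest.mark.parametrize(
    "m_e,m_m,expected",
    [(0, 0, 0), (80, -80, -20), (10, -10, 20), (-30, 30, -60), (45, 0, 45)],
)
def test_circular_difference_examples(m_e, m_m, expected):
    assert circular_slope_difference(m_e, m_m) == pytest.approx(expected)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    m_e=st.floats(-90.0, 90.0, exclude_min=True),
    m_m=st.floats(-90.0, 90.0, exclude_min=True),
)
def test_circular_difference_bounded(m_e, m_m):
    d = circular_slope_difference(m_e, m_m)
    assert -90.0 <= d < 90.0
    # d is the raw difference modulo 180 degrees
    assert (m_e - m_m - d) % 180.0 == pytest.approx(0.0, abs=1e-6) or (
        m_e - m_m - d
    ) % 180.0 == pytest.approx(180.0, abs=1e-6)


# ------------------------------------------------------------------ bootstrap


def test_bootstrap_degenerate_trials_zero_width():
    df = make_trials([{"cues": "+++", "response": "up"} for _ in range(30)])
    lo, hi = bootstrap_slope_ci(df, n_boot=50, rng=np.random.default_rng(16))
    assert lo == pytest.approx(hi)


def test_bootstrap_requires_replicates():
    df = make_trials([{"cues": "+++", "response": "up"} for _ in range(5)])
    with pytest.raises(ValueError):
        bootstrap_slope_ci(df, n_boot=0)


def test_bootstrap_covers_point_estimate(easy_task):
    agent = AgentSpec(
        kind="threshold", boundary=LinearBoundary(4, -20.0), sigma_internal=0.5
    )
    df = simulate_trials(agent, easy_task, 250, np.random.default_rng(17))
    fit = fit_waitgo_logistic(build_wait_go_table(df))
    point = line_of_indifference(fit).slope_deg
    lo, hi = bootstrap_slope_ci(df, n_boot=200, rng=np.random.default_rng(18))
    assert lo <= point <= hi
    # the indifference slope tracks the generating slope systematically
    # (it is not unbiased for it); a collapsing boundary must show up as
    # a clearly negative interval
    assert hi < 0.0


# ------------------------------------------------------------ exclusion test


def test_exclusion_screen():
    good = make_trials(
        [{"cues": "+++", "response": "up" if i < 90 else "down"} for i in range(100)]
    )
    res = binomial_exclusion_test(good)
    assert res.p_value < 0.05 and not res.excluded

    chance = make_trials(
        [{"cues": "+++", "response": "up" if i % 2 else "down"} for i in range(100)]
    )
    res = binomial_exclusion_test(chance)
    assert res.excluded

    with pytest.raises(ValueError):
        binomial_exclusion_test(good.iloc[:0])
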