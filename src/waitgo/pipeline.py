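"""End-to-end experiment pipeline: solve -> simulate -> infer -> compare.

Presets encode the six study designs (three game types each: easy,
difficult and mixed).  All internal time is in ISI units (one unit per
cue); millisecond quantities from the designs are converted once at
preset construction, e.g. a 10 s intertrial delay at a 200 ms ISI is
``D_I = 50`` units.

A cohort of simulated participants plays fixed-duration blocks of every
condition with reward-rate-optimal boundaries (or any supplied agent),
after which the inference pipeline mirrors the treatment of real data:
nondecision-lag estimation from the easy games, stripping, the binomial
exclusion screen, per-condition wait/go logistic fits, indifference
slopes with optional bootstrap CIs, circular slope differences between
the mixed condition and its single-difficulty reference, a paired t test
across the cohort, and fixed-vs-varying boundary model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import boundary_inference as bi
from . import model_selection as ms
from .optimal_policy import extract_boundary, solve_optimal_policy
from .synthetic_cohort import AgentSpec, BlockPlan, simulate_cohort
from .task import TaskConfig

__all__ = [
    "ExperimentPreset",
    "EXPERIMENT_PRESETS",
    "RunConfig",
    "run_experiment_preset",
    "summarize_cohort",
]


@dataclass(frozen=True)
class ExperimentPreset:
    """Task parameters of one study design, in ISI units."""

    name: str
    isi_ms: float
    eps_easy: float
    eps_difficult: float
    d_correct: float
    d_incorrect: float
    durations: Mapping[str, float]  # block duration per condition, ISI units
    reference_condition: str  # single-difficulty condition compared to mixed
    mixed_subset: str  # which difficulty of mixed trials enters the comparison

    def tasks(self, reward: float = 1.0) -> dict[str, TaskConfig]:
        return {
            "easy": TaskConfig.single(
                self.eps_easy, self.d_correct, self.d_incorrect, reward=reward
            ),
            "difficult": TaskConfig.single(
                self.eps_difficult, self.d_correct, self.d_incorrect, reward=reward
            ),
            "mixed": TaskConfig.mixed(
                (self.eps_easy, self.eps_difficult),
                self.d_correct,
                self.d_incorrect,
                reward=reward,
            ),
        }

    @property
    def mixed_subset_drift(self) -> float:
        return self.eps_easy if self.mixed_subset == "easy" else self.eps_difficult


def _preset(
    name: str,
    isi_ms: float,
    eps_easy: float,
    eps_difficult: float,
    d_correct_s: float,
    d_incorrect_s: float,
    durations_s: Mapping[str, float],
    reference: str = "easy",
    mixed_subset: str = "easy",
) -> ExperimentPreset:
    unit = isi_ms / 1000.0
    return ExperimentPreset(
        name=name,
        isi_ms=isi_ms,
        eps_easy=eps_easy,
        eps_difficult=eps_difficult,
        d_correct=d_correct_s / unit,
        d_incorrect=d_incorrect_s / unit,
        durations={k: v / unit for k, v in durations_s.items()},
        reference_condition=reference,
        mixed_subset=mixed_subset,
    )


_BLOCK_S = {"easy": 240.0, "difficult": 300.0, "mixed": 300.0}

EXPERIMENT_PRESETS: dict[str, ExperimentPreset] = {
    "exp1": _preset("exp1", 200.0, 0.20, 0.0, 3.0, 10.0, _BLOCK_S),
    "exp2a": _preset("exp2a", 200.0, 0.22, 0.0, 10.0 / 3.0, 10.0, _BLOCK_S),
    "exp2b": _preset("exp2b", 50.0, 0.22, 0.0, 2.5 / 3.0, 2.5, _BLOCK_S),
    "exp2c": _preset("exp2c", 200.0, 0.22, 0.0, 10.0, 10.0, _BLOCK_S),
    "exp2d": _preset("exp2d", 50.0, 0.22, 0.0, 2.5, 2.5, _BLOCK_S),
    "exp3": _preset(
        "exp3",
        50.0,
        0.40,
        0.10,
        3.5,
        3.5,
        _BLOCK_S,
        reference="difficult",
        mixed_subset="difficult",
    ),
}


@dataclass(frozen=True)
class RunConfig:
    """Settings for one pipeline run."""

    preset: str = "exp1"
    n_participants: int = 24
    n_blocks: int = 2
    seed: int = 0
    sigma_internal: float = 0.5
    sigma_drift: float = 0.0
    p_attend: float = 1.0
    nd_samples: int = 0
    duration_scale: float = 1.0  # shrink blocks for quick runs
    t_max: int = 100
    nd_threshold: float = 0.75
    nd_max_lag: int = 10
    alpha: float = 0.05
    n_boot: int | None = None  # None skips bootstrap CIs
    bic_margin: float = ms.DEFAULT_MARGIN

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def run_experiment_preset(
    name: str,
    config: RunConfig | None = None,
    **overrides,
) -> dict:
    """Run the full pipeline for one preset.

    Returns a bundle with the raw trial table, per-participant estimates
    (slope, intercept, coefficients, nondecision lag, exclusion flag,
    model comparison), and the cohort summary.
    """
    if name not in EXPERIMENT_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(EXPERIMENT_PRESETS)}")
    if config is None:
        config = RunConfig(preset=name, **overrides)
    elif overrides:
        raise TypeError("pass either a RunConfig or keyword overrides, not both")
    preset = EXPERIMENT_PRESETS[name]
    tasks = preset.tasks()

    # stage 1: optimal boundaries per condition
    boundaries = {
        cond: extract_boundary(solve_optimal_policy(task, t_max=config.t_max))
        for cond, task in tasks.items()
    }
    agents = {
        cond: AgentSpec(
            kind="threshold",
            boundary=boundaries[cond],
            sigma_internal=config.sigma_internal,
            sigma_drift=config.sigma_drift,
            p_attend=config.p_attend,
            nd_samples=config.nd_samples,
        )
        for cond in tasks
    }

    # stage 2: simulate the cohort
    plans = [
        BlockPlan(
            condition=cond,
            task=tasks[cond],
            duration=preset.durations[cond] * config.duration_scale,
            n_blocks=config.n_blocks,
        )
        for cond in ("easy", "difficult", "mixed")
    ]
    trials = simulate_cohort(
        config.n_participants,
        lambda p, cond, rng: agents[cond],
        plans,
        seed=config.seed,
    )

    # stage 3: per-participant inference
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ref = preset.reference_condition
    part_rows = []
    comp_rows = []
    for p, pdata in trials.groupby("participant"):
        nd_est = bi.estimate_nondecision(
            pdata[pdata["condition"] == "easy"],
            threshold=config.nd_threshold,
            max_lag=config.nd_max_lag,
        )
        stripped, _ = bi.strip_nondecision(pdata, nd_est.nd)
        excl = bi.binomial_exclusion_test(
            stripped[stripped["condition"] == "mixed"], alpha=config.alpha
        )
        for cond, keep in [
            (ref, None),
            ("mixed", preset.mixed_subset_drift),
        ]:
            table = bi.build_wait_go_table(stripped, condition=cond, keep_difficulty=keep)
            fit = bi.fit_waitgo_logistic(table)
            slope = bi.line_of_indifference(fit)
            ci = (np.nan, np.nan)
            if config.n_boot:
                ci = bi.bootstrap_slope_ci(
                    stripped,
                    n_boot=config.n_boot,
                    rng=rng,
                    condition=cond,
                    keep_difficulty=keep,
                )
            part_rows.append(
                {
                    "participant": p,
                    "condition": cond,
                    "beta0": fit.beta0,
                    "betaT": fit.betaT,
                    "betaX": fit.betaX,
                    "slope_deg": slope.slope_deg,
                    "intercept": slope.intercept,
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "nd": nd_est.nd,
                    "excluded": excl.excluded,
                }
            )
            comp = ms.compare_boundary_models(table, margin=config.bic_margin)
            comp_rows.append(
                {
                    "participant": p,
                    "condition": cond,
                    "bic_fixed": comp.bic_fixed,
                    "bic_varying": comp.bic_varying,
                    "delta_bic": comp.delta_bic,
                    "post_prob_varying": comp.post_prob_varying,
                    "winner": comp.winner,
                }
            )
    participants = pd.DataFrame(part_rows)
    comparisons = pd.DataFrame(comp_rows)
    summary = summarize_cohort(participants, reference_condition=ref)
    return {
        "preset": preset,
        "config": config,
        "trials": trials,
        "boundaries": boundaries,
        "participants": participants,
        "model_comparisons": comparisons,
        "summary": summary,
    }


def summarize_cohort(
    participants: pd.DataFrame,
    reference_condition: str = "easy",
    mixed_condition: str = "mixed",
) -> dict:
    """Cohort-level summary of per-participant slope estimates.

    Excluded participants are dropped; the mixed-vs-reference contrast is
    the circular slope difference per participant, tested against zero
    with a one-sample t test (equivalent to the paired test on
    conditions).  With zero variance across participants the t statistic
    is undefined and reported as NaN.
    """
    if participants["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants to summarize")
    n_excluded = int(
        participants.drop_duplicates("participant")["excluded"].sum()
    )
    kept = participants[~participants["excluded"]]
    if kept.empty:
        raise ValueError("no participants left after exclusions")
    wide = kept.pivot(index="participant", columns="condition", values="slope_deg")
    deltas = np.array(
        [
            bi.circular_slope_difference(e, m)
            for e, m in zip(wide[reference_condition], wide[mixed_condition])
        ]
    )
    if np.std(deltas, ddof=1) > 0:
        t_stat, p_val = stats.ttest_1samp(deltas, 0.0)
    else:
        t_stat, p_val = np.nan, np.nan
    return {
        "n_participants": int(participants["participant"].nunique()),
        "n_excluded": n_excluded,
        "mean_slope": {
            cond: float(kept[kept["condition"] == cond]["slope_deg"].mean())
            for cond in kept["condition"].unique()
        },
        "mean_delta_deg": float(deltas.mean()),
        "deltas_deg": deltas,
        "t_stat": float(t_stat) if np.isfinite(t_stat) else float("nan"),
        "df": len(deltas) - 1,
        "p_value": float(p_val) if np.isfinite(p_val) else float("nan"),
        "reference_condition": reference_condition,
    }
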