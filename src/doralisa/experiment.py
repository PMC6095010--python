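"""Longitudinal protocol: groups, knowledge schedules, phases and aggregation.

Simulated individuals differ only in top-down lateral inhibition, drawn once
per individual from the group's normal distribution (means 0.4 / 0.6 / 0.8,
SD 0.1) and treated as maturational: the same level governs both relational
learning and test-time reasoning.  Each individual learns over its own
100-object world, then solves eight test phases of 20 generated A:B::C:D
problems, using the representations learned up to the scheduled checkpoint —
100 x t at phase t for the low-knowledge schedule, 100 x t + 200 for the
high-knowledge schedule (which assumes more relational knowledge at study
entry).  Trial outcomes are classified as analogical (all required
transformations correctly inferred and bound), incomplete (some but not all),
or associative (none — including empty answers and bare object copies), and
pooled into group-level percentages and per-phase trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .learning import LearningConfig, run_learning_phase
from .mapping import AnswerRecord, OUTCOMES, build_knowledge, solve_problem
from .problems import generate_battery, generate_world

__all__ = [
    "GroupConfig",
    "GROUPS",
    "SolverParams",
    "sample_inhibition",
    "classify_counts",
    "classify_response",
    "run_simulation",
    "run_group",
    "SummaryTable",
    "aggregate",
]

#: Inhibition draws are clipped into this range; a normal with SD 0.1 can
#: stray outside the meaningful (0, 1] interval.
INHIBITION_CLIP = (0.05, 1.0)


@dataclass(frozen=True)
class GroupConfig:
    """One simulated group of the longitudinal study."""

    name: str
    inhibition_mean: float
    inhibition_sd: float = 0.1
    n_sims: int = 100
    n_phases: int = 8
    trials_per_phase: int = 20
    n_learning_trials: int = 800
    checkpoint_offset: int = 0  # 0 = low knowledge, 200 = high knowledge

    def phase_checkpoint(self, phase: int) -> int:
        """Learning-trial checkpoint used at test phase ``phase`` (1-based)."""
        if not 1 <= phase <= self.n_phases:
            raise ValueError(f"phase must lie in [1, {self.n_phases}]")
        trial = 100 * phase + self.checkpoint_offset
        if trial > self.n_learning_trials:
            raise ValueError(
                f"phase {phase} needs checkpoint {trial} but only "
                f"{self.n_learning_trials} trials are trained"
            )
        return trial


GROUPS: dict[str, GroupConfig] = {
    "low": GroupConfig("low", 0.4),
    "medium": GroupConfig("medium", 0.6),
    "high": GroupConfig("high", 0.8),
    "high_knowledge": GroupConfig(
        "high_knowledge", 0.8, n_learning_trials=1000, checkpoint_offset=200
    ),
}


@dataclass(frozen=True)
class SolverParams:
    """Test-time constants passed through to the mapping/inference engine."""

    n_passes: int = 2
    eta: float = 0.9
    response_noise: float = 0.1
    retrieval_threshold: float = 1.0
    winner_threshold: float = 0.3
    wm_bleed: float = 0.45


def sample_inhibition(group: GroupConfig, rng: np.random.Generator) -> float:
    """Draw one individual's lateral inhibition level for a group."""
    lam = rng.normal(group.inhibition_mean, group.inhibition_sd)
    return float(np.clip(lam, *INHIBITION_CLIP))


def classify_counts(n_correct: int, n_required: int) -> str:
    """Outcome class from correctly inferred transformation counts."""
    if n_required > 0 and n_correct == n_required:
        return "analogical"
    if n_correct > 0:
        return "incomplete"
    return "associative"


def classify_response(answer: AnswerRecord) -> str:
    """Classify a trial's generated D term against the correct answer.

    Analogical: every required transformation is present in D with the
    correct role-to-object assignment.  Incomplete: at least one but not all.
    Associative: none correct — empty answers and featural copies of B/C
    objects without correct relational structure land here.
    """
    return classify_counts(answer.n_correct, answer.n_instances)


def run_simulation(
    group: GroupConfig,
    learning: LearningConfig,
    solver: SolverParams,
    rng: np.random.Generator,
    sim_index: int = 0,
) -> list[dict]:
    """One simulated individual: sample inhibition, learn, then test 8 phases."""
    lam = sample_inhibition(group, rng)
    world = generate_world(rng=rng, inhibition=lam)
    cfg = replace(learning, n_trials=group.n_learning_trials)
    checkpoints = {
        c.trial: c for c in run_learning_phase(world, cfg, lam, rng)
    }
    rows: list[dict] = []
    for phase in range(1, group.n_phases + 1):
        trial_ckpt = group.phase_checkpoint(phase)
        knowledge = build_knowledge(
            checkpoints[trial_ckpt], solver.retrieval_threshold
        )
        battery = generate_battery(group.trials_per_phase, rng)
        for item, problem in enumerate(battery):
            answer = solve_problem(
                problem,
                knowledge,
                lam,
                rng=rng,
                n_passes=solver.n_passes,
                eta=solver.eta,
                response_noise=solver.response_noise,
                retrieval_threshold=solver.retrieval_threshold,
                winner_threshold=solver.winner_threshold,
                wm_bleed=solver.wm_bleed,
            )
            rows.append(
                {
                    "group": group.name,
                    "sim": sim_index,
                    "inhibition": lam,
                    "phase": phase,
                    "checkpoint": trial_ckpt,
                    "item": item,
                    "difficulty_class": problem.difficulty_class,
                    "n_transformations": problem.n_transformations,
                    "difficulty": problem.difficulty,
                    "n_correct": answer.n_correct,
                    "outcome": classify_response(answer),
                }
            )
    return rows


def run_group(
    group: GroupConfig | str,
    n_sims: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
    learning: LearningConfig | None = None,
    solver: SolverParams | None = None,
) -> pd.DataFrame:
    """Run a full group: ``n_sims`` individuals x 8 phases x 20 trials.

    Every individual gets an independent child seed of ``seed``, so reduced
    and full runs with the same seed share their leading individuals.
    Returns one row per classified trial.
    """
    if isinstance(group, str):
        group = GROUPS[group]
    if n_sims is not None:
        group = replace(group, n_sims=n_sims)
    learning = learning or LearningConfig()
    solver = solver or SolverParams()
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rows: list[dict] = []
    for sim_index, child in enumerate(seed_seq.spawn(group.n_sims)):
        rng = np.random.default_rng(child)
        rows.extend(run_simulation(group, learning, solver, rng, sim_index))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SummaryTable:
    """Pooled solution-type percentages and learning trajectories per group."""

    summary: pd.DataFrame      # group x outcome -> percentage (pooled phases)
    trajectories: pd.DataFrame  # group x phase -> proportion per outcome
    by_difficulty: pd.DataFrame  # group x difficulty class -> prop analogical

    def percentage(self, group: str, outcome: str) -> float:
        return float(self.summary.loc[group, outcome])


def aggregate(results: pd.DataFrame) -> SummaryTable:
    """Pool classified trials into the summary table and trajectory series.

    The summary pools all phases and individuals of a group into one
    percentage per solution type (rows sum to 100).  Trajectories give the
    per-phase proportion of each outcome; the difficulty breakdown gives the
    proportion of analogical solutions per difficulty class.
    """
    if results.empty:
        raise ValueError("no completed trials to aggregate")
    counts = (
        results.groupby(["group", "outcome"]).size().unstack(fill_value=0)
    )
    for outcome in OUTCOMES:
        if outcome not in counts:
            counts[outcome] = 0
    counts = counts[list(OUTCOMES)]
    summary = counts.div(counts.sum(axis=1), axis=0) * 100.0
    traj = (
        results.groupby(["group", "phase", "outcome"]).size()
        .unstack(fill_value=0)
        .pipe(lambda df: df.div(df.sum(axis=1), axis=0))
        .reset_index()
    )
    for outcome in OUTCOMES:
        if outcome not in traj:
            traj[outcome] = 0.0
    diff = (
        results.assign(analogical=lambda df: df["outcome"] == "analogical")
        .groupby(["group", "difficulty_class"])["analogical"]
        .mean()
        .reset_index(name="prop_analogical")
    )
    return SummaryTable(summary, traj, diff)
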