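"""Comparison-based relational learning and the representation-quality metric.

Learning is driven by comparison: when two items are compared, their shared
semantic features receive input from both and become roughly twice as active
as unshared features.  A newly recruited predicate PO learns connections to
the active semantics by simple Hebbian learning, so it codes the featural
overlap of the compared items (e.g. the role *inside* when two contained
objects are compared), together with an RB unit binding the new predicate to
each compared object.  When two learned predicates are compared, the same
rule sharpens the overlap: defining semantics stay strong while accidental
ones decay — refinement.  When two role-filler sets co-occur in working
memory, a P unit is recruited over their RBs, yielding a multi-place relation.

Working-memory competition makes learning sensitive to lateral inhibition in
two ways.  First, the comparison partner is chosen by recipient competition:
with weak inhibition the partner is near-random, so mismatched items are
compared and the resulting predicates split their weights over accidental
overlap.  Second, unselected items still resident in working memory are
imperfectly suppressed: their semantics bleed into the Hebbian pass at a
level proportional to (1 - lambda), contaminating new predicates.  Both
pathways make low-inhibition learners accumulate "dirty" representations.

Representation quality of a predicate is the mean connection weight to the
semantics defining its transformation (or role) divided by (mean of all other
nonzero connection weights + 1); the +1 bounds quality in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import problems as pb
from .dynamics import RECENCY_PENALTY, recipient_response, sample_winner, select_for_wm
from .representations import LTM, Network, Token

__all__ = [
    "LearningConfig",
    "Checkpoint",
    "QualityReport",
    "coactive_semantics",
    "predicate_from_comparison",
    "form_relation",
    "quality",
    "quality_from_weights",
    "best_target",
    "run_learning_phase",
    "RelationLearner",
]


@dataclass(frozen=True)
class LearningConfig:
    """Parameters of the unstructured learning protocol.

    gamma
        Hebbian learning rate in (0, 1]; with the default 1.0 a single
        comparison saturates connections to fully shared semantics.
    n_trials, checkpoint_every
        Total learning trials and the checkpoint interval.
    items_min, items_max
        Per trial, between 2 and 6 items are sampled from long-term memory
        and compared pairwise.
    relevance_threshold
        A predicate counts as relevant to a transformation once every
        defining semantic of one of its roles is connected above this weight.
    relevance_mix
        After the unstructured opening period, probability that a trial
        samples among relevant learned predicates (refinement) instead of
        uniformly over objects.
    unstructured_trials
        Length of the opening period during which only objects are sampled.
    wm_bleed
        Scale of working-memory bleed-through: unselected items' semantics
        enter the Hebbian pass at activation wm_bleed * (1 - lambda).
    prune_fraction
        Connections weaker than this fraction of the predicate's strongest
        connection are dropped after each Hebbian pass (weak, unreinforced
        connections do not survive).
    """

    gamma: float = 1.0
    n_trials: int = 800
    checkpoint_every: int = 100
    items_min: int = 2
    items_max: int = 6
    relevance_threshold: float = 0.9
    relevance_mix: float = 0.5
    unstructured_trials: int = 100
    wm_bleed: float = 0.7
    prune_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if not 2 <= self.items_min <= self.items_max <= 6:
            raise ValueError("items per trial must stay within [2, 6]")
        if self.n_trials < self.checkpoint_every:
            raise ValueError("n_trials must cover at least one checkpoint")


def coactive_semantics(a: Token, b: Token) -> dict[int, float]:
    """Semantic activation pattern when two POs are compared (co-active).

    Each semantic receives the summed input of both items' connection
    weights; activations are normalized so that a feature fully shared by
    both items is at 1.0 and (for unit-weight items) an unshared feature at
    0.5 — shared semantics are roughly twice as active as unshared ones.
    Fully disjoint items yield a uniform pattern (no shared structure).
    """
    if a.layer != "PO" or b.layer != "PO":
        raise ValueError("comparison operates on PO units")
    top = max(max(a.down.values(), default=0.0), max(b.down.values(), default=0.0))
    if top <= 0.0:
        return {}
    denom = 2.0 * top
    act: dict[int, float] = {}
    for sem, w in a.down.items():
        act[sem] = w / denom
    for sem, w in b.down.items():
        act[sem] = act.get(sem, 0.0) + w / denom
    return act


def predicate_from_comparison(
    net: Network,
    a: Token,
    b: Token,
    gamma: float = 1.0,
    *,
    pred: Token | None = None,
    bleed: tuple[Iterable[int], float] | None = None,
    sharpen: float = 1.0,
    prune_fraction: float = 0.0,
) -> Token:
    """Recruit (or update) a predicate PO from the comparison of two POs.

    The predicate learns one Hebbian pass: delta_w(s) = gamma * activation(s),
    accumulated onto any existing weight and clipped at 1.  When both
    compared items are objects, an RB is recruited binding the new predicate
    to each of them.  ``bleed`` optionally injects the semantics of other,
    imperfectly inhibited working-memory items at a fixed activation floor;
    ``sharpen`` raises the activation pattern to a power (competition in the
    semantic layer: > 1 suppresses weakly active semantics).  Weights below
    ``prune_fraction`` of the strongest learned weight are dropped.
    """
    act = coactive_semantics(a, b)
    if bleed is not None:
        sems, level = bleed
        if level > 0.0:
            for sem in sems:
                if act.get(sem, 0.0) < level:
                    act[sem] = level
    if sharpen != 1.0:
        act = {s: v**sharpen for s, v in act.items()}
    if pred is None:
        analog = net.new_analog(LTM)
        pred = net.add_po(analog.id, "predicate", {})
        if a.is_object and b.is_object:
            net.add_rb(analog.id, pred.id, a.id)
            net.add_rb(analog.id, pred.id, b.id)
    for sem, activation in act.items():
        w = pred.down.get(sem, 0.0) + gamma * activation
        pred.down[sem] = min(1.0, w)
    if pred.down and prune_fraction > 0.0:
        cutoff = prune_fraction * max(pred.down.values())
        for sem in [s for s, w in pred.down.items() if w < cutoff]:
            del pred.down[sem]
    return pred


def form_relation(net: Network, rb_ids: Sequence[int], analog_id: int) -> Token | None:
    """Recruit a P unit over co-firing, cross-mapped role-filler sets.

    Requires at least two RBs co-selected in working memory; with fewer this
    is a no-op (a single role-filler pair carries no multi-place structure).
    The new P learns saturated (weight 1.0) connections to every RB, encoding
    a multi-place relation such as ``contains(object1, object2)``.
    """
    if len(rb_ids) < 2:
        return None
    return net.add_p(analog_id, rb_ids)


def quality_from_weights(
    weights: Mapping[int, float], relevant_ids: Iterable[int]
) -> float:
    """Quality of a weight vector relative to a defining semantic set."""
    relevant = list(relevant_ids)
    if not relevant:
        raise ValueError("relevant semantic set must be non-empty")
    rel_mean = sum(weights.get(s, 0.0) for s in relevant) / len(relevant)
    others = [w for s, w in weights.items() if s not in set(relevant) and w > 0.0]
    other_mean = sum(others) / len(others) if others else 0.0
    return rel_mean / (other_mean + 1.0)


def quality(pred: Token, relevant_ids: Iterable[int]) -> float:
    """Representation quality of a predicate relative to defining semantics.

    Q = mean(w over relevant semantics) / (mean(other nonzero weights) + 1).
    Absent relevant connections count as weight 0; a predicate with no other
    connections has denominator 1.  Bounded in [0, 1].
    """
    if not pred.is_predicate:
        raise ValueError("quality is defined for predicate POs")
    return quality_from_weights(pred.down, relevant_ids)


def best_target(weights: Mapping[int, float]) -> tuple[str, float]:
    """The transformation role a predicate codes most strongly.

    Returns (role name, summed weight to that role's defining semantics);
    ties break toward the first listed role.
    """
    best_name = pb.ROLE_NAMES[0]
    best_sum = -1.0
    for name in pb.ROLE_NAMES:
        total = sum(weights.get(s, 0.0) for s in pb.ROLE_SEMANTICS[name])
        if total > best_sum:
            best_name, best_sum = name, total
    return best_name, best_sum


def _relevant_roles(pred: Token, threshold: float) -> list[str]:
    """Roles whose every defining semantic the predicate connects above threshold."""
    return [
        role
        for role, sems in pb.ROLE_SEMANTICS.items()
        if all(pred.down.get(s, 0.0) > threshold for s in sems)
    ]


@dataclass(frozen=True)
class Checkpoint:
    """Snapshot of the learned predicate inventory after a number of trials."""

    trial: int
    predicates: dict[int, dict[int, float]]
    qualities: dict[int, float]

    @property
    def mean_quality(self) -> float:
        if not self.qualities:
            return float("nan")
        return float(np.mean(list(self.qualities.values())))


@dataclass(frozen=True)
class QualityReport:
    """Per-checkpoint mean representation quality for one learning run."""

    inhibition: float
    checkpoints: tuple[Checkpoint, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "checkpoint": [c.trial for c in self.checkpoints],
                "n_predicates": [len(c.predicates) for c in self.checkpoints],
                "mean_quality": [c.mean_quality for c in self.checkpoints],
            }
        )


def _snapshot(net: Network, trial: int, predicate_ids: Sequence[int]) -> Checkpoint:
    preds = {}
    quals = {}
    for pid in predicate_ids:
        tok = net.tokens[pid]
        preds[pid] = dict(tok.down)
        name, _ = best_target(tok.down)
        quals[pid] = quality(tok, pb.ROLE_SEMANTICS[name])
    return Checkpoint(trial, preds, quals)


def run_learning_phase(
    net: Network,
    cfg: LearningConfig,
    inhibition: float,
    rng: np.random.Generator,
) -> list[Checkpoint]:
    """Run unstructured comparison-based learning over an object world.

    Per trial, 2-6 items are sampled from long-term memory — uniformly over
    objects during the opening period, thereafter with probability
    ``relevance_mix`` among relevant learned predicates (refinement;
    relevance is strong connection to the semantics defining a specific
    relation or role) — and compared pairwise under working-memory
    competition at the given lateral inhibition.  New predicates (and, for
    complementary containment roles learned in one trial, P units) are added
    back to memory and become available for later comparisons.  Returns a
    checkpoint every ``checkpoint_every`` trials.
    """
    object_ids = [
        t.id for t in net.tokens.values() if t.is_object
    ]
    if not object_ids:
        raise ValueError("the world must contain object POs before learning")
    bleed_level = cfg.wm_bleed * (1.0 - inhibition)
    sharpen = 1.0 + inhibition
    predicate_ids: list[int] = []
    relevant_ids: list[int] = []
    relevant_seen: set[int] = set()
    checkpoints: list[Checkpoint] = []
    for trial in range(1, cfg.n_trials + 1):
        m = int(rng.integers(cfg.items_min, cfg.items_max + 1))
        use_relevant = (
            trial > cfg.unstructured_trials
            and len(relevant_ids) >= 2
            and rng.random() < cfg.relevance_mix
        )
        if use_relevant:
            pool = relevant_ids
            k = min(m, len(pool))
            items = [pool[int(i)]
                     for i in rng.choice(len(pool), size=k, replace=False)]
        else:
            items = [object_ids[int(i)]
                     for i in rng.choice(len(object_ids), size=m, replace=False)]
        remaining = list(items)
        last_fired: int | None = None
        new_rbs_by_role: dict[str, int] = {}
        while len(remaining) >= 2:
            support = {
                i: (RECENCY_PENALTY if i == last_fired else 1.0) for i in remaining
            }
            focal = select_for_wm(remaining, support, inhibition, rng)
            others = [i for i in remaining if i != focal]
            act = recipient_response(
                net.tokens[focal].down,
                {i: net.tokens[i].down for i in others},
                inhibition,
            )
            partner = sample_winner(act, rng)
            if partner is None:
                partner = others[int(rng.integers(len(others)))]
            bystanders = [i for i in items if i not in (focal, partner)]
            bleed_sems: set[int] = set()
            if bleed_level >= cfg.prune_fraction * cfg.gamma:
                for i in bystanders:
                    bleed_sems.update(net.tokens[i].down)
            pred = predicate_from_comparison(
                net,
                net.tokens[focal],
                net.tokens[partner],
                cfg.gamma,
                bleed=(bleed_sems, bleed_level),
                sharpen=sharpen,
                prune_fraction=cfg.prune_fraction,
            )
            predicate_ids.append(pred.id)
            roles = _relevant_roles(pred, cfg.relevance_threshold)
            if roles and pred.id not in relevant_seen:
                relevant_seen.add(pred.id)
                relevant_ids.append(pred.id)
            if roles:
                name, _ = best_target(pred.down)
                if name in pb.BINARY.roles:
                    rbs = [
                        t.id
                        for t in net.analog_tokens(pred.analog_id, "RB")
                    ]
                    if rbs:
                        new_rbs_by_role[name] = rbs[0]
            last_fired = focal
            remaining.remove(focal)
            remaining.remove(partner)
        if len(new_rbs_by_role) == 2:
            # Both containment roles predicated in one trial: their role-filler
            # sets co-occupied working memory, signalling whole-relation
            # formation.
            rb_ids = [new_rbs_by_role[r] for r in pb.BINARY.roles]
            analog_id = net.tokens[rb_ids[0]].analog_id
            form_relation(net, rb_ids, analog_id)
        if trial % cfg.checkpoint_every == 0:
            checkpoints.append(_snapshot(net, trial, predicate_ids))
    return checkpoints


class RelationLearner(BaseEstimator):
    """Learn structured relational predicates from an unstructured object world.

    A scikit-learn style estimator: ``fit`` takes a world
    (:func:`doralisa.problems.generate_world` network; one is generated when
    ``X`` is None) and runs comparison-based learning at the configured
    lateral inhibition, exposing the learned network and per-checkpoint
    quality as fitted attributes.

    Parameters mirror :class:`LearningConfig` plus:

    inhibition
        Top-down lateral inhibition lambda in (0, 1] of the simulated
        individual (maturational; fixed across learning and reasoning).
    random_state
        Seed or generator controlling every source of randomness.

    Attributes
    ----------
    network_ : Network
        The world network including all recruited predicates, RBs and Ps.
    checkpoints_ : list[Checkpoint]
        Predicate snapshots every ``checkpoint_every`` trials.
    quality_report_ : QualityReport
        Mean representation quality per checkpoint.
    """

    def __init__(
        self,
        inhibition: float = 0.8,
        gamma: float = 1.0,
        n_trials: int = 800,
        checkpoint_every: int = 100,
        items_min: int = 2,
        items_max: int = 6,
        relevance_threshold: float = 0.9,
        relevance_mix: float = 0.5,
        unstructured_trials: int = 100,
        wm_bleed: float = 0.7,
        prune_fraction: float = 0.3,
        random_state: int | np.random.Generator | None = None,
    ) -> None:
        self.inhibition = inhibition
        self.gamma = gamma
        self.n_trials = n_trials
        self.checkpoint_every = checkpoint_every
        self.items_min = items_min
        self.items_max = items_max
        self.relevance_threshold = relevance_threshold
        self.relevance_mix = relevance_mix
        self.unstructured_trials = unstructured_trials
        self.wm_bleed = wm_bleed
        self.prune_fraction = prune_fraction
        self.random_state = random_state

    def _config(self) -> LearningConfig:
        return LearningConfig(
            gamma=self.gamma,
            n_trials=self.n_trials,
            checkpoint_every=self.checkpoint_every,
            items_min=self.items_min,
            items_max=self.items_max,
            relevance_threshold=self.relevance_threshold,
            relevance_mix=self.relevance_mix,
            unstructured_trials=self.unstructured_trials,
            wm_bleed=self.wm_bleed,
            prune_fraction=self.prune_fraction,
        )

    def fit(self, X: Network | None = None, y=None) -> "RelationLearner":
        rng = np.random.default_rng(self.random_state)
        net = X if X is not None else pb.generate_world(rng=rng)
        cfg = self._config()
        self.checkpoints_ = run_learning_phase(net, cfg, self.inhibition, rng)
        self.network_ = net
        self.quality_report_ = QualityReport(
            self.inhibition, tuple(self.checkpoints_)
        )
        return self

    def checkpoint_at(self, trial: int) -> Checkpoint:
        check_is_fitted(self, "checkpoints_")
        for ckpt in self.checkpoints_:
            if ckpt.trial == trial:
                return ckpt
        raise KeyError(f"no checkpoint at trial {trial}")
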