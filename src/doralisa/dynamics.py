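"""Activation dynamics: asynchronous binding and inhibition-controlled competition.

Two competitions are governed by the top-down lateral inhibition parameter
lambda.  In the driver, propositions compete to enter working memory; in the
recipient, units compete to respond to the semantic pattern imposed by the
driver.  Both competitions are sharpened by lateral inhibition: at lambda
near 1 they approach winner-take-all, at lambda near 0 selection becomes
nearly random ("reduced competition and more random selection").

Rather than integrating oscillator differential equations, firing is modelled
as an ordered sequence of discrete slots with algebraic competition.  Binding
information is carried by firing order: within each role-filler pair, the role
PO fires in the slot directly before its filler, and distinct pairs occupy
disjoint slots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .representations import Network, P, PO, RB, Token

__all__ = [
    "CompetitionParams",
    "FiringSlot",
    "FiringSchedule",
    "temperature",
    "select_for_wm",
    "fire_sequence",
    "recipient_response",
    "sample_winner",
]

#: Floor keeping the selection temperature finite at lambda = 1.
TEMPERATURE_EPS = 0.01

#: Normalized activation above which a unit counts as a clear winner.
WINNER_THRESHOLD = 0.5

#: Multiplicative support penalty for the most recently fired proposition.
RECENCY_PENALTY = 0.5


def temperature(inhibition: float) -> float:
    """Selection temperature tau(lambda) = (1 - lambda) + eps.

    Strictly decreasing in lambda: strong inhibition means sharp, nearly
    deterministic competition, weak inhibition means soft, noisy competition.
    """
    if not 0.0 < inhibition <= 1.0:
        raise ValueError("inhibition must lie in (0, 1]")
    return (1.0 - inhibition) + TEMPERATURE_EPS


@dataclass(frozen=True)
class CompetitionParams:
    """Lateral inhibition level and its derived selection temperature."""

    inhibition: float

    @property
    def tau(self) -> float:
        return temperature(self.inhibition)


def select_for_wm(
    candidates: Sequence[int],
    support: Mapping[int, float],
    inhibition: float,
    rng: np.random.Generator,
) -> int:
    """Choose which driver proposition enters working memory.

    Samples from a softmax over support scores with temperature tau(lambda):
    as lambda -> 1 selection approaches the argmax, as lambda -> 0 it
    approaches a uniform draw.  Support reflects pragmatic centrality and
    recency; the caller supplies the scores.
    """
    if len(candidates) == 0:
        raise ValueError("cannot select from an empty driver")
    tau = temperature(inhibition)
    scores = np.array([support.get(c, 1.0) for c in candidates], dtype=float)
    logits = (scores - scores.max()) / tau
    probs = np.exp(logits)
    probs /= probs.sum()
    return candidates[int(rng.choice(len(candidates), p=probs))]


@dataclass(frozen=True)
class FiringSlot:
    """One time slot: a single PO fires together with its semantic footprint."""

    token_id: int
    kind: str  # "role" | "filler"
    rb_id: int
    footprint: Mapping[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class FiringSchedule:
    """Ordered firing slots for one proposition (asynchronous binding)."""

    top_id: int
    slots: tuple[FiringSlot, ...]

    def __iter__(self):
        return iter(self.slots)

    def __len__(self) -> int:
        return len(self.slots)


def fire_sequence(net: Network, top_id: int) -> FiringSchedule:
    """Expand a proposition into its asynchronous role/filler firing order.

    For each RB (in the P unit's connection order) the role PO fires in one
    slot and its filler object PO in the directly following slot; role-filler
    pairs of distinct RBs never share a slot.  The semantic footprint of a
    slot is the firing PO's downward weight vector.
    """
    top = net.tokens[top_id]
    if top.layer == P:
        rb_ids = sorted(top.down)
    elif top.layer == RB:
        rb_ids = [top.id]
    else:
        raise ValueError(f"token {top_id} is not a proposition or RB")
    slots: list[FiringSlot] = []
    for rb_id in rb_ids:
        pred, obj = net.rb_children(rb_id)
        slots.append(FiringSlot(pred.id, "role", rb_id, dict(pred.down)))
        slots.append(FiringSlot(obj.id, "filler", rb_id, dict(obj.down)))
    return FiringSchedule(top_id, tuple(slots))


def recipient_response(
    footprint: Mapping[int, float],
    recipient_weights: Mapping[int, Mapping[int, float]],
    inhibition: float,
    extra_input: Mapping[int, float] | None = None,
) -> dict[int, float]:
    """Activations of recipient units competing to respond to a firing pattern.

    The raw input to each recipient unit is the overlap between the driver's
    semantic footprint and the unit's own downward weights (plus optional
    structural top-down input supplied by the caller).  Units then compete
    divisively with sharpness set by lateral inhibition::

        a_i = in_i^(1/tau) / sum_j in_j^(1/tau)

    At high lambda this approaches winner-take-all; at low lambda activation
    spreads over every unit with nonzero input.  An empty recipient or an
    all-zero input yields an all-zero map.
    """
    exponent = 1.0 / temperature(inhibition)
    raw: dict[int, float] = {}
    for tid, weights in recipient_weights.items():
        total = 0.0
        if len(footprint) <= len(weights):
            for sem, w in footprint.items():
                total += w * weights.get(sem, 0.0)
        else:
            for sem, w in weights.items():
                total += w * footprint.get(sem, 0.0)
        if extra_input is not None:
            total += extra_input.get(tid, 0.0)
        raw[tid] = total
    top = max(raw.values(), default=0.0)
    if top <= 0.0:
        return {tid: 0.0 for tid in raw}
    norm = 0.0
    powered: dict[int, float] = {}
    for tid, value in raw.items():
        a = (value / top) ** exponent if value > 0.0 else 0.0
        powered[tid] = a
        norm += a
    return {tid: a / norm for tid, a in powered.items()}


def sample_winner(
    activations: Mapping[int, float],
    rng: np.random.Generator,
) -> int | None:
    """Resolve a competition by sampling proportionally to activation.

    Returns ``None`` when nothing responds (all activations zero).  With
    sharp activations this is effectively the argmax; with diffuse
    activations (weak inhibition) the outcome is noisy — the mechanism by
    which low inhibition lets the "wrong" unit respond.
    """
    ids = list(activations)
    if not ids:
        return None
    weights = np.array([activations[i] for i in ids], dtype=float)
    total = weights.sum()
    if total <= 0.0:
        return None
    return ids[int(rng.choice(len(ids), p=weights / total))]
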