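"""Analogical mapping and self-supervised inference of the missing D term.

Driver and recipient communicate only through the shared semantic pool: as a
driver proposition fires (role before filler, pair by pair), recipient units
compete via lateral inhibition to respond, and mapping connections are
learned Hebbianly between units that are active together, with subtractive
normalization against competing mapping hypotheses.  Because fillers become
active in the slot directly after their role, object mapping is carried by
structure: the recipient objects bound to the role that just responded
receive top-down support, so featurally disjoint fillers bound to the same
learned role map to each other.

When a driver role-filler pair has nothing left to respond to (its natural
correspondent is already claimed by another mapped structure), self-supervised
learning recruits matching units in the recipient: a new RB, a predicate PO
image learned from the active driver semantics, and — where the driver object
is mapped — the mapped recipient object as filler.  Applied to an A:B::C:D
problem with A and B in the driver and C in the recipient, the recruits are
the model's generated D term.

The A-to-C correspondence is never given: it must be discovered by the
mapping process, and failure to discover it makes generation of D all but
impossible (the inferred structure is then empty or fragmentary, scored as an
associative or incomplete solution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping as TMapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import problems as pb
from .dynamics import (
    RECENCY_PENALTY,
    WINNER_THRESHOLD,
    FiringSchedule,
    FiringSlot,
    fire_sequence,
    recipient_response,
    sample_winner,
    select_for_wm,
)
from .learning import Checkpoint, best_target, quality_from_weights
from .representations import DRIVER, Network, P, PO, RB, RECIPIENT, Token

__all__ = [
    "Mapping",
    "InferredRB",
    "AnswerRecord",
    "build_knowledge",
    "encode_problem",
    "map_analogs",
    "infer_missing",
    "solve_problem",
    "AnalogySolver",
    "OUTCOMES",
]

OUTCOMES = ("analogical", "incomplete", "associative")

#: Top-down input a recipient object receives when bound (in the recipient)
#: to the role unit that won the directly preceding slot.
STRUCTURAL_SUPPORT = 1.3

#: Spontaneous background input every recipient unit receives while a driver
#: pattern fires.  With strong inhibition it is competed away; with weak
#: inhibition it lets unrelated units respond — the "many units responding"
#: failure mode of a compromised recipient.
RESPONSE_NOISE = 0.1

#: Fraction of the strongest response a sampled recipient responder must
#: reach to count as a clear winner of a slot's competition; below it the
#: slot ends with no unit responding and no mapping update.
CLEAR_WINNER_FRACTION = 0.3

#: Input a recipient unit receives per unit of existing mapping weight to the
#: firing driver unit.  This feedback keeps developing mappings coherent and
#: breaks ties between indistinguishable recipient candidates: once one
#: hypothesis wins a competition, it reinforces itself on later passes.
MAPPING_FEEDBACK = 1.0

@dataclass
class Mapping:
    """Mapping connections and their one-to-one winner assignment per layer."""

    weights: dict[tuple[int, int], float] = field(default_factory=dict)
    winners: dict[int, int] = field(default_factory=dict)  # driver id -> recipient id

    def winner_of(self, driver_id: int) -> int | None:
        return self.winners.get(driver_id)


def _hebbian_update(
    weights: dict[tuple[int, int], float],
    driver_id: int,
    activations: TMapping[int, float],
    winner: int,
    eta: float,
) -> None:
    """One mapping-learning step with subtractive normalization.

    delta m(d, r) = eta * (a_d a_r - a_d max_other_m), where max_other_m is
    the strongest competing hypothesis involving either unit; weights are
    clipped to [0, 1].  The sampled winner counts as the co-active unit.
    """
    row_max: dict[int, float] = {}
    col_max: dict[int, float] = {}
    for (d, r), w in weights.items():
        if w > row_max.get(d, 0.0):
            row_max[d] = w
        if w > col_max.get(r, 0.0):
            col_max[r] = w

    def competing(d: int, r: int) -> float:
        comp = 0.0
        for (dd, rr), w in weights.items():
            if dd == d and rr != r and w > comp:
                comp = w
            elif rr == r and dd != d and w > comp:
                comp = w
        return comp

    for r in activations:
        a_r = 1.0 if r == winner else 0.0
        key = (driver_id, r)
        if a_r == 0.0 and key not in weights:
            continue
        delta = eta * (a_r - competing(driver_id, r))
        new = min(1.0, max(0.0, weights.get(key, 0.0) + delta))
        if new > 0.0:
            weights[key] = new
        elif key in weights:
            del weights[key]


def _assign_winners(
    net: Network, weights: TMapping[tuple[int, int], float]
) -> dict[int, int]:
    """Row-wise argmax subject to a one-to-one constraint within each layer.

    Pairs are taken greedily by descending weight; ties break by weight then
    lowest (driver, recipient) id.
    """
    pairs = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    taken_d: set[int] = set()
    taken_r: set[int] = set()
    winners: dict[int, int] = {}
    for (d, r), w in pairs:
        if w <= 0.0 or d in taken_d or r in taken_r:
            continue
        if net.tokens[d].layer != net.tokens[r].layer:
            continue
        winners[d] = r
        taken_d.add(d)
        taken_r.add(r)
    return winners


def _order_props(
    props: Sequence[int],
    inhibition: float,
    rng: np.random.Generator,
    last_fired: int | None,
) -> tuple[list[int], int | None]:
    """One full driver cycle: every proposition fires once, order by WM competition."""
    order: list[int] = []
    remaining = list(props)
    while remaining:
        support = {
            p: (RECENCY_PENALTY if p == last_fired else 1.0) for p in remaining
        }
        nxt = select_for_wm(remaining, support, inhibition, rng)
        order.append(nxt)
        remaining.remove(nxt)
        last_fired = nxt
    return order, last_fired


def map_analogs(
    net: Network,
    driver_id: int,
    recipient_id: int,
    inhibition: float,
    n_passes: int = 2,
    rng: np.random.Generator | None = None,
    eta: float = 0.9,
    response_noise: float = RESPONSE_NOISE,
    winner_threshold: float = CLEAR_WINNER_FRACTION,
    driver_bleed: float = 0.0,
) -> Mapping:
    """Learn mapping connections between driver and recipient banks.

    ``driver_bleed`` models imperfect suppression of the rest of the driver
    while one unit fires: every slot's semantic footprint is contaminated by
    the other driver POs' semantics at that fraction of their weight.  With
    weak lateral inhibition the driver's firing pattern is therefore smeared
    over the whole bank, and the more cluttered the representations, the
    harder the recipient competition becomes.

    Runs ``n_passes`` full driver cycles.  Per cycle, each driver proposition
    is selected into working memory (competition with recency support) and
    fired slot by slot; recipient POs compete to respond to each slot's
    semantic footprint (with structural top-down support for fillers,
    feedback from already-formed mapping connections, and a
    spontaneous-activity floor), and the sampled responder — when it is a
    clear winner, activation at least ``winner_threshold`` of the strongest
    response — is linked to the firing unit by the Hebbian rule with
    subtractive normalization.  RB- and P-layer connections are updated when
    their children responded consistently.  Returns the mapping with its
    one-to-one winner assignment.
    """
    if not net.analogs[driver_id].token_ids or not net.analogs[recipient_id].token_ids:
        raise ValueError("driver and recipient banks must be non-empty")
    rng = np.random.default_rng(rng)
    props = [t.id for t in net.top_tokens(driver_id)]
    mapping = Mapping()
    if not props:
        return mapping
    rec_pos = {
        t.id: t.down for t in net.analog_tokens(recipient_id, PO)
    }
    rec_rbs = net.analog_tokens(recipient_id, RB)
    rec_ps = net.analog_tokens(recipient_id, P)
    smear: dict[int, float] = {}
    if driver_bleed > 0.0:
        for t in net.analog_tokens(driver_id, PO):
            for sem, w in t.down.items():
                v = driver_bleed * w
                if v > smear.get(sem, 0.0):
                    smear[sem] = v
    last_fired: int | None = None
    for _ in range(n_passes):
        order, last_fired = _order_props(props, inhibition, rng, last_fired)
        for top_id in order:
            schedule = fire_sequence(net, top_id)
            if smear:
                schedule = FiringSchedule(
                    schedule.top_id,
                    tuple(
                        FiringSlot(
                            s.token_id,
                            s.kind,
                            s.rb_id,
                            {
                                sem: max(s.footprint.get(sem, 0.0), v)
                                for sem, v in smear.items()
                            } | {
                                sem: w
                                for sem, w in s.footprint.items()
                                if w >= smear.get(sem, 0.0)
                            },
                        )
                        for s in schedule
                    ),
                )
            role_winner: int | None = None
            rb_images: dict[int, int] = {}  # driver rb -> recipient rb winner
            coherent_p: Token | None = None  # recipient P already engaged by this firing
            for slot in schedule:
                extra = {
                    tid: response_noise
                    + MAPPING_FEEDBACK
                    * mapping.weights.get((slot.token_id, tid), 0.0)
                    for tid in rec_pos
                }
                if slot.kind == "filler" and role_winner is not None:
                    for rb in rec_rbs:
                        if role_winner in rb.down:
                            for cid in rb.down:
                                if cid != role_winner and net.tokens[cid].is_object:
                                    extra[cid] = extra.get(cid, 0.0) + STRUCTURAL_SUPPORT
                if slot.kind == "role" and coherent_p is not None:
                    # Top-down support from the recipient proposition already
                    # engaged by this firing: its remaining role units are
                    # primed, keeping role-filler pairs of one driver
                    # proposition aligned with one recipient proposition.
                    matched_rbs = set(rb_images.values())
                    for rid in coherent_p.down:
                        if rid in matched_rbs:
                            continue
                        for cid in net.tokens[rid].down:
                            if net.tokens[cid].is_predicate:
                                extra[cid] = extra.get(cid, 0.0) + STRUCTURAL_SUPPORT
                act = recipient_response(
                    slot.footprint, rec_pos, inhibition, extra_input=extra
                )
                winner = sample_winner(act, rng)
                clear = (
                    winner is not None
                    and act[winner] >= winner_threshold * max(act.values())
                )
                if clear:
                    _hebbian_update(
                        mapping.weights, slot.token_id, act, winner, eta
                    )
                if slot.kind == "role":
                    role_winner = winner if clear else None
                else:
                    if clear and role_winner is not None:
                        for rb in rec_rbs:
                            if role_winner in rb.down and winner in rb.down:
                                rb_images[slot.rb_id] = rb.id
                                _hebbian_update(
                                    mapping.weights,
                                    slot.rb_id,
                                    {rb.id: 1.0},
                                    rb.id,
                                    eta,
                                )
                                if coherent_p is None:
                                    for rp in rec_ps:
                                        if rb.id in rp.down:
                                            coherent_p = rp
                                            break
                                break
                    role_winner = None
            top = net.tokens[top_id]
            if top.layer == P and rb_images:
                matched = set(rb_images.values())
                for rp in rec_ps:
                    if matched <= set(rp.down):
                        _hebbian_update(
                            mapping.weights, top_id, {rp.id: 1.0}, rp.id, eta
                        )
                        break
    mapping.winners = _assign_winners(net, mapping.weights)
    return mapping


@dataclass(frozen=True)
class InferredRB:
    """One role-filler pair of the generated D term."""

    driver_rb: int
    pred_token: int
    pred_weights: dict[int, float]
    object_token: int
    object_recruited: bool


def infer_missing(
    net: Network,
    driver_id: int,
    recipient_id: int,
    mapping: Mapping,
    inhibition: float,
    rng: np.random.Generator | None = None,
) -> list[InferredRB]:
    """Self-supervised inference: recruit recipient units for unmapped driver RBs.

    Fires the driver one final cycle.  A driver RB with an RB-layer mapping
    winner corresponds to existing recipient structure and triggers nothing.
    An RB for which no recipient role-filler pair ever responded clearly
    during mapping (no RB winner) triggers recruitment of matching units: a
    predicate PO image Hebbian-copied from the firing driver predicate, the
    mapped image of the driver object (or a new blank object inheriting its
    semantics at weight 0.5) and an RB binding them.  Driver P units with
    two or more inferred RBs get a recruited P image over them.

    With no prior mapping at all, inference is refused and the answer is
    empty (scored as a failure).
    """
    rng = np.random.default_rng(rng)
    po_winners = {
        d: r for d, r in mapping.winners.items() if net.tokens[d].layer == PO
    }
    if not po_winners:
        return []
    inferred: list[InferredRB] = []
    props = [t.id for t in net.top_tokens(driver_id)]
    order, _ = _order_props(props, inhibition, rng, None)
    for top_id in order:
        top = net.tokens[top_id]
        rb_ids = sorted(top.down) if top.layer == P else [top_id]
        new_rbs: list[int] = []
        for rb_id in rb_ids:
            if mapping.winner_of(rb_id) is not None:
                continue
            pred, obj = net.rb_children(rb_id)
            pred_img = net.add_po(recipient_id, "predicate", dict(pred.down))
            obj_winner = po_winners.get(obj.id)
            if obj_winner is not None and not net.tokens[obj_winner].is_object:
                # A chaotic mapping can land a filler on a non-object unit;
                # such an image cannot fill a role and is discarded.
                obj_winner = None
            if obj_winner is not None:
                obj_img = obj_winner
                recruited = False
            else:
                obj_img = net.add_po(
                    recipient_id, "object", {s: 0.5 for s in obj.down}
                ).id
                recruited = True
            rb_img = net.add_rb(recipient_id, pred_img.id, obj_img)
            new_rbs.append(rb_img.id)
            inferred.append(
                InferredRB(rb_id, pred_img.id, dict(pred_img.down), obj_img, recruited)
            )
        if top.layer == P and len(new_rbs) >= 2:
            net.add_p(recipient_id, new_rbs)
    return inferred


# -- problem encoding and end-to-end solving ------------------------------


def build_knowledge(
    checkpoint: Checkpoint | TMapping[str, TMapping[int, float] | None],
    retrieval_threshold: float = 1.0,
) -> dict[str, dict[int, float] | None]:
    """Select, per transformation role, the learned predicate used at test.

    A test item's transformation activates its defining semantics, and the
    learned predicate responding most selectively is retrieved: among
    predicates whose summed weight to the role's defining semantics reaches
    ``retrieval_threshold``, the one with the highest representation quality
    for that role wins (ties to the earliest recruit).  Roles for which
    nothing was learned map to ``None`` — such terms are encoded with object
    features only.
    """
    if not isinstance(checkpoint, Checkpoint):
        return {role: (dict(w) if w is not None else None)
                for role, w in checkpoint.items()}
    knowledge: dict[str, dict[int, float] | None] = {}
    for role, sems in pb.ROLE_SEMANTICS.items():
        best_w: dict[int, float] | None = None
        best_q = -1.0
        for pid in sorted(checkpoint.predicates):
            weights = checkpoint.predicates[pid]
            total = sum(weights.get(s, 0.0) for s in sems)
            if total < retrieval_threshold:
                continue
            q = quality_from_weights(weights, sems)
            if q > best_q:
                best_q, best_w = q, weights
        knowledge[role] = dict(best_w) if best_w is not None else None
    return knowledge


@dataclass
class EncodedProblem:
    """A problem laid out in a network: A and B in the driver, C in the recipient."""

    net: Network
    driver_id: int
    recipient_id: int
    a_object_tokens: list[int]
    c_object_tokens: list[int]
    #: (instance index, role) -> expected recipient object token in the correct D
    expected_objects: dict[tuple[int, str], int]


def encode_problem(
    problem: pb.Problem,
    knowledge: TMapping[str, TMapping[int, float] | None],
    inhibition: float,
    pool_size: int = 1000,
) -> EncodedProblem:
    """Encode A and B terms into the driver and the C term into the recipient.

    Term objects are object POs attached to four random semantics; each is
    bound to the retrieved predicate of every transformation it takes part
    in.  The B term shares the A term's objects (the same elements,
    transformed), so the driver holds two parallel copies of the role
    structure over one set of objects; the recipient holds one copy over C's
    objects.  Transformations whose predicate was never learned are left
    unencoded (the term keeps only its object features).
    """
    net = Network(pool_size=pool_size, inhibition=inhibition)
    driver = net.new_analog(DRIVER)
    recipient = net.new_analog(RECIPIENT)
    a_tokens = [net.create_object(sorted(s), driver.id).id for s in problem.a_objects]
    c_tokens = [
        net.create_object(sorted(s), recipient.id).id for s in problem.c_objects
    ]
    expected: dict[tuple[int, str], int] = {}

    def build_copy(analog_id: int, obj_tokens: list[int]) -> None:
        for k, inst in enumerate(problem.instances):
            bindings = []
            for role in inst.roles:
                weights = knowledge.get(role)
                if weights is None:
                    continue
                pred = net.add_po(analog_id, "predicate", weights)
                bindings.append((pred.id, obj_tokens[inst.role_objects[role]]))
            if bindings:
                net.make_proposition(bindings, analog_id)

    build_copy(driver.id, a_tokens)  # A term
    build_copy(driver.id, a_tokens)  # B term (same objects, transformed)
    build_copy(recipient.id, c_tokens)  # C term
    for k, inst in enumerate(problem.instances):
        for role in inst.roles:
            expected[(k, role)] = c_tokens[inst.role_objects[role]]
    return EncodedProblem(net, driver.id, recipient.id, a_tokens, c_tokens, expected)


@dataclass(frozen=True)
class AnswerRecord:
    """Outcome of one test trial: the generated D term against the correct one."""

    problem: pb.Problem
    n_instances: int
    n_correct: int
    correct_instances: tuple[bool, ...]
    n_mapped_pos: int
    n_inferred: int
    inhibition: float

    @property
    def outcome(self) -> str:
        if self.n_correct == self.n_instances and self.n_instances > 0:
            return "analogical"
        if self.n_correct > 0:
            return "incomplete"
        return "associative"


def solve_problem(
    problem: pb.Problem,
    knowledge: TMapping[str, TMapping[int, float] | None],
    inhibition: float,
    rng: np.random.Generator | None = None,
    n_passes: int = 2,
    eta: float = 0.9,
    response_noise: float = RESPONSE_NOISE,
    retrieval_threshold: float = 1.0,
    winner_threshold: float = CLEAR_WINNER_FRACTION,
    wm_bleed: float = 0.45,
    pool_size: int = 1000,
) -> AnswerRecord:
    """Solve one A:B::C:D item end to end and score the generated D term.

    Encodes the terms with the learned predicates, discovers the A-C
    correspondence by mapping, generates D by self-supervised inference, and
    scores each transformation instance: correct when an inferred role-filler
    pair carries a predicate coding that role (its strongest defining
    connection) bound to the C object that the correct answer assigns to the
    role.  Mapping connections do not persist across trials.
    """
    rng = np.random.default_rng(rng)
    enc = encode_problem(problem, knowledge, inhibition, pool_size)
    mapping = map_analogs(
        enc.net,
        enc.driver_id,
        enc.recipient_id,
        inhibition,
        n_passes=n_passes,
        rng=rng,
        eta=eta,
        response_noise=response_noise,
        winner_threshold=winner_threshold,
        driver_bleed=wm_bleed * (1.0 - inhibition),
    )
    inferred = infer_missing(
        enc.net, enc.driver_id, enc.recipient_id, mapping, inhibition, rng
    )
    answers: list[tuple[str, int]] = []
    for rb in inferred:
        role, total = best_target(rb.pred_weights)
        if total > 0.0:
            answers.append((role, rb.object_token))
    correct_flags: list[bool] = []
    for k, inst in enumerate(problem.instances):
        ok = all(
            (role, enc.expected_objects[(k, role)]) in answers
            for role in inst.roles
        )
        correct_flags.append(ok)
    n_pos = sum(
        1 for d in mapping.winners if enc.net.tokens[d].layer == PO
    )
    return AnswerRecord(
        problem=problem,
        n_instances=len(problem.instances),
        n_correct=sum(correct_flags),
        correct_instances=tuple(correct_flags),
        n_mapped_pos=n_pos,
        n_inferred=len(inferred),
        inhibition=inhibition,
    )


class AnalogySolver(BaseEstimator):
    """Solve generative geometric analogies with learned relational knowledge.

    A scikit-learn style estimator: ``fit`` binds the knowledge base (a
    learning :class:`~doralisa.learning.Checkpoint`, or a prebuilt role ->
    predicate-weights mapping) and ``predict`` classifies each problem's
    generated D term as analogical, incomplete or associative.

    Parameters
    ----------
    inhibition : float
        Lateral inhibition lambda used during mapping and inference (the
        same maturational level as during learning).
    n_passes : int
        Full driver cycles of mapping before inference.
    eta : float
        Mapping-connection learning rate.
    response_noise : float
        Spontaneous input floor of recipient units.
    retrieval_threshold : float
        Minimum summed weight to a role's defining semantics for a learned
        predicate to be retrievable at encoding time.
    winner_threshold : float
        Normalized activation a responder needs to count as a clear winner.
    random_state : int | Generator | None
        Controls every random draw during solving.
    """

    def __init__(
        self,
        inhibition: float = 0.8,
        n_passes: int = 2,
        eta: float = 0.9,
        response_noise: float = RESPONSE_NOISE,
        retrieval_threshold: float = 1.0,
        winner_threshold: float = CLEAR_WINNER_FRACTION,
        wm_bleed: float = 0.45,
        random_state: int | np.random.Generator | None = None,
    ) -> None:
        self.inhibition = inhibition
        self.n_passes = n_passes
        self.eta = eta
        self.response_noise = response_noise
        self.retrieval_threshold = retrieval_threshold
        self.winner_threshold = winner_threshold
        self.wm_bleed = wm_bleed
        self.random_state = random_state

    def fit(self, X, y=None) -> "AnalogySolver":
        """Bind the knowledge base: a Checkpoint or role -> weights mapping."""
        self.knowledge_ = build_knowledge(X, self.retrieval_threshold)
        self._rng = np.random.default_rng(self.random_state)
        return self

    def solve(
        self, problem: pb.Problem, rng: np.random.Generator | None = None
    ) -> AnswerRecord:
        check_is_fitted(self, "knowledge_")
        return solve_problem(
            problem,
            self.knowledge_,
            self.inhibition,
            rng=self._rng if rng is None else rng,
            n_passes=self.n_passes,
            eta=self.eta,
            response_noise=self.response_noise,
            retrieval_threshold=self.retrieval_threshold,
            winner_threshold=self.winner_threshold,
            wm_bleed=self.wm_bleed,
        )

    def predict(self, problems: Sequence[pb.Problem]) -> np.ndarray:
        """Classify each problem's generated answer (outcome label array)."""
        check_is_fitted(self, "knowledge_")
        return np.array([self.solve(p).outcome for p in problems], dtype=object)
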