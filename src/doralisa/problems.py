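"""Synthetic stimulus generation: the transformation world and analogy batteries.

The learning environment consists of 100 objects attached to random semantic
subsets from a pool of 1000, structured by five geometric transformations
(adding an element, changing size, halving, doubling, changing containment).
Each unary transformation is defined by two dedicated semantic units; the
binary containment relation has two roles (outside/inside), each defined by
two units.  Every object carries the defining semantics of two to four
transformations (one role only, chosen at random, for containment) plus four
idiosyncratic feature semantics.

Test items are open-ended A:B::C:D geometric analogies: the A:B pair
instantiates one to three transformations over A's objects, and C instantiates
the same transformations over fresh objects; the correct D is the role
structure that applies those transformations to C's objects.  Batteries mix
difficulty 30% hard (3 transformations), 35% medium (2), 35% easy (1), with
the documented unary/binary sub-mixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .representations import LTM, Network

__all__ = [
    "Transformation",
    "TRANSFORMATIONS",
    "ROLE_SEMANTICS",
    "ROLE_NAMES",
    "N_DEFINING_SEMANTICS",
    "TransformationInstance",
    "Problem",
    "generate_world",
    "difficulty_score",
    "generate_battery",
]


@dataclass(frozen=True)
class Transformation:
    """A ground-truth transformation: name, arity, and defining semantics."""

    name: str
    arity: int
    roles: tuple[str, ...]
    role_semantics: dict[str, frozenset[int]]

    @property
    def defining(self) -> frozenset[int]:
        out: set[int] = set()
        for sems in self.role_semantics.values():
            out |= sems
        return frozenset(out)


def _build_transformations() -> tuple[Transformation, ...]:
    unary_names = ("add_element", "change_size", "halving", "doubling")
    out = []
    idx = 0
    for name in unary_names:
        sems = frozenset({idx, idx + 1})
        idx += 2
        out.append(Transformation(name, 1, (name,), {name: sems}))
    roles = ("outside", "inside")
    role_sems = {}
    for role in roles:
        role_sems[role] = frozenset({idx, idx + 1})
        idx += 2
    out.append(Transformation("change_containment", 2, roles, role_sems))
    return tuple(out)


TRANSFORMATIONS: tuple[Transformation, ...] = _build_transformations()
BY_NAME = {t.name: t for t in TRANSFORMATIONS}
UNARY_NAMES = tuple(t.name for t in TRANSFORMATIONS if t.arity == 1)
BINARY = BY_NAME["change_containment"]

#: Every (transformation role -> defining semantics); unary roles reuse the name.
ROLE_SEMANTICS: dict[str, frozenset[int]] = {}
for _t in TRANSFORMATIONS:
    ROLE_SEMANTICS.update(_t.role_semantics)
ROLE_NAMES = tuple(ROLE_SEMANTICS)

N_DEFINING_SEMANTICS = sum(len(s) for s in ROLE_SEMANTICS.values())
#: First pool index usable as an idiosyncratic object feature.
FEATURE_OFFSET = N_DEFINING_SEMANTICS

N_OBJECT_FEATURES = 4


def generate_world(
    n_objects: int = 100,
    pool_size: int = 1000,
    rng: np.random.Generator | None = None,
    inhibition: float = 1.0,
) -> Network:
    """Generate the learning world: a network whose LTM holds the object POs.

    Each object samples 2-4 transformations without replacement; a sampled
    containment contributes exactly one role's semantics (chosen at random);
    four idiosyncratic features are drawn from the non-defining part of the
    pool.  Deterministic under a seeded generator.
    """
    rng = np.random.default_rng(rng)
    if pool_size < FEATURE_OFFSET + N_OBJECT_FEATURES:
        raise ValueError(
            f"pool_size {pool_size} too small for {FEATURE_OFFSET} defining "
            f"semantics plus {N_OBJECT_FEATURES} object features"
        )
    net = Network(pool_size=pool_size, inhibition=inhibition)
    analog = net.new_analog(LTM)
    n_transforms = len(TRANSFORMATIONS)
    for _ in range(n_objects):
        k = int(rng.integers(2, 5))
        chosen = rng.choice(n_transforms, size=k, replace=False)
        sems: set[int] = set()
        for ti in chosen:
            t = TRANSFORMATIONS[int(ti)]
            if t.arity == 1:
                sems |= t.role_semantics[t.name]
            else:
                role = t.roles[int(rng.integers(len(t.roles)))]
                sems |= t.role_semantics[role]
        feats = rng.choice(
            pool_size - FEATURE_OFFSET, size=N_OBJECT_FEATURES, replace=False
        )
        sems |= {int(f) + FEATURE_OFFSET for f in feats}
        net.create_object(sorted(sems), analog.id)
    return net


def difficulty_score(elements: int, transformations: int) -> float:
    """Item difficulty = 0.5 x elements + 1 x transformations."""
    if elements < 0 or transformations < 0:
        raise ValueError("elements and transformations must be non-negative")
    return 0.5 * elements + 1.0 * transformations


@dataclass(frozen=True)
class TransformationInstance:
    """One transformation within a problem, with its role -> object assignment.

    ``role_objects`` maps each role of the transformation to the index of the
    term object filling it (indices are shared across the A and C terms: A's
    object i corresponds to C's object i in the correct answer).
    """

    name: str
    role_objects: dict[str, int]

    @property
    def roles(self) -> tuple[str, ...]:
        return BY_NAME[self.name].roles


@dataclass(frozen=True)
class Problem:
    """A generated A:B::C:D item.

    The A:B pair applies ``instances`` to A's objects; C shows fresh objects
    in the same role structure, and the correct D applies the same
    transformations to C's objects.  Term objects are bare feature bundles
    (four idiosyncratic semantics each); the relational content lives entirely
    in the instances.
    """

    difficulty_class: str  # easy | medium | hard
    instances: tuple[TransformationInstance, ...]
    a_objects: tuple[frozenset[int], ...]
    c_objects: tuple[frozenset[int], ...]

    @property
    def n_transformations(self) -> int:
        return len(self.instances)

    @property
    def elements(self) -> int:
        return len(self.a_objects)

    @property
    def difficulty(self) -> float:
        return difficulty_score(self.elements, self.n_transformations)


def _largest_remainder(n: int, shares: tuple[float, ...]) -> list[int]:
    """Apportion n into integer counts proportional to shares.

    Largest-remainder rounding; ties broken by listed order so batteries are
    reproducible.
    """
    raw = [n * s for s in shares]
    counts = [int(x) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(shares)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


# Difficulty classes as (n_binary, n_unary) compositions, listed in the
# documented assignment order used for remainder allocation.
HARD_MIXES = ((2, 1), (1, 2), (0, 3))
MEDIUM_MIXES = ((2, 0), (0, 2), (1, 1))
EASY_MIXES = ((1, 0), (0, 1))
CLASS_SHARES = (0.30, 0.35, 0.35)  # hard, medium, easy


def _compositions(n: int) -> list[tuple[str, tuple[int, int]]]:
    hard, medium, easy = _largest_remainder(n, CLASS_SHARES)
    out: list[tuple[str, tuple[int, int]]] = []
    for cls, total, mixes, shares in (
        ("hard", hard, HARD_MIXES, (1 / 3, 1 / 3, 1 / 3)),
        ("medium", medium, MEDIUM_MIXES, (1 / 3, 1 / 3, 1 / 3)),
        ("easy", easy, EASY_MIXES, (0.5, 0.5)),
    ):
        counts = _largest_remainder(total, shares)
        if cls == "easy" and total % 2 == 1:
            # remainder to the unary mix
            counts = [total // 2, total - total // 2]
        for mix, c in zip(mixes, counts):
            out.extend((cls, mix) for _ in range(c))
    return out


def _sample_features(rng: np.random.Generator, pool_size: int, used: set[int]) -> frozenset[int]:
    feats: set[int] = set()
    while len(feats) < N_OBJECT_FEATURES:
        f = int(rng.integers(FEATURE_OFFSET, pool_size))
        if f not in used:
            feats.add(f)
            used.add(f)
    return frozenset(feats)


def _make_problem(
    cls: str,
    n_binary: int,
    n_unary: int,
    rng: np.random.Generator,
    pool_size: int,
) -> Problem:
    unaries = rng.choice(len(UNARY_NAMES), size=n_unary, replace=False)
    instances: list[TransformationInstance] = []
    n_objects = 2 * n_binary if n_binary else n_unary
    obj = 0
    for _ in range(n_binary):
        instances.append(
            TransformationInstance(
                BINARY.name, {"outside": obj, "inside": obj + 1}
            )
        )
        obj += 2
    slot = 0
    for ui in unaries:
        name = UNARY_NAMES[int(ui)]
        if n_binary:
            target = slot % n_objects  # round-robin over containment objects
        else:
            target = slot  # one object per unary transformation
        instances.append(TransformationInstance(name, {name: target}))
        slot += 1
    used: set[int] = set()
    a_objects = tuple(_sample_features(rng, pool_size, used) for _ in range(n_objects))
    c_objects = tuple(_sample_features(rng, pool_size, used) for _ in range(n_objects))
    return Problem(cls, tuple(instances), a_objects, c_objects)


def generate_battery(
    n: int = 20,
    rng: np.random.Generator | None = None,
    pool_size: int = 1000,
) -> list[Problem]:
    """Generate one test battery of ``n`` problems at the 30/35/35 mix.

    For n = 20 the class counts are (6 hard, 7 medium, 7 easy) with sub-mixes
    (2,2,2), (3,2,2) and (3 binary, 4 unary).  Problems are presented in a
    shuffled order; generation is deterministic under a seeded generator.
    """
    if n < 1:
        raise ValueError("battery size must be at least 1")
    rng = np.random.default_rng(rng)
    comps = _compositions(n)
    problems = [
        _make_problem(cls, nb, nu, rng, pool_size) for cls, (nb, nu) in comps
    ]
    order = rng.permutation(len(problems))
    return [problems[int(i)] for i in order]
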