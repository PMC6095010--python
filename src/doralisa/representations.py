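"""LISAese knowledge structures: semantics, tokens, analogs, and the network.

Relational knowledge is represented in a strictly layered hierarchy.  At the
bottom, a shared pool of distributed *semantic* units codes the features of
objects and relational roles.  Above it sit three layers of localist token
units: PO units (single predicates/roles or objects) connect downward to
semantics; RB (role-binding) units conjunctively link exactly one predicate PO
to one object PO; P (proposition) units link RB units into multi-place
relational structures such as ``contains(house, square)``.

Tokens are grouped into *analogs* (coherent situations or learned structures).
Analogs are tagged as belonging to the driver bank (the current focus of
attention), the recipient bank (active memory that responds to the driver), or
long-term memory.  Driver and recipient are mutually exclusive banks that
communicate only through the shared semantic pool; cross-bank correspondences
live in the network's mapping connections.

All downward connection weights and mapping weights lie in [0, 1].  Weights
are stored sparsely: an absent key means weight zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "PO",
    "RB",
    "P",
    "DRIVER",
    "RECIPIENT",
    "LTM",
    "Semantic",
    "Token",
    "Analog",
    "Network",
    "serialize_network",
    "deserialize_network",
]

PO = "PO"
RB = "RB"
P = "P"
LAYERS = (PO, RB, P)

DRIVER = "driver"
RECIPIENT = "recipient"
LTM = "ltm"
ROLE_TAGS = (DRIVER, RECIPIENT, LTM)

SERIAL_FORMAT = "doralisa-network"
SERIAL_VERSION = 1


@dataclass
class Semantic:
    """A unit in the shared distributed feature pool.

    Semantics carry no intrinsic meaning; they are stable, detectable
    properties of stimuli.  ``id`` indexes into the pool, ``activation`` is a
    transient state clamped to [0, 1].
    """

    id: int
    activation: float = 0.0

    def __post_init__(self) -> None:
        self.activation = min(1.0, max(0.0, self.activation))


@dataclass
class Token:
    """A localist unit in the PO/RB/P hierarchy.

    ``down`` maps lower-layer unit ids to connection weights in [0, 1]:
    semantic ids for a PO, PO token ids for an RB, RB token ids for a P.
    ``po_kind`` distinguishes predicate from object POs and is ``None`` for
    RB/P tokens.
    """

    id: int
    layer: str
    analog_id: int
    po_kind: str | None = None
    down: dict[int, float] = field(default_factory=dict)
    activation: float = 0.0

    @property
    def is_predicate(self) -> bool:
        return self.layer == PO and self.po_kind == "predicate"

    @property
    def is_object(self) -> bool:
        return self.layer == PO and self.po_kind == "object"


@dataclass
class Analog:
    """A set of tokens forming one situation; lives in exactly one bank."""

    id: int
    role_tag: str
    token_ids: list[int] = field(default_factory=list)


class LayeringError(ValueError):
    """A connection or token violates the strict PO/RB/P layering."""


class Network:
    """A semantic pool plus analogs of tokens, banks, and mapping connections.

    The network issues globally unique token ids so that mapping connections
    (driver token id, recipient token id) -> weight have stable keys across
    analogs.  ``inhibition`` is the top-down lateral inhibition level (lambda)
    of the simulated individual; it is fixed for the network's lifetime and
    controls competition sharpness in every selection process.
    """

    def __init__(self, pool_size: int = 1000, inhibition: float = 1.0) -> None:
        if pool_size <= 0:
            raise ValueError("pool_size must be positive")
        if not 0.0 < inhibition <= 1.0:
            raise ValueError("inhibition must lie in (0, 1]")
        self.pool_size = pool_size
        self.inhibition = inhibition
        self.tokens: dict[int, Token] = {}
        self.analogs: dict[int, Analog] = {}
        self.mapping: dict[tuple[int, int], float] = {}
        self._next_token = 0
        self._next_analog = 0

    # -- construction -----------------------------------------------------

    def new_analog(self, role_tag: str = LTM) -> Analog:
        if role_tag not in ROLE_TAGS:
            raise ValueError(f"unknown role_tag {role_tag!r}")
        analog = Analog(self._next_analog, role_tag)
        self.analogs[analog.id] = analog
        self._next_analog += 1
        return analog

    def _add_token(self, token: Token) -> Token:
        self.tokens[token.id] = token
        self.analogs[token.analog_id].token_ids.append(token.id)
        return token

    def add_po(
        self,
        analog_id: int,
        po_kind: str,
        weights: Mapping[int, float],
    ) -> Token:
        """Add a PO unit with downward weights onto semantic units."""
        if po_kind not in ("predicate", "object"):
            raise ValueError(f"po_kind must be predicate|object, got {po_kind!r}")
        down = {}
        for sem, w in weights.items():
            if not 0 <= sem < self.pool_size:
                raise LayeringError(
                    f"semantic id {sem} outside pool [0, {self.pool_size})"
                )
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight {w} outside [0, 1]")
            if w > 0.0:
                down[int(sem)] = float(w)
        token = Token(self._next_token, PO, analog_id, po_kind, down)
        self._next_token += 1
        return self._add_token(token)

    def create_object(self, semantic_ids: Iterable[int], analog_id: int) -> Token:
        """Create an object PO attached with weight 1.0 to the given semantics."""
        ids = list(semantic_ids)
        if not ids:
            raise ValueError("an object must be attached to at least one semantic")
        return self.add_po(analog_id, "object", {i: 1.0 for i in ids})

    def add_rb(self, analog_id: int, pred_id: int, obj_id: int) -> Token:
        """Add an RB binding one predicate PO to one object PO (weights 1.0)."""
        pred = self.tokens[pred_id]
        obj = self.tokens[obj_id]
        if not pred.is_predicate or not obj.is_object:
            raise LayeringError(
                "an RB must bind exactly one predicate PO and one object PO "
                f"(got {pred.layer}/{pred.po_kind} and {obj.layer}/{obj.po_kind})"
            )
        token = Token(self._next_token, RB, analog_id, None, {pred_id: 1.0, obj_id: 1.0})
        self._next_token += 1
        return self._add_token(token)

    def add_p(self, analog_id: int, rb_ids: Iterable[int]) -> Token:
        ids = list(rb_ids)
        for rid in ids:
            if self.tokens[rid].layer != RB:
                raise LayeringError("a P unit may connect only to RB units")
        token = Token(self._next_token, P, analog_id, None, {r: 1.0 for r in ids})
        self._next_token += 1
        return self._add_token(token)

    def make_proposition(
        self,
        bindings: list[tuple[int, int]],
        analog_id: int,
    ) -> Token:
        """Build role-filler structure from ordered (predicate, object) pairs.

        Each pair becomes an RB with weight 1.0 to both POs.  Two or more
        pairs are linked by a single P unit; a single-place predication yields
        a bare RB with no P.  Returns the top token (P, or the lone RB).
        """
        if not bindings:
            raise ValueError("bindings must be non-empty")
        rbs = [self.add_rb(analog_id, pred, obj) for pred, obj in bindings]
        if len(rbs) == 1:
            return rbs[0]
        return self.add_p(analog_id, [rb.id for rb in rbs])

    # -- queries ----------------------------------------------------------

    def analog_tokens(self, analog_id: int, layer: str | None = None) -> list[Token]:
        toks = [self.tokens[t] for t in self.analogs[analog_id].token_ids]
        if layer is not None:
            toks = [t for t in toks if t.layer == layer]
        return toks

    def rb_children(self, rb_id: int) -> tuple[Token, Token]:
        """Return (predicate PO, object PO) of an RB."""
        pred = obj = None
        for cid in self.tokens[rb_id].down:
            child = self.tokens[cid]
            if child.is_predicate:
                pred = child
            elif child.is_object:
                obj = child
        if pred is None or obj is None:
            raise LayeringError(f"RB {rb_id} lacks a predicate/object pair")
        return pred, obj

    def top_tokens(self, analog_id: int) -> list[Token]:
        """Top-level structures of an analog: P units plus RBs under no P."""
        toks = self.analog_tokens(analog_id)
        under_p: set[int] = set()
        for t in toks:
            if t.layer == P:
                under_p.update(t.down)
        return [t for t in toks if t.layer == P or (t.layer == RB and t.id not in under_p)]

    def validate(self) -> None:
        """Check the structural invariants; raise LayeringError on violation."""
        for token in self.tokens.values():
            if token.layer not in LAYERS:
                raise LayeringError(f"unknown layer {token.layer!r}")
            if token.analog_id not in self.analogs:
                raise LayeringError(f"token {token.id} in unknown analog")
            for cid, w in token.down.items():
                if not 0.0 <= w <= 1.0:
                    raise ValueError(f"weight {w} outside [0, 1]")
                if token.layer == PO:
                    if not 0 <= cid < self.pool_size:
                        raise LayeringError("PO connected outside semantic pool")
                else:
                    child = self.tokens.get(cid)
                    if child is None:
                        raise LayeringError(f"{token.layer} child {cid} missing")
                    expected = PO if token.layer == RB else RB
                    if child.layer != expected:
                        raise LayeringError(
                            f"{token.layer} unit {token.id} connects to "
                            f"{child.layer} unit {cid}; layering is strict"
                        )
            if token.layer == RB:
                kinds = sorted(
                    self.tokens[c].po_kind or "" for c in token.down
                )
                if len(token.down) != 2 or kinds != ["object", "predicate"]:
                    raise LayeringError(
                        f"RB {token.id} must bind exactly one predicate and one object"
                    )
        seen: set[int] = set()
        for analog in self.analogs.values():
            for tid in analog.token_ids:
                if tid in seen:
                    raise LayeringError(f"token {tid} belongs to more than one analog")
                seen.add(tid)
        for (d, r), w in self.mapping.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError("mapping weight outside [0, 1]")
            if self.tokens[d].layer != self.tokens[r].layer:
                raise LayeringError("mapping connections must link same-layer tokens")


# -- serialization --------------------------------------------------------


def serialize_network(net: Network) -> str:
    """Serialize a network to a JSON checkpoint string (documented schema)."""
    blob = {
        "format": SERIAL_FORMAT,
        "version": SERIAL_VERSION,
        "pool_size": net.pool_size,
        "inhibition": net.inhibition,
        "next_token": net._next_token,
        "next_analog": net._next_analog,
        "analogs": [
            {"id": a.id, "role_tag": a.role_tag} for a in net.analogs.values()
        ],
        "tokens": [
            {
                "id": t.id,
                "layer": t.layer,
                "po_kind": t.po_kind,
                "analog": t.analog_id,
                "down": [[int(k), float(v)] for k, v in sorted(t.down.items())],
            }
            for t in net.tokens.values()
        ],
        "mapping": [
            [int(d), int(r), float(w)] for (d, r), w in sorted(net.mapping.items())
        ],
    }
    return json.dumps(blob)


def deserialize_network(blob: str) -> Network:
    """Rebuild a network from its JSON checkpoint; validates all invariants."""
    try:
        data = json.loads(blob)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed checkpoint: {exc}") from exc
    if not isinstance(data, dict) or data.get("format") != SERIAL_FORMAT:
        raise ValueError("malformed checkpoint: missing format marker")
    if data.get("version") != SERIAL_VERSION:
        raise ValueError(f"unsupported checkpoint version {data.get('version')!r}")
    net = Network(pool_size=data["pool_size"], inhibition=data["inhibition"])
    for a in data["analogs"]:
        net.analogs[a["id"]] = Analog(a["id"], a["role_tag"])
    for t in data["tokens"]:
        token = Token(
            t["id"], t["layer"], t["analog"], t["po_kind"],
            {int(k): float(v) for k, v in t["down"]},
        )
        net.tokens[token.id] = token
        net.analogs[token.analog_id].token_ids.append(token.id)
    for d, r, w in data.get("mapping", []):
        net.mapping[(int(d), int(r))] = float(w)
    net._next_token = data.get("next_token", max(net.tokens, default=-1) + 1)
    net._next_analog = data.get("next_analog", max(net.analogs, default=-1) + 1)
    net.validate()
    return net
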