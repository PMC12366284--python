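"""Domain model for curly-arrow enzyme mechanisms.

A mechanism is an ordered sequence of catalytic steps.  Each step carries a
labelled molecular graph of every chemical species in the active site (the
*reactant frame* of the step, possibly disconnected) together with the curly
arrows that describe the concerted electron movements transforming it into
the next state.  A curly arrow moves one or two electrons from a *source*
(a lone pair on an atom, or an existing bond) to a *sink* (an atom, an
existing bond, or an incipient bond between two not-yet-bonded atoms).

The model is purely structural: no 3D coordinates, no stereochemistry, no
kinetics.  Hydrogens that take part in the chemistry are explicit atoms.
Validation never raises — :func:`validate_mechanism` returns a list of
violation descriptions so that a document can be checked exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from typing import Iterable, Mapping


class BondOrder(str, Enum):
    """Covalent bond order.  Aromatic is a first-class order, kept distinct
    from alternating single/double bonds (no kekulization is performed)."""

    SINGLE = "single"
    DOUBLE = "double"
    TRIPLE = "triple"
    AROMATIC = "aromatic"


class EndpointKind(str, Enum):
    ATOM = "atom"
    BOND = "bond"
    INCIPIENT = "incipient"


@dataclass(frozen=True)
class AtomNode:
    """One atom of an active-site state.

    ``atom_id`` is unique within its state; ``element`` is the atomic
    number.  Formal charges are integers; partial charges do not exist in
    this model.
    """

    atom_id: int
    element: int
    formal_charge: int = 0


@dataclass(frozen=True)
class BondEdge:
    """An undirected bond between two atoms (stored with atom_a <= atom_b)."""

    atom_a: int
    atom_b: int
    order: BondOrder = BondOrder.SINGLE

    def __post_init__(self) -> None:
        if self.atom_a > self.atom_b:
            a, b = self.atom_a, self.atom_b
            object.__setattr__(self, "atom_a", b)
            object.__setattr__(self, "atom_b", a)
        if not isinstance(self.order, BondOrder):
            object.__setattr__(self, "order", BondOrder(self.order))

    @property
    def atoms(self) -> tuple[int, int]:
        return (self.atom_a, self.atom_b)

    def other(self, atom_id: int) -> int:
        return self.atom_b if atom_id == self.atom_a else self.atom_a


@dataclass(frozen=True)
class ArrowEndpoint:
    """Tail or tip of a curly arrow.

    ``kind`` decides the meaning of ``atoms``: a single atom (lone pair or
    radical site), an existing bond (both atoms), or an incipient bond
    (ordered pair; the bond does not yet exist in the state).
    """

    kind: EndpointKind
    atoms: tuple[int, ...]

    @staticmethod
    def atom(atom_id: int) -> "ArrowEndpoint":
        return ArrowEndpoint(EndpointKind.ATOM, (atom_id,))

    @staticmethod
    def bond(a: int, b: int) -> "ArrowEndpoint":
        return ArrowEndpoint(EndpointKind.BOND, (min(a, b), max(a, b)))

    @staticmethod
    def incipient(a: int, b: int) -> "ArrowEndpoint":
        return ArrowEndpoint(EndpointKind.INCIPIENT, (a, b))

    @property
    def touched(self) -> frozenset[int]:
        """Atoms touched by this endpoint.  Bond endpoints (existing or
        incipient) touch both atoms of the bond."""
        return frozenset(self.atoms)


@dataclass(frozen=True)
class CurlyArrow:
    """One electron-flow arrow: 1 (fishhook) or 2 electrons moving from
    ``source`` to ``sink``."""

    electrons: int
    source: ArrowEndpoint
    sink: ArrowEndpoint


@dataclass(frozen=True)
class ActiveSiteState:
    """Labelled molecular graph of all species present in one catalytic
    step.  The graph is simple and may be disconnected."""

    atoms: tuple[AtomNode, ...]
    bonds: tuple[BondEdge, ...]

    @cached_property
    def _atom_map(self) -> dict[int, AtomNode]:
        return {a.atom_id: a for a in self.atoms}

    @cached_property
    def _bond_map(self) -> dict[tuple[int, int], BondEdge]:
        return {b.atoms: b for b in self.bonds}

    @cached_property
    def adjacency(self) -> dict[int, dict[int, BondOrder]]:
        adj: dict[int, dict[int, BondOrder]] = {a.atom_id: {} for a in self.atoms}
        for b in self.bonds:
            if b.atom_a in adj and b.atom_b in adj and b.atom_a != b.atom_b:
                adj[b.atom_a][b.atom_b] = b.order
                adj[b.atom_b][b.atom_a] = b.order
        return adj

    def atom(self, atom_id: int) -> AtomNode:
        return self._atom_map[atom_id]

    def has_atom(self, atom_id: int) -> bool:
        return atom_id in self._atom_map

    def has_bond(self, a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in self._bond_map

    def bond_between(self, a: int, b: int) -> BondEdge:
        return self._bond_map[(min(a, b), max(a, b))]

    def neighbors(self, atom_id: int) -> tuple[int, ...]:
        return tuple(sorted(self.adjacency[atom_id]))


@dataclass(frozen=True)
class CatalyticStep:
    """One concerted set of electron movements: a state plus >= 1 arrows."""

    step_index: int
    state: ActiveSiteState
    arrows: tuple[CurlyArrow, ...]


@dataclass(frozen=True)
class Mechanism:
    """An enzyme mechanism: an ordered sequence of catalytic steps plus
    optional annotations (EC numbers, CATH superfamilies of the catalytic
    domains)."""

    mechanism_id: str
    steps: tuple[CatalyticStep, ...]
    annotations: Mapping | None = None

    @property
    def n_arrows(self) -> int:
        return sum(len(s.arrows) for s in self.steps)


def reaction_centres(arrow: CurlyArrow) -> frozenset[int]:
    """Atoms directly touched by the arrow's tail or tip.

    If the tail or tip interacts with a bond (existing or incipient), both
    atoms of that bond count.  An atom touched by both tail and tip appears
    once.  Any valid arrow yields between 1 and 4 centres.
    """
    return arrow.source.touched | arrow.sink.touched


def _validate_endpoint(
    ep: ArrowEndpoint, state: ActiveSiteState, where: str, is_source: bool
) -> list[str]:
    out: list[str] = []
    if is_source and ep.kind is EndpointKind.INCIPIENT:
        out.append(f"{where}: arrow source cannot be an incipient bond")
        return out
    expected = 1 if ep.kind is EndpointKind.ATOM else 2
    if len(ep.atoms) != expected:
        out.append(f"{where}: {ep.kind.value} endpoint must reference {expected} atom(s)")
        return out
    for aid in ep.atoms:
        if not state.has_atom(aid):
            out.append(f"{where}: references atom {aid} absent from state")
            return out
    if ep.kind is EndpointKind.BOND and not state.has_bond(*ep.atoms):
        out.append(f"{where}: references bond {ep.atoms} absent from state")
    if ep.kind is EndpointKind.INCIPIENT:
        a, b = ep.atoms
        if a == b:
            out.append(f"{where}: incipient bond ({a},{b}) must join two distinct atoms")
        elif state.has_bond(a, b):
            out.append(
                f"{where}: incipient bond ({a},{b}) already exists in state "
                "(use a bond sink instead)"
            )
    return out


def validate_mechanism(mech: Mechanism) -> list[str]:
    """Check every domain invariant; return a (possibly empty) list of
    human-readable violations.  Idempotent and side-effect free."""
    out: list[str] = []
    if not mech.mechanism_id:
        out.append("mechanism: empty mechanism_id")
    if not mech.steps:
        out.append("mechanism: must contain at least one step")
    for pos, step in enumerate(mech.steps, start=1):
        if step.step_index != pos:
            out.append(
                f"step at position {pos}: step_index {step.step_index} breaks the "
                f"consecutive 1..n numbering"
            )
        out.extend(_validate_step(step))
    return out


def _validate_step(step: CatalyticStep) -> list[str]:
    out: list[str] = []
    where = f"step {step.step_index}"
    state = step.state
    seen_ids: set[int] = set()
    for a in state.atoms:
        if a.atom_id in seen_ids:
            out.append(f"{where}: duplicate atom_id {a.atom_id}")
        seen_ids.add(a.atom_id)
        if not (1 <= a.element <= 118):
            out.append(f"{where}, atom {a.atom_id}: element {a.element} outside 1..118")
    seen_pairs: set[tuple[int, int]] = set()
    for b in state.bonds:
        if b.atom_a == b.atom_b:
            out.append(f"{where}: self-bond on atom {b.atom_a}")
            continue
        for aid in b.atoms:
            if aid not in seen_ids:
                out.append(f"{where}, bond {b.atoms}: references unknown atom {aid}")
        if b.atoms in seen_pairs:
            out.append(f"{where}: duplicate bond between atoms {b.atoms}")
        seen_pairs.add(b.atoms)
    if not step.arrows:
        out.append(f"{where}: a catalytic step needs at least one arrow")
    for i, arrow in enumerate(step.arrows, start=1):
        aw = f"{where}, arrow {i}"
        if arrow.electrons not in (1, 2):
            out.append(f"{aw}: electrons must be 1 or 2, got {arrow.electrons}")
        out.extend(_validate_endpoint(arrow.source, state, f"{aw} (source)", True))
        out.extend(_validate_endpoint(arrow.sink, state, f"{aw} (sink)", False))
        if arrow.source == arrow.sink:
            out.append(f"{aw}: source and sink are identical")
    return out
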