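"""Arrow-environments: the unit of mechanism comparison.

An arrow-environment (arrow-env) is the subgraph of an active-site state
within a fixed number of bonds of a curly arrow's reaction centres,
labelled with the arrow's electron count and tail/tip roles.  Three named
definitions are shipped:

``one_away``
    reaction centres plus a single shell of atoms (bond distance <= 1);
``two_away``
    two shells (distance <= 2);
``ezmechanism_like``
    like ``two_away`` but carbon and hydrogen atoms in the outermost
    (second) shell are treated as interchangeable, since at that distance
    a C or H should contribute similarly to the reaction energetics.

Custom definitions are ordinary :class:`ArrowEnvDefinition` instances with
any depth and any outermost-shell equivalence set.

Each reaction-centre atom carries a two-digit annotation ``(electrons,
role)`` where role is 1 for atoms touched by the arrow's tail, 2 for its
tip and 3 for both; atoms of a bond endpoint count as touched.  Envs of
the same definition compare equal iff their labelled graphs are
isomorphic (element or equivalence class, formal charge, arrow digits,
bond orders; chirality never considered), realised through a
deterministic canonical key.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable

from .canon import canonical_order
from .errors import MechsimError
from .model import (
    ActiveSiteState,
    BondEdge,
    CatalyticStep,
    CurlyArrow,
    reaction_centres,
)


@dataclass(frozen=True)
class ArrowEnvDefinition:
    """A named recipe for building arrow-envs.

    ``shell_depth`` is the number of bond-distance shells around the
    reaction centres; ``outer_equivalents`` is a set of atomic numbers
    merged into one equivalence class for atoms at exactly the outermost
    shell (empty set: no merging).
    """

    name: str
    shell_depth: int
    outer_equivalents: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.shell_depth < 1:
            raise ValueError("shell_depth must be >= 1")


ONE_AWAY = ArrowEnvDefinition("one_away", 1)
TWO_AWAY = ArrowEnvDefinition("two_away", 2)
EZMECHANISM_LIKE = ArrowEnvDefinition("ezmechanism_like", 2, frozenset({1, 6}))

DEFINITIONS: dict[str, ArrowEnvDefinition] = {
    d.name: d for d in (ONE_AWAY, TWO_AWAY, EZMECHANISM_LIKE)
}


def get_definition(name: str) -> ArrowEnvDefinition:
    try:
        return DEFINITIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown arrow-env definition {name!r}; known: {sorted(DEFINITIONS)}"
        ) from None


@dataclass(frozen=True)
class EnvAtom:
    """An atom inside an arrow-env.

    ``digits`` is ``(electrons, role)`` for reaction centres, ``None``
    otherwise.  ``equivalence`` replaces the element with a set of
    interchangeable elements for outermost-shell atoms under definitions
    that declare equivalents.
    """

    atom_id: int
    element: int
    formal_charge: int = 0
    equivalence: tuple[int, ...] | None = None
    digits: tuple[int, int] | None = None

    @property
    def elements(self) -> tuple[int, ...]:
        """Atomic numbers this atom may match, sorted ascending."""
        return tuple(sorted(self.equivalence)) if self.equivalence else (self.element,)

    @property
    def label(self) -> tuple:
        return (self.elements, self.formal_charge, self.digits or (0, 0))


@dataclass(eq=False)
class ArrowEnv:
    """Canonicalized subgraph around one curly arrow."""

    atoms: tuple[EnvAtom, ...]
    bonds: tuple[BondEdge, ...]
    definition: ArrowEnvDefinition

    @cached_property
    def _index_of(self) -> dict[int, int]:
        return {a.atom_id: i for i, a in enumerate(self.atoms)}

    @cached_property
    def adjacency(self) -> dict[int, dict[int, str]]:
        """Index-based adjacency with bond-order values."""
        adj: dict[int, dict[int, str]] = {i: {} for i in range(len(self.atoms))}
        idx = self._index_of
        for b in self.bonds:
            i, j = idx[b.atom_a], idx[b.atom_b]
            adj[i][j] = b.order.value
            adj[j][i] = b.order.value
        return adj

    @cached_property
    def canonical_ranks(self) -> dict[int, int]:
        """Atom index -> canonical position, stable across atom-id
        permutations and fragment reorderings."""
        labels = [a.label for a in self.atoms]
        perm = canonical_order(labels, self.adjacency)
        return {v: pos for pos, v in enumerate(perm)}

    @cached_property
    def smarts(self) -> str:
        from .smarts import to_smarts

        return to_smarts(self)

    @cached_property
    def canonical_key(self) -> str:
        return f"{self.definition.name}|{self.smarts}"

    @property
    def mapped_atoms(self) -> frozenset[int]:
        """atom_ids carrying arrow digits (the reaction centres)."""
        return frozenset(a.atom_id for a in self.atoms if a.digits is not None)


def shell_atoms(
    state: ActiveSiteState, centres: Iterable[int], depth: int
) -> set[int]:
    """All atoms within ``depth`` bonds of any centre (centres included).

    Computed by multi-source BFS over the state's bond graph, per
    connected component.
    """
    centres = set(centres)
    for c in centres:
        if not state.has_atom(c):
            raise MechsimError(f"shell_atoms: unknown centre atom {c}")
    if depth < 0:
        raise MechsimError("shell_atoms: depth must be >= 0")
    dist = {c: 0 for c in centres}
    queue = deque(centres)
    while queue:
        u = queue.popleft()
        if dist[u] == depth:
            continue
        for v in state.adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return set(dist)


def extract_arrow_env(
    step: CatalyticStep, arrow: CurlyArrow, definition: ArrowEnvDefinition
) -> ArrowEnv:
    """Build the arrow-env of ``arrow`` within ``step`` under ``definition``.

    The env is the induced subgraph of the state on the shell atoms: every
    bond of the state between two included atoms is kept, including bonds
    connecting two outermost-shell atoms.
    """
    state = step.state
    centres = reaction_centres(arrow)
    tail, tip = arrow.source.touched, arrow.sink.touched
    # per-atom distances drive both inclusion and outer-shell equivalence
    dist: dict[int, int] = {c: 0 for c in centres}
    queue = deque(centres)
    while queue:
        u = queue.popleft()
        if dist[u] == definition.shell_depth:
            continue
        for v in state.adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    included = sorted(dist)
    env_atoms: list[EnvAtom] = []
    for aid in included:
        node = state.atom(aid)
        digits = None
        if aid in centres:
            role = (1 if aid in tail else 0) + (2 if aid in tip else 0)
            digits = (arrow.electrons, role)
        equivalence = None
        if (
            definition.outer_equivalents
            and dist[aid] == definition.shell_depth
            and node.element in definition.outer_equivalents
        ):
            equivalence = tuple(sorted(definition.outer_equivalents))
        env_atoms.append(
            EnvAtom(aid, node.element, node.formal_charge, equivalence, digits)
        )
    in_env = set(included)
    env_bonds = tuple(
        b for b in state.bonds if b.atom_a in in_env and b.atom_b in in_env
    )
    return ArrowEnv(tuple(env_atoms), env_bonds, definition)


def canonical_key(env: ArrowEnv) -> str:
    """Stable key: equal iff the two envs (of the same definition) are
    isomorphic under the label predicate."""
    return env.canonical_key


def env_equal(a: ArrowEnv, b: ArrowEnv) -> bool:
    """Equality of two arrow-envs.  Comparing envs built under different
    definitions is undefined and rejected."""
    if a.definition != b.definition:
        raise MechsimError(
            f"cannot compare arrow-envs of different definitions "
            f"({a.definition.name} vs {b.definition.name})"
        )
    return a.canonical_key == b.canonical_key
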