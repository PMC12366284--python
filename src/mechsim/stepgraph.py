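"""Directed graphs of arrow-envs within a catalytic step.

All arrows of a step act in concert; their ordering carries no temporal
meaning.  Structure comes from the *follows* relation: arrow B follows
arrow A when B's tail touches an atom touched by A's tip (bond endpoints
count as touched atoms).  Each arrow-env is a node, each follows pair a
directed edge.  Chains of arrows need not be linear — they can branch or
close into cycles — hence a graph rather than a sequence.

The *chains* of a step are exactly the edges of this graph: ordered pairs
of arrow-env keys.  Two arrow instances with identical canonical keys
merge into one node (set semantics, multiplicity kept as a diagnostic);
an edge between two distinct instances sharing a key is retained as a
loop edge.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping

import networkx as nx

from .arrowenv import ArrowEnv, ArrowEnvDefinition, extract_arrow_env
from .model import CatalyticStep, CurlyArrow


@dataclass(frozen=True)
class StepGraph:
    """Arrow-env graph of one catalytic step."""

    step_index: int
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    multiplicity: tuple[tuple[str, int], ...] = ()

    def multiplicity_of(self, key: str) -> int:
        return dict(self.multiplicity).get(key, 0)


def follows(prev: CurlyArrow, next: CurlyArrow) -> bool:
    """True iff ``next``'s tail touches an atom touched by ``prev``'s tip."""
    return bool(next.source.touched & prev.sink.touched)


def build_step_graph(
    step: CatalyticStep, definition: ArrowEnvDefinition
) -> StepGraph:
    """Build the arrow-env graph of ``step`` under ``definition``.

    Output is deterministic and invariant to the listed order of arrows
    (the follows relation is derived from endpoints, not positions).
    Self-pairs over the same arrow instance are excluded.
    """
    envs = [extract_arrow_env(step, a, definition) for a in step.arrows]
    keys = [e.canonical_key for e in envs]
    edges = frozenset(
        (keys[i], keys[j])
        for i, j in permutations(range(len(step.arrows)), 2)
        if follows(step.arrows[i], step.arrows[j])
    )
    counts = Counter(keys)
    return StepGraph(
        step_index=step.step_index,
        nodes=frozenset(keys),
        edges=edges,
        multiplicity=tuple(sorted(counts.items())),
    )


def chains(graph: StepGraph) -> frozenset[tuple[str, str]]:
    """The chains of a step: its edge set (ordered env-key pairs)."""
    return graph.edges


def to_networkx(graph: StepGraph) -> nx.DiGraph:
    g = nx.DiGraph(step_index=graph.step_index)
    for key, mult in graph.multiplicity:
        g.add_node(key, multiplicity=mult)
    g.add_edges_from(graph.edges)
    return g


def to_dot(graph: StepGraph) -> str:
    """Minimal DOT rendering for debugging."""
    lines = [f'digraph "step_{graph.step_index}" {{']
    for node in sorted(graph.nodes):
        lines.append(f'  "{node}";')
    for a, b in sorted(graph.edges):
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines)


def write_graphml(graph: StepGraph, path) -> None:
    nx.write_graphml(to_networkx(graph), path)
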