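"""Canonical labeling of small labelled graphs.

Arrow-environments are tiny (a few dozen atoms at most), so an exact
canonical form is affordable: iterative neighbourhood-label refinement
(1-dimensional Weisfeiler-Leman with vertex and edge labels) followed by
exhaustive individualization of the first non-discrete cell, keeping the
lexicographically smallest certificate.  Two graphs receive the same
certificate iff there is a label-preserving isomorphism between them.

Vertex labels must be totally orderable tuples; edge labels are strings.
"""

from __future__ import annotations

from typing import Mapping, Sequence

Label = tuple
Adjacency = Mapping[int, Mapping[int, str]]


def _refine(colors: list[int], adj: Adjacency) -> list[int]:
    n = len(colors)
    while True:
        sigs = [
            (colors[v], tuple(sorted((adj[v][u], colors[u]) for u in adj[v])))
            for v in range(n)
        ]
        order = {s: i for i, s in enumerate(sorted(set(sigs)))}
        new = [order[s] for s in sigs]
        if new == colors:
            return colors
        colors = new


def _certificate(
    perm: Sequence[int], labels: Sequence[Label], adj: Adjacency
) -> tuple:
    pos = {v: i for i, v in enumerate(perm)}
    edges = sorted(
        (min(pos[u], pos[v]), max(pos[u], pos[v]), adj[u][v])
        for u in adj
        for v in adj[u]
        if u < v
    )
    return (tuple(labels[v] for v in perm), tuple(edges))


def canonical_order(labels: Sequence[Label], adj: Adjacency) -> list[int]:
    """Return a canonical vertex ordering (position -> vertex index).

    Deterministic across runs and invariant to the input vertex numbering:
    isomorphic inputs yield identical certificates, hence identical
    relabelled graphs.
    """
    n = len(labels)
    if n == 0:
        return []
    init = {lab: i for i, lab in enumerate(sorted(set(labels)))}
    colors = [init[lab] for lab in labels]

    best: list[tuple] = []  # [cert, perm], mutable closure cell

    def search(colors: list[int]) -> None:
        colors = _refine(list(colors), adj)
        cells: dict[int, list[int]] = {}
        for v, c in enumerate(colors):
            cells.setdefault(c, []).append(v)
        target = None
        for c in sorted(cells):
            if len(cells[c]) > 1:
                target = c
                break
        if target is None:
            perm = sorted(range(n), key=lambda v: colors[v])
            cert = _certificate(perm, labels, adj)
            if not best or cert < best[0]:
                best[:] = [cert, perm]
            return
        for v in cells[target]:
            branched = [2 * c for c in colors]
            branched[v] -= 1
            search(branched)

    search(colors)
    return best[1]


def certificate(labels: Sequence[Label], adj: Adjacency) -> tuple:
    """Canonical certificate of a labelled graph (equality <=> isomorphism)."""
    return _certificate(canonical_order(labels, adj), labels, adj)
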