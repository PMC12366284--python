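"""Canonical mechanism JSON format and similarity-graph export.

The JSON exchange format (version "1.0") is the canonical on-disk
representation of a mechanism; see ``docs/mechanism-json-v1.md`` for the
schema.  Writing is byte-stable: atoms are sorted by id, bonds by atom
pair, keys emitted in a fixed order, so the same mechanism always
produces identical bytes and ``parse(write(m))`` is the identity up to
that canonical ordering.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .errors import MechanismParseError, MechanismValidationError
from .model import (
    ActiveSiteState,
    ArrowEndpoint,
    AtomNode,
    BondEdge,
    BondOrder,
    CatalyticStep,
    CurlyArrow,
    EndpointKind,
    Mechanism,
    validate_mechanism,
)

FORMAT_VERSION = "1.0"


# ---------------------------------------------------------------------------
# JSON writing

def _atom_to_dict(a: AtomNode) -> dict:
    d = {"id": a.atom_id, "element": a.element}
    if a.formal_charge:
        d["charge"] = a.formal_charge
    return d


def _endpoint_to_dict(ep: ArrowEndpoint) -> dict:
    return {"kind": ep.kind.value, "atoms": list(ep.atoms)}


def mechanism_to_dict(mech: Mechanism) -> dict:
    """Deterministically ordered plain-dict form of a mechanism."""
    steps = []
    for step in mech.steps:
        steps.append(
            {
                "step_index": step.step_index,
                "atoms": [
                    _atom_to_dict(a)
                    for a in sorted(step.state.atoms, key=lambda a: a.atom_id)
                ],
                "bonds": [
                    {"atoms": list(b.atoms), "order": b.order.value}
                    for b in sorted(step.state.bonds, key=lambda b: b.atoms)
                ],
                "arrows": [
                    {
                        "electrons": ar.electrons,
                        "source": _endpoint_to_dict(ar.source),
                        "sink": _endpoint_to_dict(ar.sink),
                    }
                    for ar in step.arrows
                ],
            }
        )
    mrec: dict = {"mechanism_id": mech.mechanism_id}
    if mech.annotations is not None:
        mrec["annotations"] = dict(mech.annotations)
    mrec["steps"] = steps
    return {"format_version": FORMAT_VERSION, "mechanism": mrec}


def write_mechanism_json(mech: Mechanism) -> str:
    """Serialize a validated mechanism to canonical JSON text."""
    violations = validate_mechanism(mech)
    if violations:
        raise MechanismValidationError(violations)
    return json.dumps(mechanism_to_dict(mech), indent=2, sort_keys=True) + "\n"


# ---------------------------------------------------------------------------
# JSON parsing

def _endpoint_from_dict(d: Mapping) -> ArrowEndpoint:
    try:
        kind = EndpointKind(d["kind"])
        atoms = tuple(int(a) for a in d["atoms"])
    except (KeyError, TypeError, ValueError) as e:
        raise MechanismParseError(f"malformed arrow endpoint {d!r}: {e}") from None
    if kind is EndpointKind.BOND:
        atoms = tuple(sorted(atoms))
    return ArrowEndpoint(kind, atoms)


def mechanism_from_dict(doc: Mapping) -> Mechanism:
    try:
        mrec = doc["mechanism"]
        steps = []
        for srec in mrec["steps"]:
            atoms = tuple(
                AtomNode(int(a["id"]), int(a["element"]), int(a.get("charge", 0)))
                for a in srec["atoms"]
            )
            bonds = tuple(
                BondEdge(
                    int(b["atoms"][0]),
                    int(b["atoms"][1]),
                    BondOrder(b.get("order", "single")),
                )
                for b in srec["bonds"]
            )
            arrows = tuple(
                CurlyArrow(
                    int(ar["electrons"]),
                    _endpoint_from_dict(ar["source"]),
                    _endpoint_from_dict(ar["sink"]),
                )
                for ar in srec["arrows"]
            )
            steps.append(
                CatalyticStep(int(srec["step_index"]), ActiveSiteState(atoms, bonds), arrows)
            )
        mech = Mechanism(
            mechanism_id=str(mrec["mechanism_id"]),
            steps=tuple(steps),
            annotations=mrec.get("annotations"),
        )
    except MechanismParseError:
        raise
    except (KeyError, TypeError, ValueError) as e:
        raise MechanismParseError(f"malformed mechanism document: {e}") from None
    violations = validate_mechanism(mech)
    if violations:
        raise MechanismValidationError(violations)
    return mech


def parse_mechanism_json(text: str) -> Mechanism:
    """Parse and validate one mechanism document."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise MechanismParseError(
            f"invalid JSON at line {e.lineno} column {e.colno}: {e.msg}"
        ) from None
    return mechanism_from_dict(doc)


def load_mechanism(path) -> Mechanism:
    return parse_mechanism_json(Path(path).read_text())


def save_mechanism(mech: Mechanism, path) -> None:
    Path(path).write_text(write_mechanism_json(mech))


# ---------------------------------------------------------------------------
# Similarity-graph export

def export_similarity_graph(
    scores: pd.DataFrame,
    cutoff: float,
    *,
    annotations: Mapping[str, Mapping] | None = None,
    graphml_path=None,
    tsv_path=None,
) -> nx.Graph:
    """Threshold graph of a pair-score table.

    One node per mechanism (attributes: EC class, CATH superfamilies,
    empty string when unknown) and one edge for every pair whose score is
    >= ``cutoff``.  Isolated nodes are retained.  Input rows must give
    each unordered pair one consistent score; conflicting duplicates are
    rejected as asymmetric.  Optionally writes GraphML and an edge-list
    TSV (mech_a, mech_b, score, definition, method).
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0,1], got {cutoff}")
    pair_scores: dict[frozenset, tuple] = {}
    ids: set[str] = set()
    for row in scores.itertuples(index=False):
        a, b, s = str(row.mech_a), str(row.mech_b), float(row.score)
        if a == b:
            raise ValueError(f"self-pair {a!r} in score table")
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score {s} for pair ({a},{b}) outside [0,1]")
        ids.update((a, b))
        pair = frozenset((a, b))
        meta = (
            s,
            str(getattr(row, "definition", "")),
            str(getattr(row, "method", "")),
        )
        if pair in pair_scores and abs(pair_scores[pair][0] - s) > 1e-12:
            raise ValueError(
                f"asymmetric score table: pair ({a},{b}) listed with scores "
                f"{pair_scores[pair][0]} and {s}"
            )
        pair_scores[pair] = meta

    graph = nx.Graph()
    for mid in sorted(ids):
        ann = dict(annotations.get(mid, {})) if annotations else {}
        graph.add_node(
            mid,
            ec=";".join(ann.get("ec", []) or []),
            cath=";".join(ann.get("cath", []) or []),
        )
    edge_rows = []
    for pair in sorted(pair_scores, key=sorted):
        score, definition, method = pair_scores[pair]
        if score >= cutoff:
            a, b = sorted(pair)
            graph.add_edge(a, b, score=score)
            edge_rows.append(
                {
                    "mech_a": a,
                    "mech_b": b,
                    "score": score,
                    "definition": definition,
                    "method": method,
                }
            )
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
    if tsv_path is not None:
        pd.DataFrame(
            edge_rows, columns=["mech_a", "mech_b", "score", "definition", "method"]
        ).to_csv(tsv_path, sep="\t", index=False)
    return graph
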