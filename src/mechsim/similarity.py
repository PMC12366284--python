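"""Jaccard-based similarity of catalytic steps and whole mechanisms.

Two scoring methods exist for every arrow-env definition, six score
flavours in total (named e.g. "two_away unordered"):

*unordered*
    the Jaccard/Tanimoto index |A ∩ B| / |A ∪ B| of the two sets of
    arrow-env canonical keys; 1 means every arrow-env is shared, 0 means
    none are.
*ordered*
    the simple average of the env-set Jaccard and the Jaccard of the two
    sets of chains (the edges of the step graphs).

At mechanism level the env and chain sets are pooled across all steps
with no step-to-step alignment.  The Jaccard of two empty sets is taken
as 1 so that self-similarity is always exactly 1, even for chain-free
mechanisms.  Scores are symmetric and live in [0, 1].

For display, scores are rounded half-up to integer percentages
(0.41667 -> "42%"); machine output keeps the raw fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Union

import pandas as pd

from .arrowenv import ArrowEnvDefinition, DEFINITIONS, TWO_AWAY
from .model import CatalyticStep, Mechanism
from .stepgraph import build_step_graph

Comparable = Union[Mechanism, CatalyticStep]

METHODS = ("unordered", "ordered")


@dataclass(frozen=True)
class SimilarityScore:
    """One similarity score with its components.

    ``j_envs`` is the env-set Jaccard; ``j_chains`` the chain-set Jaccard
    (``None`` for unordered scores).  For ordered scores ``value`` is the
    mean of the two components.
    """

    value: float
    definition: str
    method: str
    level: str
    j_envs: float
    j_chains: float | None = None

    @property
    def percent(self) -> int:
        return percent_display(self.value)

    @property
    def name(self) -> str:
        return f"{self.definition} {self.method}"


def percent_display(value: float) -> int:
    """Round a [0,1] fraction half-up to an integer percentage."""
    return int(math.floor(value * 100.0 + 0.5))


def jaccard(a: Iterable, b: Iterable) -> float:
    """|a ∩ b| / |a ∪ b|, with the empty-vs-empty case defined as 1."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def step_envs(step: CatalyticStep, definition: ArrowEnvDefinition) -> frozenset[str]:
    return build_step_graph(step, definition).nodes


def step_chains(
    step: CatalyticStep, definition: ArrowEnvDefinition
) -> frozenset[tuple[str, str]]:
    return build_step_graph(step, definition).edges


def mechanism_envs(
    mech: Mechanism, definition: ArrowEnvDefinition
) -> frozenset[str]:
    """Distinct arrow-env keys pooled over all catalytic steps."""
    out: set[str] = set()
    for step in mech.steps:
        out |= step_envs(step, definition)
    return frozenset(out)


def mechanism_chains(
    mech: Mechanism, definition: ArrowEnvDefinition
) -> frozenset[tuple[str, str]]:
    """Distinct chains (step-graph edges) pooled over all steps."""
    out: set[tuple[str, str]] = set()
    for step in mech.steps:
        out |= step_chains(step, definition)
    return frozenset(out)


def _level(x: Comparable) -> str:
    if isinstance(x, Mechanism):
        return "mechanism"
    if isinstance(x, CatalyticStep):
        return "step"
    raise TypeError(f"cannot score object of type {type(x).__name__}")


def _envs(x: Comparable, definition: ArrowEnvDefinition) -> frozenset[str]:
    return (
        mechanism_envs(x, definition)
        if isinstance(x, Mechanism)
        else step_envs(x, definition)
    )


def _chains(x: Comparable, definition: ArrowEnvDefinition):
    return (
        mechanism_chains(x, definition)
        if isinstance(x, Mechanism)
        else step_chains(x, definition)
    )


def _check_pair(a: Comparable, b: Comparable) -> str:
    la, lb = _level(a), _level(b)
    if la != lb:
        raise TypeError(f"cannot compare a {la} with a {lb}")
    return la


def similarity_unordered(
    a: Comparable, b: Comparable, definition: ArrowEnvDefinition = TWO_AWAY
) -> SimilarityScore:
    """Jaccard of the two arrow-env key sets."""
    level = _check_pair(a, b)
    j = jaccard(_envs(a, definition), _envs(b, definition))
    return SimilarityScore(j, definition.name, "unordered", level, j_envs=j)


def similarity_ordered(
    a: Comparable, b: Comparable, definition: ArrowEnvDefinition = TWO_AWAY
) -> SimilarityScore:
    """Mean of the env-set Jaccard and the chain-set Jaccard."""
    level = _check_pair(a, b)
    j_envs = jaccard(_envs(a, definition), _envs(b, definition))
    j_chains = jaccard(_chains(a, definition), _chains(b, definition))
    return SimilarityScore(
        (j_envs + j_chains) / 2.0,
        definition.name,
        "ordered",
        level,
        j_envs=j_envs,
        j_chains=j_chains,
    )


def score_suite(a: Comparable, b: Comparable) -> pd.DataFrame:
    """All six (definition x method) scores for one pair, as a table with
    columns definition, method, score, percent, j_envs, j_chains."""
    rows = []
    for definition in DEFINITIONS.values():
        for method in METHODS:
            fn = similarity_unordered if method == "unordered" else similarity_ordered
            s = fn(a, b, definition)
            rows.append(
                {
                    "definition": s.definition,
                    "method": s.method,
                    "score": s.value,
                    "percent": s.percent,
                    "j_envs": s.j_envs,
                    "j_chains": s.j_chains,
                }
            )
    return pd.DataFrame(rows)
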