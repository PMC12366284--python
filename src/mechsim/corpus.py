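"""Corpus-level analyses: all-vs-all scoring, arrow-env usage statistics,
threshold clustering and EC/CATH agreement breakdowns.

These operations mirror the questions a curated mechanism corpus is asked:
how chemically diverse is it (how many distinct arrow-envs cover it, which
are ubiquitous, which are unique to one enzyme family), and do mechanisms
that score as similar belong to enzymes of the same fold (CATH superfamily
set) and the same reaction type (EC subsubclass, the first three EC
numbers)?
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .arrowenv import ArrowEnvDefinition, TWO_AWAY, extract_arrow_env
from .model import Mechanism
from .similarity import (
    jaccard,
    mechanism_chains,
    mechanism_envs,
    similarity_ordered,
    similarity_unordered,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# all-vs-all

def all_vs_all(
    mechs: Sequence[Mechanism],
    definition: ArrowEnvDefinition = TWO_AWAY,
    method: str = "unordered",
) -> pd.DataFrame:
    """Pairwise similarity over a corpus: n(n-1)/2 rows, ordered by
    (mech_a, mech_b), symmetric by construction.

    Env and chain sets are extracted once per mechanism, so runtime is
    linear in corpus size for extraction plus quadratic for the Jaccard
    comparisons.
    """
    if len(mechs) < 2:
        raise ValueError("all_vs_all needs at least two mechanisms")
    ids = [m.mechanism_id for m in mechs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate mechanism ids: {dupes}")
    if method not in ("unordered", "ordered"):
        raise ValueError(f"unknown method {method!r}")
    by_id = {m.mechanism_id: m for m in mechs}
    envs = {i: mechanism_envs(by_id[i], definition) for i in ids}
    chains = (
        {i: mechanism_chains(by_id[i], definition) for i in ids}
        if method == "ordered"
        else None
    )
    rows = []
    for a, b in itertools.combinations(sorted(ids), 2):
        j_envs = jaccard(envs[a], envs[b])
        if method == "unordered":
            score, j_chains = j_envs, None
        else:
            j_chains = jaccard(chains[a], chains[b])
            score = (j_envs + j_chains) / 2.0
        rows.append(
            {
                "mech_a": a,
                "mech_b": b,
                "definition": definition.name,
                "method": method,
                "score": score,
                "j_envs": j_envs,
                "j_chains": j_chains,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# usage statistics

@dataclass(frozen=True)
class CorpusStats:
    """Chemical-diversity statistics of a corpus under one definition.

    ``catalogue`` ranks every distinct arrow-env by the number of
    catalytic steps it appears in (columns: key, smarts, n_arrows,
    n_steps, n_mechanisms).
    """

    definition: str
    n_mechanisms: int
    n_steps: int
    n_arrows: int
    n_distinct_envs: int
    mean_arrows_per_env: float
    n_singleton_envs: int
    catalogue: pd.DataFrame = field(repr=False)

    def n_common_envs(self, min_steps: int = 20) -> int:
        """Number of envs seen in more than ``min_steps`` catalytic steps."""
        return int((self.catalogue["n_steps"] > min_steps).sum())

    def to_dict(self) -> dict:
        return {
            "definition": self.definition,
            "n_mechanisms": self.n_mechanisms,
            "n_steps": self.n_steps,
            "n_arrows": self.n_arrows,
            "n_distinct_envs": self.n_distinct_envs,
            "mean_arrows_per_env": self.mean_arrows_per_env,
            "n_singleton_envs": self.n_singleton_envs,
        }


def env_usage_stats(
    mechs: Sequence[Mechanism], definition: ArrowEnvDefinition = TWO_AWAY
) -> CorpusStats:
    """Count distinct arrow-envs and their spread over arrows, steps and
    mechanisms."""
    arrow_count: dict[str, int] = {}
    step_sets: dict[str, set] = {}
    mech_sets: dict[str, set] = {}
    smarts_of: dict[str, str] = {}
    n_steps = 0
    n_arrows = 0
    for mech in mechs:
        for step in mech.steps:
            n_steps += 1
            for arrow in step.arrows:
                n_arrows += 1
                env = extract_arrow_env(step, arrow, definition)
                key = env.canonical_key
                arrow_count[key] = arrow_count.get(key, 0) + 1
                step_sets.setdefault(key, set()).add((mech.mechanism_id, step.step_index))
                mech_sets.setdefault(key, set()).add(mech.mechanism_id)
                smarts_of.setdefault(key, env.smarts)
    catalogue = pd.DataFrame(
        [
            {
                "key": key,
                "smarts": smarts_of[key],
                "n_arrows": arrow_count[key],
                "n_steps": len(step_sets[key]),
                "n_mechanisms": len(mech_sets[key]),
            }
            for key in arrow_count
        ],
        columns=["key", "smarts", "n_arrows", "n_steps", "n_mechanisms"],
    ).sort_values(["n_steps", "key"], ascending=[False, True], ignore_index=True)
    n_distinct = len(arrow_count)
    return CorpusStats(
        definition=definition.name,
        n_mechanisms=len(mechs),
        n_steps=n_steps,
        n_arrows=n_arrows,
        n_distinct_envs=n_distinct,
        mean_arrows_per_env=(n_arrows / n_distinct) if n_distinct else 0.0,
        n_singleton_envs=sum(1 for s in mech_sets.values() if len(s) == 1),
        catalogue=catalogue,
    )


# ---------------------------------------------------------------------------
# EC / CATH breakdown

@dataclass(frozen=True)
class PairBreakdown:
    """Counts of above-cutoff pairs classified by fold and reaction-type
    agreement.

    ``cells`` holds the four (same/different CATH superfamily set) x
    (same/different EC subsubclass) counts.  Pairs whose CATH sets overlap
    partially are reported separately (never folded into same/different),
    as are pairs lacking usable annotations.
    """

    cutoff: float
    cells: Mapping[tuple[str, str], int]
    partial_overlap: int
    unannotated: int
    total_pairs: int

    def check_conservation(self) -> bool:
        return (
            sum(self.cells.values()) + self.partial_overlap + self.unannotated
            == self.total_pairs
        )


def _subsubclasses(ec_list: Iterable[str] | None) -> frozenset[str]:
    """First-three-level EC prefixes; wildcard or incomplete codes are
    treated as missing annotation."""
    out = set()
    for ec in ec_list or ():
        parts = str(ec).split(".")
        if len(parts) >= 3 and all(p.isdigit() for p in parts[:3]):
            out.add(".".join(parts[:3]))
    return frozenset(out)


def ec_cath_breakdown(
    scores: pd.DataFrame,
    annotations: Mapping[str, Mapping],
    cutoffs: Sequence[float],
) -> dict[float, PairBreakdown]:
    """Classify every above-cutoff pair for each cutoff.

    CATH-same means the two superfamily *sets* are equal; CATH-different
    means they are disjoint; anything in between is partial overlap.
    EC-same means the mechanisms share at least one EC subsubclass.
    """
    results: dict[float, PairBreakdown] = {}
    for cutoff in cutoffs:
        cells = {
            (c, e): 0
            for c in ("same_cath", "different_cath")
            for e in ("same_ec", "different_ec")
        }
        partial = 0
        unannotated = 0
        total = 0
        for row in scores.itertuples(index=False):
            if float(row.score) < cutoff:
                continue
            total += 1
            ann_a = annotations.get(str(row.mech_a)) or {}
            ann_b = annotations.get(str(row.mech_b)) or {}
            cath_a = frozenset(ann_a.get("cath") or ())
            cath_b = frozenset(ann_b.get("cath") or ())
            ec_a = _subsubclasses(ann_a.get("ec"))
            ec_b = _subsubclasses(ann_b.get("ec"))
            if not cath_a or not cath_b or not ec_a or not ec_b:
                unannotated += 1
                continue
            ec_cell = "same_ec" if ec_a & ec_b else "different_ec"
            if cath_a == cath_b:
                cells[("same_cath", ec_cell)] += 1
            elif not cath_a & cath_b:
                cells[("different_cath", ec_cell)] += 1
            else:
                partial += 1
        if unannotated:
            logger.warning(
                "cutoff %.2f: %d pairs excluded for missing annotations",
                cutoff,
                unannotated,
            )
        results[cutoff] = PairBreakdown(cutoff, cells, partial, unannotated, total)
    return results


# ---------------------------------------------------------------------------
# clustering

@dataclass(frozen=True)
class ClusterResult:
    components: tuple[frozenset[str], ...]  # size >= 2, largest first
    isolated: frozenset[str]
    graph: nx.Graph = field(repr=False)


def cluster_graph(scores: pd.DataFrame, cutoff: float) -> ClusterResult:
    """Connected components of the threshold graph at ``cutoff``."""
    from .formats import export_similarity_graph

    graph = export_similarity_graph(scores, cutoff)
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    multi = tuple(
        sorted(
            (c for c in comps if len(c) >= 2),
            key=lambda c: (-len(c), sorted(c)),
        )
    )
    isolated = frozenset(n for c in comps if len(c) == 1 for n in c)
    return ClusterResult(multi, isolated, graph)
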