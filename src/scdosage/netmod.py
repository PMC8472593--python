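"""Dense-module detection (MCODE) and hypergeometric gene-set enrichment.

MCODE (molecular complex detection) scores each vertex by the density of the
highest k-core of its closed neighborhood, then greedily grows complexes
from high-weight seeds, admitting neighbors whose weight is within
``node_score_cutoff`` of the seed's. Complexes without a k-core are
discarded and the optional haircut trims loosely attached (degree-1)
members. The complex score is density x size, favoring large dense clusters.

Enrichment is the one-sided hypergeometric upper tail of the overlap between
a query gene list and each annotated set, restricted to a declared
background universe, with Benjamini-Hochberg control across sets.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .types import GeneSetCollection


@dataclass(frozen=True)
class MCODEParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.node_score_cutoff <= 1:
            raise ValidationError("node_score_cutoff must lie in [0, 1]")
        if self.k_core < 1 or self.degree_cutoff < 1:
            raise ValidationError("k_core and degree_cutoff must be >= 1")


@dataclass(frozen=True)
class ModuleResult:
    members: frozenset
    score: float
    seed_gene: str
    density: float

    @property
    def size(self) -> int:
        return len(self.members)


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def _highest_kcore(graph: nx.Graph, k_min: int) -> tuple[int, nx.Graph] | None:
    """Highest k-core with k >= k_min of `graph`, or None if none exists."""
    if graph.number_of_edges() == 0:
        return None
    core = nx.core_number(graph)
    kmax = max(core.values())
    if kmax < k_min:
        return None
    nodes = [v for v, c in core.items() if c >= kmax]
    return kmax, graph.subgraph(nodes)


def mcode_vertex_weights(graph: nx.Graph, params: MCODEParams | None = None) -> dict:
    """weight(v) = k x density of the highest k-core of v's closed
    neighborhood; 0 when the neighborhood holds no k-core (isolated or
    tree-like surroundings)."""
    params = params or MCODEParams()
    weights: dict = {}
    for v in graph.nodes:
        closed = graph.subgraph([v, *graph.neighbors(v)])
        if closed.number_of_nodes() - 1 < params.degree_cutoff:
            weights[v] = 0.0
            continue
        best = _highest_kcore(closed, params.k_core)
        if best is None:
            weights[v] = 0.0
        else:
            k, sub = best
            weights[v] = k * _density(sub)
    return weights


def mcode_find_modules(
    graph: nx.Graph,
    params: MCODEParams | None = None,
    query: Iterable | None = None,
) -> list[ModuleResult]:
    """Greedy seeded complex detection.

    When ``query`` is given the graph is first restricted to those genes
    (the recurrent dosage genes of the concordance stage). Modules are
    vertex-disjoint; output is sorted by score descending, ties broken by
    size then lexicographic seed id.
    """
    params = params or MCODEParams()
    if query is not None:
        graph = graph.subgraph([g for g in query if g in graph])
    weights = mcode_vertex_weights(graph, params)
    order = sorted(weights, key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    modules: list[ModuleResult] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0:
            continue
        cutoff = (1.0 - params.node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt = []
            for v in frontier:
                for u in graph.neighbors(v):
                    if u in members or u in assigned:
                        continue
                    if weights[u] >= cutoff:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
        sub = graph.subgraph(members)
        core = _highest_kcore(sub, params.k_core)
        if core is None:
            continue  # no k-core: not a complex
        if params.haircut:
            sub = nx.k_core(sub, 2)
            members = set(sub.nodes)
        if params.fluff:
            extra = set()
            for v in members:
                for u in graph.neighbors(v):
                    if u in members or u in assigned:
                        continue
                    closed = graph.subgraph([u, *graph.neighbors(u)])
                    if _density(closed) > params.fluff_density:
                        extra.add(u)
            members |= extra
            sub = graph.subgraph(members)
        if len(members) < 2:
            continue
        dens = _density(sub)
        modules.append(
            ModuleResult(
                members=frozenset(members),
                score=dens * len(members),
                seed_gene=str(seed),
                density=dens,
            )
        )
        assigned |= members
    modules.sort(key=lambda m: (-m.score, -m.size, m.seed_gene))
    return modules


def modules_to_frame(modules: list[ModuleResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "module_id": [f"M{i + 1}" for i in range(len(modules))],
            "score": [m.score for m in modules],
            "density": [m.density for m in modules],
            "size": [m.size for m in modules],
            "seed": [m.seed_gene for m in modules],
            "members": [",".join(sorted(m.members)) for m in modules],
        }
    )


def hypergeometric_enrichment(
    query: Iterable,
    sets: GeneSetCollection,
    background: Iterable,
) -> pd.DataFrame:
    """One-sided over-representation test for each gene set.

    p = P(overlap >= observed) under sampling |query| genes without
    replacement from the background; sets are intersected with the
    background before testing and sets that vanish are dropped.
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise ValidationError(
            f"{len(stray)} query genes outside the background, e.g. {sorted(stray)[:5]}"
        )
    n_bg, n_q = len(background), len(query)
    rows = []
    for name in sets:
        members = sets.members(name) & background
        if not members:
            continue
        overlap = len(members & query)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(members), n_q))
        rows.append((name, overlap, len(members), n_q, n_bg, min(p, 1.0)))
    out = pd.DataFrame(
        rows,
        columns=["set_name", "overlap", "set_size", "query_size", "background_size", "p"],
    )
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out
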