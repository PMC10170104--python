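"""Pathway over-representation (hypergeometric tail) with topology-based
impact from relative betweenness centrality.

The reference metabolome (universe) defaults to the union of all compounds
appearing in the pathway library.  Impact of a pathway is the centrality mass
of its hit members over the total centrality of all members; pathways whose
members carry no centrality (e.g. edgeless membership lists) get impact 0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
from scipy.stats import hypergeom

from .feature_io import PathwayDef

__all__ = [
    "PathwayResult",
    "hypergeometric_enrichment",
    "relative_betweenness",
    "pathway_impact",
    "analyze_pathways",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayResult:
    name: str
    size: int          # pathway membership m
    hits: int          # query members found in the pathway
    p_value: float     # P(X >= hits), hypergeometric
    impact: float      # centrality-weighted hit share, in [0, 1]


def hypergeometric_enrichment(universe_size: int, pathway_size: int,
                              query_size: int, hits: int) -> float:
    """Exact upper-tail hypergeometric p value, P(X >= hits).

    ``universe_size`` compounds of which ``pathway_size`` are in the pathway;
    ``query_size`` drawn; ``hits`` of the draw land in the pathway.
    """
    N, m, n, k = universe_size, pathway_size, query_size, hits
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError(f"infeasible sizes: N={N}, m={m}, n={n}")
    if not (0 <= k <= min(m, n)):
        raise ValueError(f"infeasible hit count k={k} for m={m}, n={n}")
    if k < max(0, m + n - N):
        raise ValueError(f"k={k} below the feasible minimum {max(0, m + n - N)}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, m, n))


def relative_betweenness(pathway: PathwayDef) -> dict[str, float]:
    """Betweenness centrality per member, normalized by (|V|-1)(|V|-2)/2.

    The graph is undirected and unweighted; shortest-path ties are split
    fractionally.  Isolated members get centrality 0.
    """
    g = nx.Graph()
    g.add_nodes_from(pathway.members)
    g.add_edges_from(pathway.edges)
    return {node: float(c) for node, c in
            nx.betweenness_centrality(g, normalized=True).items()}


def pathway_impact(pathway: PathwayDef, hit_ids: Iterable[str]) -> float:
    """Centrality mass of the hits over total member centrality (0 if none)."""
    hits = set(hit_ids)
    extra = hits - set(pathway.members)
    if extra:
        raise ValueError(f"hit ids not in pathway {pathway.name!r}: {sorted(extra)}")
    centrality = relative_betweenness(pathway)
    denom = sum(centrality.values())
    if denom == 0:
        return 0.0
    return sum(centrality[h] for h in hits) / denom


def analyze_pathways(query: Sequence[str], library: Sequence[PathwayDef],
                     universe: Iterable[str] | None = None) -> list[PathwayResult]:
    """Over-representation and impact for every pathway, sorted by p ascending.

    Query ids outside the universe are dropped with a logged warning.  With
    ``universe=None`` the reference metabolome is the union of all library
    members.
    """
    if not library:
        raise ValueError("pathway library is empty")
    if universe is None:
        universe_set: set[str] = set()
        for pw in library:
            universe_set.update(pw.members)
    else:
        universe_set = set(universe)
    query_set = set(query)
    dropped = query_set - universe_set
    if dropped:
        logger.warning("%d query compound(s) outside the reference metabolome dropped: %s",
                       len(dropped), sorted(dropped))
    query_used = query_set & universe_set
    results = []
    for pw in library:
        members = set(pw.members)
        hits = query_used & members
        p = hypergeometric_enrichment(len(universe_set), len(members),
                                      len(query_used), len(hits))
        impact = pathway_impact(pw, hits)
        results.append(PathwayResult(pw.name, len(members), len(hits), p, impact))
    results.sort(key=lambda r: (r.p_value, r.name))
    return results
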