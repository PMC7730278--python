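"""Scaffold protein-interaction network and gene-set enrichment.

Builds the direction-annotated network induced by the scaffold genes on a
supplied scored edge list, detects hubs by degree, and tests gene-set
over-representation with the one-sided hypergeometric tail and BH FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .de import adjust_fdr
from .trend import ScaffoldSet

__all__ = [
    "PPINetwork",
    "build_network",
    "find_hubs",
    "enrich_sets",
]

#: Minimum combined interaction score retained by default ("medium
#: confidence" convention for 0-1 scores).
DEFAULT_MIN_SCORE = 0.4

#: Default hub threshold: nodes with at least this many interactions.
DEFAULT_HUB_DEGREE = 7


@dataclass
class PPINetwork:
    """Direction-annotated interaction network over scaffold genes."""

    graph: nx.Graph
    min_score: float

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def direction_counts(self) -> dict:
        counts = {"up": 0, "down": 0, "nonconsistent": 0}
        for _, d in self.graph.nodes(data="direction"):
            counts[d] += 1
        return counts

    def nodes_table(self, hub_degree: int = DEFAULT_HUB_DEGREE) -> pd.DataFrame:
        hubs = set(find_hubs(self, min_degree=hub_degree))
        rows = [
            {
                "gene": g,
                "direction": data["direction"],
                "degree": self.graph.degree[g],
                "is_hub": g in hubs,
            }
            for g, data in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows).set_index("gene")

    def summary(self) -> str:
        c = self.direction_counts()
        return (
            f"Scaffold network: {self.graph.number_of_nodes()} nodes "
            f"({c['down']} down, {c['up']} up, {c['nonconsistent']} "
            f"nonconsistent), {self.n_edges} edges at score >= {self.min_score}"
        )


def _directions_from(genes) -> dict:
    if isinstance(genes, ScaffoldSet):
        return genes.directions.to_dict()
    if isinstance(genes, dict):
        return dict(genes)
    return {g: "nonconsistent" for g in genes}


def build_network(genes, edges: pd.DataFrame,
                  min_score: float = DEFAULT_MIN_SCORE) -> PPINetwork:
    """Induced subgraph of the scored edge list on the scaffold genes.

    ``genes`` may be a :class:`ScaffoldSet`, a gene -> direction mapping,
    or a plain gene list (directions default to nonconsistent). Edges
    referencing genes outside the set are dropped with a warning summary;
    self-loops are discarded; edges below ``min_score`` are filtered.
    """
    directions = _directions_from(genes)
    scores = edges["score"].to_numpy(dtype=float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("edge scores must lie in [0, 1]")
    g = nx.Graph()
    g.add_nodes_from(
        (gene, {"direction": d}) for gene, d in directions.items()
    )
    known = set(directions)
    dropped = 0
    for a, b, s in edges[["gene_a", "gene_b", "score"]].itertuples(index=False):
        if a == b:
            continue
        if a not in known or b not in known:
            dropped += 1
            continue
        if s >= min_score:
            g.add_edge(a, b, score=float(s))
    if dropped:
        warnings.warn(
            f"dropped {dropped} edges referencing genes outside the set",
            stacklevel=2,
        )
    return PPINetwork(graph=g, min_score=min_score)


def find_hubs(net: PPINetwork, min_degree: int = DEFAULT_HUB_DEGREE) -> list:
    """Nodes with degree >= ``min_degree``, by descending degree then id."""
    deg = dict(net.graph.degree())
    hubs = [g for g, d in deg.items() if d >= min_degree]
    return sorted(hubs, key=lambda g: (-deg[g], g))


def enrich_sets(query, universe, annotation: dict,
                q_threshold: float | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a query.

    For each term with K annotated genes in the universe of size N, the
    probability of observing at least k of them among the n query genes is
    the upper hypergeometric tail; q-values are BH across tested terms.
    Terms with no annotated gene in the universe are skipped. Returns a
    DataFrame (term, k, K, n, N, p, q) sorted by p; ``q_threshold``
    optionally filters the output.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for term, genes in annotation.items():
        members = set(genes) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(result):
        result["q"] = adjust_fdr(result["p"].to_numpy())
        result = result.sort_values(["p", "term"]).reset_index(drop=True)
    else:
        result["q"] = np.array([], dtype=float)
    if q_threshold is not None:
        result = result[result["q"] < q_threshold].reset_index(drop=True)
    return result
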