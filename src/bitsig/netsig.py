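"""Signature connectivity networks from up/down expression comparisons.

The all-vs-all shared-gene counts of an expression compendium form a graph:
experiments are nodes, the merged number of shared up- plus down-regulated
genes is the edge weight. This module merges the two directional comparison
results, extracts weighted graphs (by weight threshold or top-k edges),
pulls one-hop sub-networks around query perturbations, computes second-order
similarity (common-neighbor counts, by running the bit engine on the
binarized adjacency matrix), and scores signature/gene-set overlaps with the
one-sided hypergeometric tail used in Fisher's exact enrichment tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .bitpack import pack
from .engine import ComparisonResult, compare_self

__all__ = [
    "EdgeTable",
    "merge_up_down",
    "build_graph",
    "subnetwork",
    "second_order_similarity",
    "overlap_enrichment",
    "DEFAULT_EDGE_CUT",
]

# adjacency binarization cut: edges sharing fewer up/down genes than this are
# indistinguishable from the unrelated-pair background
DEFAULT_EDGE_CUT = 20


@dataclass
class EdgeTable:
    """Weighted undirected edges plus optional per-node signature sizes."""

    edges: list  # (node_i id, node_j id, weight)
    node_sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for i, j, w in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node {i!r}")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"duplicate edge {i!r}-{j!r}")
            seen.add(key)
            if w < 0:
                raise ValueError(f"negative weight on edge {i!r}-{j!r}")

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> list:
        out: dict = {}
        for i, j, _ in self.edges:
            out.setdefault(i)
            out.setdefault(j)
        return list(out)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, j, w in self.edges:
            g.add_edge(i, j, weight=float(w))
        for n, s in self.node_sizes.items():
            if n in g:
                g.nodes[n]["signature_size"] = int(s)
        return g


def merge_up_down(up: ComparisonResult, down: ComparisonResult) -> ComparisonResult:
    """Cellwise sum of the up-shared and down-shared count tables.

    Both inputs must be AND comparisons over identical id sets; the merged
    count for a pair is (shared up genes) + (shared down genes).
    """
    for r, name in ((up, "up"), (down, "down")):
        if r.operator != "AND":
            raise ValueError(f"{name} result uses {r.operator}, expected AND")
    if up.query_ids != down.query_ids or up.library_ids != down.library_ids:
        raise ValueError("up and down results cover different signatures")
    if up.counts.shape != down.counts.shape:
        raise ValueError(
            f"shape mismatch: up {up.counts.shape} vs down {down.counts.shape}"
        )
    if up.is_self != down.is_self:
        raise ValueError("cannot merge a self-comparison with a cross-comparison")
    return ComparisonResult(
        query_ids=up.query_ids,
        library_ids=up.library_ids,
        counts=up.counts.astype(np.uint32) + down.counts.astype(np.uint32),
        operator="AND",
        K=up.K + down.K,
        is_self=up.is_self,
    )


def _pair_rows(merged: ComparisonResult) -> list[tuple[int, int, int]]:
    if not merged.is_self:
        raise ValueError("graph construction expects a self-comparison result")
    iu = np.triu_indices(merged.counts.shape[0], k=1)
    w = merged.counts[iu]
    keep = w > 0
    return list(zip(iu[0][keep].tolist(), iu[1][keep].tolist(), w[keep].tolist()))


def build_graph(
    merged: ComparisonResult,
    threshold: int | None = None,
    top_k: int | None = None,
    node_sizes: Mapping | None = None,
) -> EdgeTable:
    """Edge table from a merged self-comparison.

    Exactly one of ``threshold`` (keep pairs with weight >= t) or ``top_k``
    (keep the k heaviest pairs) must be given. Ties in top-k are broken
    deterministically: weight descending, then smaller i, then smaller j.
    """
    if (threshold is None) == (top_k is None):
        raise ValueError("give exactly one of threshold= or top_k=")
    rows = _pair_rows(merged)
    if threshold is not None:
        if threshold < 0:
            raise ValueError("threshold must be >= 0")
        kept = [r for r in rows if r[2] >= threshold]
    else:
        if top_k <= 0:
            raise ValueError("top_k must be positive")
        rows.sort(key=lambda r: (-r[2], r[0], r[1]))
        kept = rows[:top_k]
    ids = merged.query_ids
    edges = [(ids[i], ids[j], int(w)) for i, j, w in kept]
    sizes = dict(node_sizes) if node_sizes else {}
    return EdgeTable(edges=edges, node_sizes=sizes)


def subnetwork(graph: EdgeTable, seeds: Iterable, top_edges: int | None = None) -> EdgeTable:
    """One-hop neighborhood closure around seed nodes.

    Keeps every edge whose endpoints both lie in seeds-union-neighbors(seeds),
    then optionally trims to the ``top_edges`` heaviest (same deterministic
    tie-breaking as :func:`build_graph`).
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    present = set(graph.nodes())
    missing = seeds - present
    if missing == seeds:
        raise ValueError(
            f"no seed found in the graph; missing: {sorted(map(str, missing))}"
        )
    keep_nodes = set(seeds)
    for i, j, _ in graph.edges:
        if i in seeds:
            keep_nodes.add(j)
        if j in seeds:
            keep_nodes.add(i)
    order = {n: k for k, n in enumerate(graph.nodes())}
    kept = [
        (i, j, w) for i, j, w in graph.edges if i in keep_nodes and j in keep_nodes
    ]
    if top_edges is not None:
        if top_edges <= 0:
            raise ValueError("top_edges must be positive")
        kept.sort(key=lambda e: (-e[2], order[e[0]], order[e[1]]))
        kept = kept[:top_edges]
    sizes = {n: s for n, s in graph.node_sizes.items() if n in keep_nodes}
    return EdgeTable(edges=kept, node_sizes=sizes)


def second_order_similarity(graph: EdgeTable, edge_cut: int = DEFAULT_EDGE_CUT) -> ComparisonResult:
    """Common-neighbor counts via the bit engine on the binarized adjacency.

    Edges with weight >= ``edge_cut`` become 1s of a node x node adjacency
    matrix whose columns are packed as signatures; the AND self-comparison of
    that matrix answers, for every node pair (i, j), how many nodes are
    incident on both. Depends only on the binarized adjacency, so rescaling
    weights above the cut changes nothing.
    """
    if edge_cut < 0:
        raise ValueError("edge_cut must be >= 0")
    nodes = graph.nodes()
    idx = {n: k for k, n in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=np.uint8)
    for i, j, w in graph.edges:
        if w >= edge_cut:
            adj[idx[i], idx[j]] = 1
            adj[idx[j], idx[i]] = 1
    if not adj.any():
        raise ValueError(f"no edges survive the cut at weight >= {edge_cut}")
    packed = pack(adj, feature_ids=nodes, signature_ids=nodes)
    return compare_self(packed, "AND")


def overlap_enrichment(signature: Iterable, gene_set: Iterable, universe_size: int) -> float:
    """One-sided (greater) hypergeometric tail for a signature/gene-set overlap.

    Probability of drawing at least the observed overlap when ``len(signature)``
    features are sampled without replacement from a universe of
    ``universe_size`` containing ``len(gene_set)`` marked features — the set
    overlap half of a Fisher's exact enrichment test. The observed overlap is
    computed with the packed AND count.
    """
    sig = set(signature)
    gs = set(gene_set)
    union = sorted(sig | gs, key=str)
    if universe_size < len(union):
        raise ValueError(
            f"universe size {universe_size} smaller than the union of the two sets "
            f"({len(union)})"
        )
    if sig and gs:
        indicators = np.zeros((len(union), 2), dtype=np.uint8)
        for k, f in enumerate(union):
            indicators[k, 0] = f in sig
            indicators[k, 1] = f in gs
        packed = pack(indicators, feature_ids=union, signature_ids=["sig", "set"])
        overlap = int(compare_self(packed, "AND").counts[0, 1])
    else:
        overlap = 0
    # P(X >= overlap), X ~ Hypergeom(universe_size, |gene_set|, |signature|)
    return float(hypergeom.sf(overlap - 1, universe_size, len(gs), len(sig)))
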