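"""Link-prediction scorers over the homogeneous chemical graph.

Two families are implemented:

* **Path scorers** SP_2 and SP_3: Dijkstra shortest paths (edge weights
  summed) between all non-adjacent pairs; a pair is a candidate when its
  minimum-weight path has exactly 2 or 3 edges, and its score is that
  minimal weight sum.  Because edge weights are similarities, the final
  ranking is *descending* -- a larger path-weight sum means the chain of
  similarities supporting the link is stronger.  (The alternative of
  inverting similarities into distances and ranking ascending is available
  via ``rank_predictions(ascending=True)``.)

* **Neighborhood scorers** on the unweighted neighbor structure:
  common neighbors (CN), Jaccard, Dice, Adamic-Adar (AA, 1/log k over
  common neighbors), resource allocation (RA, 1/k), and the
  degree-normalized 3-path score L3, which alone uses edge weights:
  sum over paths a-u-v-b of (w_au * w_uv * w_vb) / sqrt(k_u * k_v).

Predictions are new links only: pairs adjacent in the scored graph are
never emitted.  Paths through artificial bridge edges are flagged so they
can be filtered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from fdinet.graph_build import HomogeneousGraph

logger = logging.getLogger(__name__)

METHODS = ("sp2", "sp3", "aa", "cn", "jaccard", "ra", "l3", "dice")
NEIGHBORHOOD_METHODS = ("aa", "cn", "jaccard", "ra", "l3", "dice")

#: Base of the logarithm in the Adamic-Adar score (natural log by the usual
#: network-science convention).
AA_LOG_BASE = math.e


@dataclass(frozen=True)
class Prediction:
    """A scored candidate link (unordered, non-adjacent pair)."""

    node_a: str
    node_b: str
    method: str
    score: float
    rank: int | None = None
    uses_bridge: bool = False

    @property
    def pair(self) -> tuple[str, str]:
        return (self.node_a, self.node_b)


def _nx(graph: HomogeneousGraph | nx.Graph) -> nx.Graph:
    return graph.graph if isinstance(graph, HomogeneousGraph) else graph


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def _is_fd_pair(g: nx.Graph, a: str, b: str) -> bool:
    kinds = {g.nodes[a].get("kind"), g.nodes[b].get("kind")}
    return kinds == {"drug", "food_compound"}


# ---------------------------------------------------------------------------
# Pairwise neighborhood scorers
# ---------------------------------------------------------------------------

def cn_score(graph: HomogeneousGraph | nx.Graph, pair: tuple[str, str]) -> float:
    """Number of common neighbors of the pair."""
    g = _nx(graph)
    a, b = pair
    return float(len(set(g[a]) & set(g[b])))


def jaccard_score(graph: HomogeneousGraph | nx.Graph, pair: tuple[str, str]) -> float:
    """|Γ(a) ∩ Γ(b)| / |Γ(a) ∪ Γ(b)|; 0 when the union is empty."""
    g = _nx(graph)
    a, b = pair
    na, nb = set(g[a]), set(g[b])
    union = len(na | nb)
    return len(na & nb) / union if union else 0.0


def dice_score(graph: HomogeneousGraph | nx.Graph, pair: tuple[str, str]) -> float:
    """2 |Γ(a) ∩ Γ(b)| / (|Γ(a)| + |Γ(b)|); satisfies Dice = 2J / (1 + J)."""
    g = _nx(graph)
    a, b = pair
    na, nb = set(g[a]), set(g[b])
    total = len(na) + len(nb)
    return 2.0 * len(na & nb) / total if total else 0.0


def aa_score(
    graph: HomogeneousGraph | nx.Graph,
    pair: tuple[str, str],
    log_base: float = AA_LOG_BASE,
) -> float:
    """Adamic-Adar: sum of 1 / log(k_z) over common neighbors z.

    A common neighbor necessarily has degree >= 2 in a simple graph, so
    log(k_z) > 0; a degree <= 1 neighbor (possible only on degenerate input)
    contributes 0 with a warning.
    """
    g = _nx(graph)
    a, b = pair
    total = 0.0
    for z in set(g[a]) & set(g[b]):
        k = g.degree(z)
        if k <= 1:
            logger.warning("common neighbor %r has degree %d; contribution skipped", z, k)
            continue
        total += 1.0 / (math.log(k) / math.log(log_base))
    return total


def ra_score(graph: HomogeneousGraph | nx.Graph, pair: tuple[str, str]) -> float:
    """Resource allocation: sum of 1 / k_z over common neighbors z."""
    g = _nx(graph)
    a, b = pair
    return sum(1.0 / g.degree(z) for z in set(g[a]) & set(g[b]) if g.degree(z) > 0)


def l3_score(graph: HomogeneousGraph | nx.Graph, pair: tuple[str, str]) -> float:
    """Degree-normalized weighted 3-path score.

    Sum over simple paths a-u-v-b (u adjacent to a, v adjacent to b, u-v an
    edge, endpoints excluded as intermediates) of
    ``w_au * w_uv * w_vb / sqrt(k_u * k_v)`` with unweighted degrees k.
    """
    g = _nx(graph)
    a, b = pair
    total = 0.0
    for u in g[a]:
        if u == b:
            continue
        w_au = g[a][u]["weight"]
        for v in g[u]:
            if v == a or v == b or v == u:
                continue
            if not g.has_edge(v, b):
                continue
            total += (
                w_au * g[u][v]["weight"] * g[v][b]["weight"]
                / math.sqrt(g.degree(u) * g.degree(v))
            )
    return total


_PAIR_SCORERS = {
    "aa": aa_score,
    "cn": cn_score,
    "jaccard": jaccard_score,
    "ra": ra_score,
    "l3": l3_score,
    "dice": dice_score,
}


# ---------------------------------------------------------------------------
# Batch prediction
# ---------------------------------------------------------------------------

def _common_neighbor_candidates(g: nx.Graph) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    for z in g:
        for a, b in combinations(sorted(g[z]), 2):
            if not g.has_edge(a, b):
                pairs.add((a, b))
    return pairs


def _l3_candidates(g: nx.Graph) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    for u, v in g.edges():
        for a in g[u]:
            if a == v:
                continue
            for b in g[v]:
                if b == u or b == a:
                    continue
                if not g.has_edge(a, b):
                    pairs.add(_canonical(a, b))
    return pairs


def neighborhood_scores(
    graph: HomogeneousGraph | nx.Graph,
    method: str,
    fdi_only: bool = False,
) -> list[Prediction]:
    """Score every candidate non-adjacent pair with one neighborhood method.

    Candidates are pairs with at least one common neighbor (for L3: pairs
    joined by some 3-edge path), i.e. exactly the pairs that can receive a
    positive score.  ``fdi_only`` keeps only drug / food-compound pairs.
    """
    if method not in _PAIR_SCORERS:
        raise ValueError(f"unknown neighborhood method {method!r}; known: {NEIGHBORHOOD_METHODS}")
    g = _nx(graph)
    scorer = _PAIR_SCORERS[method]
    candidates = _l3_candidates(g) if method == "l3" else _common_neighbor_candidates(g)
    preds = []
    for a, b in sorted(candidates):
        if fdi_only and not _is_fd_pair(g, a, b):
            continue
        score = scorer(graph, (a, b))
        if score > 0.0:
            preds.append(Prediction(node_a=a, node_b=b, method=method, score=score))
    return preds


def shortest_path_scores(
    graph: HomogeneousGraph | nx.Graph,
    length: int,
    fdi_only: bool = False,
    exclude_bridge_paths: bool = False,
) -> list[Prediction]:
    """Dijkstra path scores for pairs whose shortest path has ``length`` edges.

    For each non-adjacent pair whose minimum-weight-sum path (weights summed)
    consists of exactly ``length`` edges, the score is that minimal sum.
    Pairs whose shortest path has a different edge count are not candidates.
    Paths traversing an artificial bridge edge are flagged ``uses_bridge``
    and can be dropped with ``exclude_bridge_paths``.
    """
    if length not in (2, 3):
        raise ValueError("path length must be 2 or 3")
    g = _nx(graph)
    preds = []
    for source in g:
        dists, paths = nx.single_source_dijkstra(g, source, weight="weight")
        for target, path in paths.items():
            if target <= source or len(path) - 1 != length:
                continue
            if g.has_edge(source, target):
                continue
            if fdi_only and not _is_fd_pair(g, source, target):
                continue
            uses_bridge = any(
                g[u][v].get("is_bridge", False) for u, v in zip(path, path[1:])
            )
            if exclude_bridge_paths and uses_bridge:
                continue
            preds.append(
                Prediction(
                    node_a=source,
                    node_b=target,
                    method=f"sp{length}",
                    score=dists[target],
                    uses_bridge=uses_bridge,
                )
            )
    return preds


def predict(
    graph: HomogeneousGraph | nx.Graph,
    method: str,
    fdi_only: bool = False,
    ascending: bool = False,
) -> list[Prediction]:
    """Run one scorer and return the ranked prediction list."""
    if method in ("sp2", "sp3"):
        preds = shortest_path_scores(graph, int(method[-1]), fdi_only=fdi_only)
    else:
        preds = neighborhood_scores(graph, method, fdi_only=fdi_only)
    return rank_predictions(preds, ascending=ascending)


def rank_predictions(
    predictions: Iterable[Prediction], ascending: bool = False
) -> list[Prediction]:
    """Order predictions and fill 1-based ranks.

    Default is descending by score (preference to stronger similarity
    chains); ties break lexicographically on (node_a, node_b), so the
    ranking is deterministic and independent of input order.
    """
    sign = 1.0 if ascending else -1.0
    ordered = sorted(predictions, key=lambda p: (sign * p.score, p.node_a, p.node_b))
    return [replace(p, rank=i + 1) for i, p in enumerate(ordered)]


def write_predictions_tsv(predictions: Sequence[Prediction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tmethod\tscore\trank\tuses_bridge\n")
        for p in predictions:
            fh.write(
                f"{p.node_a}\t{p.node_b}\t{p.method}\t{p.score!r}\t"
                f"{p.rank if p.rank is not None else ''}\t{int(p.uses_bridge)}\n"
            )


def read_predictions_tsv(path: str | Path) -> list[Prediction]:
    preds = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            a, b, method, score, rank, uses_bridge = line.rstrip("\n").split("\t")
            preds.append(
                Prediction(
                    a, b, method, float(score),
                    int(rank) if rank else None, bool(int(uses_bridge)),
                )
            )
    return preds
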