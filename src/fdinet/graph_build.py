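"""Sparse homogeneous graph construction from the similarity profile.

Pipeline order: the raw Tanimoto profile is thresholded (default >= 0.6,
inclusive, and zero-score pairs are always dropped); surviving edges are
re-weighted by the composition contribution -- drug-drug edges keep their
score, food-drug edges are multiplied by the food compound's contribution,
food-food edges by the larger of the two contributions; then a second,
more relaxed threshold (default 0.5; 0.3 for the relaxed batch) is applied
to the updated weights.

The thresholded graph typically falls apart into disjoint components (the
*disjoint* variant).  The *joint* variant chains the components together
with artificial bridge edges of tiny weight (default 1e-5) between randomly
chosen nodes, so scorers needing a connected graph can run; bridges are
tagged and never count as recoverable links in evaluation.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from fdinet.ingest import ChemNode, pair_contribution
from fdinet.similarity import SimilarityEdge

DEFAULT_TANIMOTO_THRESHOLD = 0.6
DEFAULT_CONTRIBUTION_THRESHOLD = 0.5
RELAXED_CONTRIBUTION_THRESHOLD = 0.3
DEFAULT_BRIDGE_WEIGHT = 1e-5


@dataclass
class HomogeneousGraph:
    """An undirected weighted graph of chemical nodes.

    Wraps a :class:`networkx.Graph` whose nodes carry a ``kind`` attribute
    (``drug`` / ``food_compound``) and whose edges carry ``weight``,
    ``subnetwork`` (DD/FF/FD) and ``is_bridge`` attributes.  ``bridges``
    lists the artificial edges added by :func:`joinify`.
    """

    graph: nx.Graph
    bridges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)

    def non_bridge_edges(self) -> list[tuple[str, str, dict]]:
        return [(u, v, d) for u, v, d in self.graph.edges(data=True) if not d.get("is_bridge")]

    def copy(self) -> "HomogeneousGraph":
        return HomogeneousGraph(graph=self.graph.copy(), bridges=list(self.bridges))

    def summary(self) -> dict:
        kinds = nx.get_node_attributes(self.graph, "kind")
        counts: dict[str, int] = {}
        for _, _, d in self.graph.edges(data=True):
            key = "bridge" if d.get("is_bridge") else d.get("subnetwork", "?")
            counts[key] = counts.get(key, 0) + 1
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_drugs": sum(1 for k in kinds.values() if k == "drug"),
            "n_food_compounds": sum(1 for k in kinds.values() if k == "food_compound"),
            "n_edges": self.graph.number_of_edges(),
            "edges_by_subnetwork": dict(sorted(counts.items())),
            "n_components": self.n_components,
            "n_bridges": len(self.bridges),
            "connected": self.graph.number_of_nodes() > 0 and nx.is_connected(self.graph),
        }


def apply_threshold(edges: Iterable[SimilarityEdge], tc: float) -> list[SimilarityEdge]:
    """Keep edges whose similarity score is >= ``tc``; zero scores always drop."""
    if not 0.0 <= tc <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [e for e in edges if e.score > 0.0 and e.score >= tc]


def update_scores(
    edges: Iterable[SimilarityEdge],
    nodes: Sequence[ChemNode],
    contributions: Mapping[tuple[str, str], float],
) -> list[SimilarityEdge]:
    """Re-weight similarity edges by the composition contribution.

    Returns new edges whose ``score`` field holds the updated weight:
    ``score * pair_contribution``.  Drug-drug edges are preserved; weights
    never increase because contributions are <= 1.
    """
    by_id = {n.node_id: n for n in nodes}
    out = []
    for e in edges:
        factor = pair_contribution(by_id[e.node_a], by_id[e.node_b], contributions)
        out.append(replace(e, score=e.score * factor))
    return out


def apply_contribution_threshold(
    edges: Iterable[SimilarityEdge], t2: float
) -> list[SimilarityEdge]:
    """Keep edges whose updated weight is >= ``t2`` (the second threshold)."""
    if not 0.0 <= t2 <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [e for e in edges if e.score >= t2]


def build_graph(
    edges: Iterable[SimilarityEdge],
    nodes: Sequence[ChemNode] | Mapping[str, str] | None = None,
) -> HomogeneousGraph:
    """Assemble the disjoint homogeneous graph from weighted edges.

    ``nodes`` (a ChemNode list or a node_id -> kind mapping) may add isolated
    nodes and supplies kind labels; endpoints of edges are always included.
    """
    g = nx.Graph()
    kind_of: dict[str, str] = {}
    if nodes is not None:
        if isinstance(nodes, Mapping):
            kind_of = dict(nodes)
        else:
            kind_of = {n.node_id: n.kind for n in nodes}
        for node_id, kind in kind_of.items():
            g.add_node(node_id, kind=kind)
    for e in edges:
        g.add_edge(e.node_a, e.node_b, weight=e.score, subnetwork=e.subnetwork, is_bridge=False)
    for node_id, sub in _infer_kinds_from_edges(g).items():
        g.nodes[node_id].setdefault("kind", sub)
    return HomogeneousGraph(graph=g)


def _infer_kinds_from_edges(g: nx.Graph) -> dict[str, str]:
    """Best-effort kind labels from DD/FF/FD edge labels for unlabelled nodes."""
    inferred: dict[str, str] = {}
    for u, v, d in g.edges(data=True):
        sub = d.get("subnetwork")
        if sub == "DD":
            inferred.setdefault(u, "drug")
            inferred.setdefault(v, "drug")
        elif sub == "FF":
            inferred.setdefault(u, "food_compound")
            inferred.setdefault(v, "food_compound")
    return inferred


def joinify(
    hg: HomogeneousGraph,
    bridge_weight: float = DEFAULT_BRIDGE_WEIGHT,
    seed: int = 0,
) -> HomogeneousGraph:
    """Connect the graph's components with artificial bridge edges.

    Component order is shuffled by ``seed`` and one node is drawn at random
    from each component; consecutive components are chained, adding exactly
    ``n_components - 1`` edges of weight ``bridge_weight``.  The tiny default
    weight keeps bridges nearly inert in weighted scorers while making
    neighborhood scorers that need a connected graph applicable.
    """
    out = hg.copy()
    components = [sorted(c) for c in nx.connected_components(out.graph)]
    if len(components) <= 1:
        return out
    rng = random.Random(seed)
    components.sort(key=lambda c: c[0])
    rng.shuffle(components)
    anchors = [rng.choice(c) for c in components]
    for a, b in zip(anchors, anchors[1:]):
        u, v = (a, b) if a < b else (b, a)
        out.graph.add_edge(u, v, weight=bridge_weight, subnetwork="bridge", is_bridge=True)
        out.bridges.append((u, v))
    return out


def from_toy(toy) -> HomogeneousGraph:
    """Build a HomogeneousGraph from a fixtures.ToyGraph."""
    g = nx.Graph()
    for n in toy.nodes:
        g.add_node(n, kind=toy.labels.get(n, "drug"))
    for u, v, w in toy.edges:
        ka, kb = toy.labels.get(u, "drug"), toy.labels.get(v, "drug")
        n_drugs = (ka == "drug") + (kb == "drug")
        sub = {2: "DD", 1: "FD", 0: "FF"}[n_drugs]
        g.add_edge(u, v, weight=w, subnetwork=sub, is_bridge=False)
    return HomogeneousGraph(graph=g)


# ---------------------------------------------------------------------------
# Interchange
# ---------------------------------------------------------------------------

def write_graph_tsv(hg: HomogeneousGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\tsubnetwork\tis_bridge\n")
        for u, v, d in sorted(hg.graph.edges(data=True)):
            a, b = (u, v) if u < v else (v, u)
            fh.write(
                f"{a}\t{b}\t{d['weight']!r}\t{d.get('subnetwork', '?')}\t"
                f"{int(bool(d.get('is_bridge')))}\n"
            )


def read_graph_tsv(path: str | Path, kinds: Mapping[str, str] | None = None) -> HomogeneousGraph:
    g = nx.Graph()
    bridges = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            a, b, w, sub, is_bridge = line.rstrip("\n").split("\t")
            bridge = bool(int(is_bridge))
            g.add_edge(a, b, weight=float(w), subnetwork=sub, is_bridge=bridge)
            if bridge:
                bridges.append((a, b))
    if kinds:
        for node_id, kind in kinds.items():
            if node_id in g:
                g.nodes[node_id]["kind"] = kind
    for node_id, kind in _infer_kinds_from_edges(g).items():
        g.nodes[node_id].setdefault("kind", kind)
    return HomogeneousGraph(graph=g, bridges=bridges)


def write_summary_json(hg: HomogeneousGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(hg.summary(), fh, indent=1, sort_keys=True)
        fh.write("\n")
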