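"""Independent brute-force reference implementations for scorer checks.

Everything here works directly on explicit edge lists with plain Python
set/loop arithmetic -- no networkx, no shared code with the package -- so a
match between package scorers and these oracles is meaningful.
"""

from __future__ import annotations

import math
from itertools import combinations


def adjacency(edges):
    """edge list [(u, v, w), ...] -> ({node: {nbr: w}}, node set)."""
    adj: dict[str, dict[str, float]] = {}
    nodes = set()
    for u, v, w in edges:
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w
        nodes.update((u, v))
    return adj, nodes


def brute_cn(edges, a, b):
    adj, _ = adjacency(edges)
    return float(len(set(adj.get(a, {})) & set(adj.get(b, {}))))


def brute_jaccard(edges, a, b):
    adj, _ = adjacency(edges)
    na, nb = set(adj.get(a, {})), set(adj.get(b, {}))
    return len(na & nb) / len(na | nb) if na | nb else 0.0


def brute_dice(edges, a, b):
    adj, _ = adjacency(edges)
    na, nb = set(adj.get(a, {})), set(adj.get(b, {}))
    total = len(na) + len(nb)
    return 2.0 * len(na & nb) / total if total else 0.0


def brute_aa(edges, a, b):
    adj, _ = adjacency(edges)
    total = 0.0
    for z in set(adj.get(a, {})) & set(adj.get(b, {})):
        k = len(adj[z])
        if k > 1:
            total += 1.0 / math.log(k)
    return total


def brute_ra(edges, a, b):
    adj, _ = adjacency(edges)
    return sum(1.0 / len(adj[z]) for z in set(adj.get(a, {})) & set(adj.get(b, {})))


def brute_l3(edges, a, b):
    """Sum over 3-edge paths a-u-v-b of w_au * w_uv * w_vb / sqrt(k_u k_v)."""
    adj, _ = adjacency(edges)
    total = 0.0
    for u, w_au in adj.get(a, {}).items():
        if u == b:
            continue
        for v, w_uv in adj[u].items():
            if v in (a, b, u):
                continue
            if b in adj[v]:
                total += w_au * w_uv * adj[v][b] / math.sqrt(len(adj[u]) * len(adj[v]))
    return total


def enumerate_simple_paths(edges, a, b, max_edges):
    """All simple a->b paths with at most ``max_edges`` edges, by DFS."""
    adj, _ = adjacency(edges)
    paths = []

    def walk(node, path):
        if len(path) - 1 > max_edges:
            return
        if node == b:
            paths.append(list(path))
            return
        for nbr in adj.get(node, {}):
            if nbr not in path:
                path.append(nbr)
                walk(nbr, path)
                path.pop()

    walk(a, [a])
    return paths


def brute_shortest(edges, a, b, max_edges=None):
    """(min path-weight sum, set of edge counts attaining it) over all simple paths.

    With positive weights a minimum-weight walk is a simple path, so full
    simple-path enumeration finds the true shortest path.
    """
    _, nodes = adjacency(edges)
    cap = max_edges if max_edges is not None else len(nodes) - 1
    adj, _ = adjacency(edges)
    best = None
    lengths: set[int] = set()
    for path in enumerate_simple_paths(edges, a, b, cap):
        if len(path) < 2:
            continue
        total = sum(adj[u][v] for u, v in zip(path, path[1:]))
        if best is None or total < best - 1e-12:
            best, lengths = total, {len(path) - 1}
        elif abs(total - best) <= 1e-12:
            lengths.add(len(path) - 1)
    return best, lengths


def brute_union_find_components(edges, nodes):
    """Component count via an independent union-find."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v, _ in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    return len({find(n) for n in nodes})


def random_er_graph(rng, n_max=12):
    """A random weighted Erdos-Renyi edge list on <= n_max nodes."""
    n = rng.randint(4, n_max)
    p = rng.uniform(0.2, 0.6)
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    for a, b in combinations(nodes, 2):
        if rng.random() < p:
            edges.append((a, b, round(rng.uniform(0.1, 1.0), 6)))
    return nodes, edges
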