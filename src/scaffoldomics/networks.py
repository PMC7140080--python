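"""DEG-seeded interaction networks: construction, trimming, merging, and
MCODE dense-region detection.

Each systems-biology level (protein-protein interaction, gene-TF,
gene-miRNA, gene co-expression, drug-protein) arrives as an undirected edge
table.  A first-order network is the DEG seed genes plus their direct
interactors, with all induced edges retained.  Networks are trimmed toward
a 200-600 node budget by degree and (optionally) betweenness thresholds
computed on the untrimmed network, merged with replicate accounting, and
mined for densely connected regions with the MCODE algorithm
(k-core-weighted vertices, greedy seeded expansion, haircut
post-processing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DenseRegion",
    "select_degs",
    "build_network",
    "trim_network",
    "merge_networks",
    "mcode_dense_regions",
    "LEVEL_TRIM_DEFAULTS",
    "NODE_BUDGET",
]

#: Per-level trimming thresholds (degree, betweenness) used by the study's
#: workflow; betweenness applies only to the co-expression level.
LEVEL_TRIM_DEFAULTS: dict[str, tuple[int, float | None]] = {
    "ppi": (10, None),
    "tf": (25, None),
    "mirna": (25, None),
    "coexpression": (2, 4.0),
    "drug": (0, None),
}

#: Declared node budget for trimmed networks (warning outside, not error).
NODE_BUDGET = (200, 600)


@dataclass
class DenseRegion:
    """A densely connected region found by MCODE."""

    nodes: frozenset
    score: float
    rank: int

    def __len__(self) -> int:
        return len(self.nodes)


def select_degs(de_table: pd.DataFrame, alpha: float = 0.05,
                gene_col: str = "gene", p_col: str = "adj_p",
                lfc_col: str = "logFC") -> pd.DataFrame:
    """Differentially expressed genes: adjusted p strictly below ``alpha``
    (default 0.05), carrying their log fold changes."""
    if p_col not in de_table:
        raise ValueError(f"DE table lacks column {p_col!r}")
    out = de_table.loc[de_table[p_col] < alpha, [gene_col, lfc_col, p_col]]
    return out.reset_index(drop=True)


def build_network(seeds: pd.DataFrame | dict, edge_table: pd.DataFrame,
                  level: str) -> nx.Graph:
    """First-order network: seed genes plus their direct interactors.

    Edges among any two included nodes (from this level's table) are
    retained.  Seeds with no interactions remain as singleton components.
    Node attributes: ``seed`` flag, ``logfc`` for seeds, ``type``
    (``"gene"`` for seeds, the level's interactor type otherwise), and
    ``in_largest_component``.  Graph attribute ``level`` records provenance.
    """
    if isinstance(seeds, pd.DataFrame):
        if seeds.empty:
            raise ValueError("empty seed set")
        seed_lfc = dict(zip(seeds["gene"], seeds["logFC"]))
    else:
        seed_lfc = dict(seeds)
    if not seed_lfc:
        raise ValueError("empty seed set")
    seed_set = set(seed_lfc)

    g = nx.Graph(level=level)
    g.add_nodes_from(seed_set)
    src = edge_table["source"].astype(str).to_numpy()
    dst = edge_table["target"].astype(str).to_numpy()
    touching = np.array([s in seed_set or t in seed_set for s, t in zip(src, dst)])
    nodes = seed_set | set(src[touching]) | set(dst[touching])
    for s, t in zip(src, dst):
        if s in nodes and t in nodes and s != t:
            g.add_edge(s, t, level=level)

    interactor_type = {"tf": "TF", "mirna": "miRNA", "drug": "drug"}.get(level, "gene")
    for n in g.nodes:
        is_seed = n in seed_set
        g.nodes[n]["seed"] = is_seed
        g.nodes[n]["type"] = "gene" if is_seed else interactor_type
        if is_seed:
            g.nodes[n]["logfc"] = float(seed_lfc[n])
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    largest = components[0] if components else set()
    for n in g.nodes:
        g.nodes[n]["in_largest_component"] = n in largest
    g.graph["n_components"] = len(components)
    return g


def trim_network(net: nx.Graph, degree_min: int = 0,
                 betweenness_min: float | None = None,
                 node_budget: tuple[int, int] = NODE_BUDGET,
                 conjunctive: bool = True) -> nx.Graph:
    """Trim non-seed nodes by degree and optional betweenness thresholds.

    Degree and betweenness are computed once on the untrimmed network;
    betweenness is exact shortest-path betweenness, unnormalized.  With
    ``conjunctive`` (default) a non-seed node is kept only if it meets both
    thresholds; otherwise meeting either suffices.  Seed nodes are never
    removed.  A result outside ``node_budget`` raises a warning, not an
    error.
    """
    if degree_min < 0 or (betweenness_min is not None and betweenness_min < 0):
        raise ValueError("thresholds must be >= 0")
    deg = dict(net.degree())
    btw = (nx.betweenness_centrality(net, normalized=False)
           if betweenness_min is not None else None)

    def keeps(n) -> bool:
        if net.nodes[n].get("seed", False):
            return True
        pass_deg = deg[n] >= degree_min
        if btw is None:
            return pass_deg
        pass_btw = btw[n] >= betweenness_min
        return (pass_deg and pass_btw) if conjunctive else (pass_deg or pass_btw)

    keep = [n for n in net.nodes if keeps(n)]
    if not keep:
        raise ValueError("trimming removed all nodes")
    out = net.subgraph(keep).copy()
    lo, hi = node_budget
    if not (lo <= out.number_of_nodes() <= hi):
        warnings.warn(
            f"trimmed network has {out.number_of_nodes()} nodes, outside the "
            f"[{lo}, {hi}] budget", stacklevel=2)
    return out


def merge_networks(networks: list[nx.Graph]) -> tuple[nx.Graph, dict]:
    """Union of networks by node id, with replicate accounting.

    Replicate nodes are ids appearing in more than one input; replicate
    edges are unordered node pairs (level-agnostic) appearing in more than
    one input.  Merged edges carry the list of contributing levels.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 networks to merge")
    merged = nx.Graph()
    node_seen: dict = {}
    edge_seen: dict = {}
    for g in networks:
        level = g.graph.get("level", "?")
        for n, attrs in g.nodes(data=True):
            node_seen[n] = node_seen.get(n, 0) + 1
            if n not in merged:
                merged.add_node(n, **attrs)
            elif attrs.get("seed"):
                merged.nodes[n].update({k: v for k, v in attrs.items() if k != "in_largest_component"})
        for u, v in g.edges:
            key = frozenset((u, v))
            edge_seen[key] = edge_seen.get(key, 0) + 1
            if merged.has_edge(u, v):
                merged.edges[u, v]["levels"].append(level)
            else:
                merged.add_edge(u, v, levels=[level])
    replicate_nodes = sorted(str(n) for n, c in node_seen.items() if c > 1)
    replicate_edges = sorted(tuple(sorted(map(str, k))) for k, c in edge_seen.items() if c > 1)
    report = {
        "n_replicate_nodes": len(replicate_nodes),
        "n_replicate_edges": len(replicate_edges),
        "replicate_nodes": replicate_nodes,
        "replicate_edges": replicate_edges,
    }
    return merged, report


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

def _graph_density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _vertex_weights(g: nx.Graph, degree_cutoff: int) -> dict:
    """MCODE vertex weighting: highest k-core number of the closed
    neighborhood times the density of that highest k-core."""
    weights = {}
    for v in g.nodes:
        if g.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = list(g.neighbors(v)) + [v]
        sub = g.subgraph(nbhd)
        core_num = nx.core_number(sub)
        k_max = max(core_num.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        core = sub.subgraph([n for n, k in core_num.items() if k >= k_max])
        weights[v] = k_max * _graph_density(core)
    return weights


def mcode_dense_regions(
    net: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
    fluff: bool = False,
) -> list[DenseRegion]:
    """Find densely connected regions with the MCODE algorithm (defaults as
    published: degree cutoff 2, node score cutoff 0.2, k-core 2, max depth
    100, haircut on, fluff off).

    Stages: (1) weight each vertex by the highest k-core of its closed
    neighborhood times that core's density; (2) from each top-weighted
    unvisited vertex, greedily grow a complex by including neighbors whose
    weight is within ``node_score_cutoff`` of the seed weight (depth-
    limited breadth-first, visited vertices belong to one complex only, so
    regions are disjoint); (3) drop complexes with no ``k_core``-core and,
    with ``haircut``, iteratively shave singly connected vertices.
    Complexes are ranked by score = density × size.
    """
    if net.number_of_nodes() == 0:
        return []
    weights = _vertex_weights(net, degree_cutoff)
    visited: set = set()
    complexes: list[set] = []
    for seed in sorted(net.nodes, key=lambda n: (-weights[n], str(n))):
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for u in frontier:
                for w in net.neighbors(u):
                    if w in visited or w in members:
                        continue
                    if weights[w] > threshold:
                        members.add(w)
                        visited.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        if len(members) > 1:
            complexes.append(members)

    regions = []
    for members in complexes:
        sub = net.subgraph(members).copy()
        core_num = nx.core_number(sub)
        if not core_num or max(core_num.values()) < k_core:
            continue
        if haircut:
            while True:
                shave = [n for n in sub.nodes if sub.degree(n) < 2]
                if not shave:
                    break
                sub.remove_nodes_from(shave)
        if sub.number_of_nodes() < 2:
            continue
        if fluff:
            extra = set()
            for n in list(sub.nodes):
                for w in net.neighbors(n):
                    if w not in sub and weights.get(w, 0) > node_score_cutoff:
                        extra.add(w)
            sub = net.subgraph(set(sub.nodes) | extra).copy()
        score = _graph_density(sub) * sub.number_of_nodes()
        regions.append((frozenset(sub.nodes), score))

    regions.sort(key=lambda r: (-r[1], sorted(map(str, r[0]))))
    return [DenseRegion(nodes=n, score=s, rank=i + 1) for i, (n, s) in enumerate(regions)]
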