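"""Connected closed frequent subgraph mining over patient graphs.

Because every node carries its transcript identity as well as its UP/DOWN tag,
subgraph isomorphism collapses to identity containment: a pattern occurs in a
patient graph iff all of its tagged nodes do.  And because each patient graph
contains *every* tag-consistent template edge between its nodes, the edge set
of a pattern is implied by its node set.  Mining therefore reduces to
enumerating connected subsets of the tagged-node universe (nodes = (feature,
tag) pairs, adjacency = tag-consistent template edges), with support counted by
intersecting per-node patient bitsets and anti-monotone pruning below the
minimum support.  Each connected subset is visited exactly once via ESU-style
exclusive-neighborhood extension.  A frequent pattern is closed when every
one-node connected extension strictly lowers its support; by a path argument
this is equivalent to having no connected proper supergraph of equal support.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .expression import DOWN, GENE, MIRNA, UP
from .patient_graphs import Node, PatientGraph, edge_consistent


@dataclass(frozen=True)
class Pattern:
    """A connected closed frequent subgraph with its supporting patients."""

    nodes: frozenset[Node]
    edges: frozenset[tuple[str, str]]
    support: int
    patients: frozenset[str]
    p_perm: float | None = None

    @property
    def node_ids(self) -> frozenset[tuple[str, str]]:
        return frozenset((f, tag) for f, _, tag in self.nodes)

    @property
    def n_gene_nodes(self) -> int:
        return sum(1 for _, typ, _ in self.nodes if typ == GENE)

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class CoModule:
    """Union of all mined patterns' nodes and edges."""

    nodes: frozenset[Node]
    edges: frozenset[tuple[str, str]]
    n_patterns: int

    def feature_ids(self, feature_type: str) -> list[str]:
        return sorted(f for f, typ, _ in self.nodes if typ == feature_type)


def absolute_min_support(min_support: int | float, n_patients: int) -> int:
    """Fractional supports convert by ceiling: 0.066 of 196 patients -> 13."""
    if 0 < min_support < 1:
        return math.ceil(min_support * n_patients)
    if min_support != int(min_support) or min_support < 1:
        raise ValueError("min_support must be a fraction in (0,1) or an integer >= 1")
    return int(min_support)


def support_percent(absolute: int, n_patients: int) -> float:
    """Absolute support as a percentage of the cohort (13 of 196 -> 6.63...)."""
    return 100.0 * absolute / n_patients


def contains(pattern: Pattern, graph: PatientGraph) -> bool:
    """True iff every pattern node (with its tag) and edge is in the graph."""
    return pattern.node_ids <= graph.node_ids and pattern.edges <= graph.edges


def _pattern_universe(graphs: list[PatientGraph], template: nx.Graph):
    """Tagged-node universe, adjacency, and per-node patient bitsets."""
    universe: list[Node] = sorted({n for g in graphs for n in g.nodes})
    index = {n: i for i, n in enumerate(universe)}
    bits = [0] * len(universe)
    for p, g in enumerate(graphs):
        for n in g.nodes:
            bits[index[n]] |= 1 << p
    adj: list[set[int]] = [set() for _ in universe]
    for u, v, data in template.edges(data=True):
        mirna, gene = (u, v) if template.nodes[u]["type"] == MIRNA else (v, u)
        for mt in (UP, DOWN):
            for gt in (UP, DOWN):
                if not edge_consistent(data["sign"], mt, gt):
                    continue
                a = index.get((mirna, MIRNA, mt))
                b = index.get((gene, GENE, gt))
                if a is not None and b is not None:
                    adj[a].add(b)
                    adj[b].add(a)
    return universe, adj, bits


def _pattern_edges(nodes: frozenset[Node], template: nx.Graph) -> frozenset:
    """Implied edge set: all tag-consistent template edges within the node set."""
    tags = {f: tag for f, _, tag in nodes}
    edges = set()
    for f, typ, _ in nodes:
        if typ != MIRNA:
            continue
        for nb in template.neighbors(f):
            if nb in tags and edge_consistent(
                template.edges[f, nb]["sign"], tags[f], tags[nb]
            ):
                edges.add((f, nb))
    return frozenset(edges)


def mine_closed_frequent(
    graphs: list[PatientGraph],
    template: nx.Graph,
    min_support: int | float,
    min_gene_nodes: int = 4,
    max_patterns: int | None = None,
) -> list[Pattern]:
    """All connected closed frequent patterns with >= min_gene_nodes gene nodes.

    The gene-node filter is applied after closure (filtering during the search
    would change which patterns are closed).  ``max_patterns`` optionally caps
    the result to the most frequent patterns after mining.
    """
    if not graphs:
        return []
    min_sup = absolute_min_support(min_support, len(graphs))
    if min_gene_nodes < 0:
        raise ValueError("min_gene_nodes must be >= 0")
    universe, adj, bits = _pattern_universe(graphs, template)
    n_univ = len(universe)
    frequent: dict[frozenset[int], int] = {}  # node-index set -> patient bitset

    def extend(sub: frozenset[int], sub_bits: int, ext: list[int],
               neighborhood: set[int], anchor: int) -> None:
        frequent[sub] = sub_bits
        ext = list(ext)
        while ext:
            w = ext.pop()
            new_bits = sub_bits & bits[w]
            if new_bits.bit_count() < min_sup:
                continue
            exclusive = [
                u for u in adj[w]
                if u > anchor and u not in sub and u not in neighborhood
            ]
            extend(
                sub | {w},
                new_bits,
                ext + exclusive,
                neighborhood | adj[w],
                anchor,
            )

    for v in range(n_univ):
        if bits[v].bit_count() < min_sup:
            continue
        extend(
            frozenset([v]),
            bits[v],
            [u for u in adj[v] if u > v],
            set(adj[v]) | {v},
            v,
        )

    patient_ids = [g.patient_id for g in graphs]
    patterns: list[Pattern] = []
    for sub, sub_bits in frequent.items():
        support = sub_bits.bit_count()
        closed = True
        boundary = set().union(*(adj[i] for i in sub)) - sub
        for u in boundary:
            if (sub_bits & bits[u]).bit_count() == support:
                closed = False
                break
        if not closed:
            continue
        nodes = frozenset(universe[i] for i in sub)
        if sum(1 for _, typ, _ in nodes if typ == GENE) < min_gene_nodes:
            continue
        supporting = frozenset(
            patient_ids[p] for p in range(len(graphs)) if sub_bits >> p & 1
        )
        patterns.append(
            Pattern(nodes, _pattern_edges(nodes, template), support, supporting)
        )
    patterns.sort(key=lambda pat: (-pat.support, -pat.size, sorted(pat.nodes)))
    if max_patterns is not None:
        patterns = patterns[:max_patterns]
    return patterns


def pattern_significance(
    pattern: Pattern,
    tag_table: pd.DataFrame,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation p-value for a pattern's support.

    The null permutes, independently for each feature, the assignment of its
    tags across patients, and recounts how many patients carry every pattern
    node; ``p = (1 + #{null support >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    n_patients = len(tag_table)
    features: dict[str, list[str]] = {}
    for f, _, tag in pattern.nodes:
        features.setdefault(f, []).append(tag)
    indicator = np.ones((n_perm, n_patients), dtype=bool)
    observed = np.ones(n_patients, dtype=bool)
    for f, wanted in features.items():
        col = tag_table[f].to_numpy()
        hit = np.isin(col, wanted) if len(wanted) == 1 else np.zeros(len(col), bool)
        observed &= hit
        order = np.argsort(rng.random((n_perm, n_patients)), axis=1)
        indicator &= hit[order]
    obs_support = int(observed.sum())
    null_support = indicator.sum(axis=1)
    return float((1 + int(np.sum(null_support >= obs_support))) / (n_perm + 1))


def merge_comodule(patterns: list[Pattern]) -> CoModule:
    """Union of node and edge sets over all patterns."""
    nodes: set[Node] = set()
    edges: set[tuple[str, str]] = set()
    for p in patterns:
        nodes |= p.nodes
        edges |= p.edges
    return CoModule(frozenset(nodes), frozenset(edges), len(patterns))


def occurrence_score(pattern: Pattern, graph: PatientGraph) -> float:
    """Fraction of a pattern's nodes present, with matching tag, in the graph."""
    if not pattern.nodes:
        raise ValueError("occurrence score undefined for an empty pattern")
    return len(pattern.node_ids & graph.node_ids) / len(pattern.node_ids)


def mining_summary(patterns: list[Pattern]) -> dict:
    """Pattern counts, distinct vertices, and mean patterns per vertex.

    The mean is the pattern count divided by the number of distinct vertices
    (e.g. 6,280 patterns over 433 vertices -> 14.5); it is NaN when nothing
    was mined.
    """
    vertices = {n for p in patterns for n in p.nodes}
    genes = {f for f, typ, _ in vertices if typ == GENE}
    mirnas = {f for f, typ, _ in vertices if typ == MIRNA}
    histogram = pd.DataFrame(
        {"support": [p.support for p in patterns], "size": [p.size for p in patterns]}
    )
    return {
        "n_patterns": len(patterns),
        "n_genes": len(genes),
        "n_mirnas": len(mirnas),
        "n_vertices": len(vertices),
        "mean_patterns_per_vertex": (
            len(patterns) / len(vertices) if vertices else float("nan")
        ),
        "histogram": histogram,
    }


class ClosedSubgraphMiner:
    """Estimator-style front end: ``fit(graphs, template)`` mines and merges.

    Parameters mirror :func:`mine_closed_frequent`; fitted attributes are
    ``patterns_``, ``comodule_`` and ``summary_``.
    """

    def __init__(
        self,
        min_support: int | float = 0.05,
        min_gene_nodes: int = 4,
        max_patterns: int | None = None,
    ):
        self.min_support = min_support
        self.min_gene_nodes = min_gene_nodes
        self.max_patterns = max_patterns

    def get_params(self, deep: bool = True) -> dict:
        return {
            "min_support": self.min_support,
            "min_gene_nodes": self.min_gene_nodes,
            "max_patterns": self.max_patterns,
        }

    def set_params(self, **params) -> "ClosedSubgraphMiner":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, graphs: list[PatientGraph], template: nx.Graph) -> "ClosedSubgraphMiner":
        self.patterns_ = mine_closed_frequent(
            graphs, template, self.min_support, self.min_gene_nodes, self.max_patterns
        )
        self.comodule_ = merge_comodule(self.patterns_)
        self.summary_ = mining_summary(self.patterns_)
        return self


def attach_significance(
    patterns: list[Pattern],
    tag_table: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[Pattern]:
    """Return patterns with ``p_perm`` filled in (one rng substream per pattern)."""
    out = []
    for i, p in enumerate(patterns):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        out.append(replace(p, p_perm=pattern_significance(p, tag_table, n_perm, rng)))
    return out


def write_patterns(patterns: list[Pattern], path: str | Path) -> None:
    """JSON lines: {nodes:[{id,type,tag}], edges, support, patients, p_perm}."""
    with open(path, "w") as fh:
        for p in patterns:
            fh.write(
                json.dumps(
                    {
                        "nodes": [
                            {"id": f, "type": typ, "tag": tag}
                            for f, typ, tag in sorted(p.nodes)
                        ],
                        "edges": sorted(map(list, p.edges)),
                        "support": p.support,
                        "patients": sorted(p.patients),
                        "p_perm": p.p_perm,
                    }
                )
                + "\n"
            )


def read_patterns(path: str | Path) -> list[Pattern]:
    patterns = []
    with open(path) as fh:
        for line in fh:
            doc = json.loads(line)
            patterns.append(
                Pattern(
                    frozenset((n["id"], n["type"], n["tag"]) for n in doc["nodes"]),
                    frozenset((m, g) for m, g in doc["edges"]),
                    doc["support"],
                    frozenset(doc["patients"]),
                    doc["p_perm"],
                )
            )
    return patterns


def comodule_to_networkx(comodule: CoModule) -> nx.Graph:
    g = nx.Graph(n_patterns=comodule.n_patterns)
    for f, typ, tag in comodule.nodes:
        g.add_node(f, type=typ, tag=tag)
    g.add_edges_from(comodule.edges)
    return g
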