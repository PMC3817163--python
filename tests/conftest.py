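"""Shared fixtures and the brute-force mining oracle."""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirmod import GENE, MIRNA, ExpressionMatrix, SampleTable
from mirmod.mining import Pattern, _pattern_edges
from mirmod.patient_graphs import PatientGraph


def make_template(edges: list[tuple[str, str, str]]) -> nx.Graph:
    """Template graph from (mirna, gene, sign) triples (r set from sign)."""
    g = nx.Graph()
    for mirna, gene, sign in edges:
        g.add_node(mirna, type=MIRNA)
        g.add_node(gene, type=GENE)
        r = 0.9 if sign == "+" else -0.9
        g.add_edge(mirna, gene, sign=sign, r=r, p=0.001, q=0.01)
    return g


def make_patient_graph(
    patient_id: str, tags: dict[str, str], template: nx.Graph
) -> PatientGraph:
    from mirmod import build_patient_graph

    return build_patient_graph(patient_id, pd.Series(tags), template)


def _connected(nodes: frozenset, edges: frozenset) -> bool:
    if len(nodes) <= 1:
        return True
    ids = {f for f, _, _ in nodes}
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(edges)
    return nx.is_connected(g)


def brute_force_mine(
    graphs: list[PatientGraph],
    template: nx.Graph,
    min_support: int,
    min_gene_nodes: int,
) -> dict[frozenset, int]:
    """Exhaustive oracle: all connected closed frequent tagged-node sets.

    Enumerates every subset of every patient graph's node set, keeps the
    connected ones (under the tag-consistent template edges they imply),
    counts support by containment, and filters patterns that have a proper
    connected superset of equal support.  Returns {node frozenset: support}.
    """
    candidates: set[frozenset] = set()
    for g in graphs:
        nodes = sorted(g.nodes)
        for r in range(1, len(nodes) + 1):
            for sub in combinations(nodes, r):
                candidates.add(frozenset(sub))

    supports: dict[frozenset, int] = {}
    for cand in candidates:
        if not _connected(cand, _pattern_edges(cand, template)):
            continue
        supports[cand] = sum(1 for g in graphs if cand <= g.nodes)

    result = {}
    for cand, support in supports.items():
        if support < min_support:
            continue
        if sum(1 for _, typ, _ in cand if typ == GENE) < min_gene_nodes:
            continue
        closed = not any(
            other > cand and s == support for other, s in supports.items()
        )
        if closed:
            result[cand] = support
    return result


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0, 10.0], [5.0, 5.0, 5.0, 5.0, 5.0]],
        index=["g1", "g2"],
        columns=["s1", "s2", "s3", "s4", "s5"],
    )
    return ExpressionMatrix(values, GENE)


@pytest.fixture
def tiny_samples() -> SampleTable:
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4", "s5"],
                "patient_id": ["p1", "p2", "p1", "p2", "p3"],
                "tissue": ["nontumor", "nontumor", "tumor", "tumor", "tumor"],
            }
        )
    )
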