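"""Per-patient labeled bipartite graphs.

Each patient graph keeps only that patient's UP/DOWN-tagged transcripts and
the template edges whose correlation sign agrees with the endpoint tags: a
positive edge needs equal tags, a negative edge opposite tags (an edge between
an up-regulated miRNA and an up-regulated gene is dropped when the pair is
negatively correlated in the template).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .expression import DOWN, MIRNA, NONE, UP

#: node identity in a patient graph / pattern: (feature_id, type, tag)
Node = tuple[str, str, str]


@dataclass(frozen=True)
class PatientGraph:
    patient_id: str
    nodes: frozenset[Node]
    edges: frozenset[tuple[str, str]]  # (mirna_id, gene_id)

    @property
    def node_ids(self) -> frozenset[tuple[str, str]]:
        """(feature_id, tag) pairs, the containment universe."""
        return frozenset((f, tag) for f, _, tag in self.nodes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(patient_id=self.patient_id)
        for f, typ, tag in self.nodes:
            g.add_node(f, type=typ, tag=tag)
        g.add_edges_from(self.edges)
        return g


def edge_consistent(sign: str, mirna_tag: str, gene_tag: str) -> bool:
    """Template edge sign vs endpoint tags: '+' needs equal, '-' opposite."""
    if mirna_tag not in (UP, DOWN) or gene_tag not in (UP, DOWN):
        return False
    return (sign == "+") == (mirna_tag == gene_tag)


def build_patient_graph(
    patient_id: str,
    tags: pd.Series,
    template: nx.Graph,
) -> PatientGraph:
    """Assemble one patient's graph from its tag row and the template.

    ``tags`` maps feature_id -> tag for this patient's tumor sample.  Tagged
    nodes are retained even when no consistent edge touches them; untagged
    (NONE) features never enter the graph.
    """
    tagged = {f: t for f, t in tags.items() if t in (UP, DOWN)}
    nodes = set()
    for f, tag in tagged.items():
        if f in template:
            nodes.add((f, template.nodes[f]["type"], tag))
    edges = set()
    for u, v, data in template.edges(data=True):
        mirna, gene = (u, v) if template.nodes[u]["type"] == MIRNA else (v, u)
        if mirna in tagged and gene in tagged and edge_consistent(
            data["sign"], tagged[mirna], tagged[gene]
        ):
            edges.add((mirna, gene))
    return PatientGraph(patient_id, frozenset(nodes), frozenset(edges))


def build_patient_graphs(
    tag_table: pd.DataFrame, template: nx.Graph
) -> list[PatientGraph]:
    """One graph per patient row of a patients x features tag table."""
    return [
        build_patient_graph(patient, tag_table.loc[patient], template)
        for patient in tag_table.index
    ]


def graph_size_summary(graphs: list[PatientGraph]) -> pd.DataFrame:
    """Per-patient node/edge counts (histograms follow by value_counts)."""
    return pd.DataFrame(
        {
            "patient_id": [g.patient_id for g in graphs],
            "n_nodes": [len(g.nodes) for g in graphs],
            "n_edges": [len(g.edges) for g in graphs],
        }
    ).set_index("patient_id")


def write_patient_graphs(graphs: list[PatientGraph], path: str | Path) -> None:
    """JSON-lines export: {patient_id, nodes:[{id,type,tag}], edges:[[m,g]]}."""
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(
                json.dumps(
                    {
                        "patient_id": g.patient_id,
                        "nodes": [
                            {"id": f, "type": typ, "tag": tag}
                            for f, typ, tag in sorted(g.nodes)
                        ],
                        "edges": sorted(map(list, g.edges)),
                    }
                )
                + "\n"
            )


def read_patient_graphs(path: str | Path) -> list[PatientGraph]:
    graphs = []
    with open(path) as fh:
        for line in fh:
            doc = json.loads(line)
            graphs.append(
                PatientGraph(
                    doc["patient_id"],
                    frozenset((n["id"], n["type"], n["tag"]) for n in doc["nodes"]),
                    frozenset((m, g) for m, g in doc["edges"]),
                )
            )
    return graphs
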