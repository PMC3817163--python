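"""Correlated target filtering and signed bipartite template graph construction.

Candidate miRNA->gene pairs (e.g. TargetScan-derived) are kept only when miRNA
and gene expression are significantly correlated across all samples, tumor and
adjacent non-tumor alike.  Significance is a one-tailed permutation test of the
Pearson coefficient in the direction of the observed sign, with
Benjamini-Hochberg FDR control applied separately to the target list of each
miRNA.  Surviving pairs form a signed bipartite template graph.
"""

from __future__ import annotations

import itertools
import math
import zlib
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import GENE, MIRNA, ExpressionMatrix, SampleTable

#: exhaustive enumeration is used when the permutation count is at most this
EXHAUSTIVE_BOUND = 5000


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation over jointly observed entries.

    Raises ValueError when fewer than 3 jointly observed samples remain or a
    vector is constant on the common support (the caller skips such pairs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"only {x.size} jointly observed samples (need >= 3)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on the common support")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))


def _perm_count(y: np.ndarray) -> float:
    """Number of distinct permutations of y (multiset permutation count)."""
    n = len(y)
    total = math.factorial(n)
    for c in pd.Series(y).value_counts():
        total //= math.factorial(c)
    return total


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    mode: str = "auto",
    exhaustive_bound: int = EXHAUSTIVE_BOUND,
) -> tuple[float, float]:
    """One-tailed permutation p-value for the Pearson correlation of x and y.

    The tail follows the sign of the observed coefficient; ties count toward
    the tail.  Sampled mode uses add-one smoothing,
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)`` (mirrored for negative
    r_obs); exhaustive mode enumerates all permutations of y and returns the
    exact tail fraction.  Returns (r_obs, p).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("auto", "sampled", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    r_obs = pearson_r(x, y)

    if mode == "auto":
        mode = "exhaustive" if _perm_count(y) <= exhaustive_bound else "sampled"

    # centered/standardized once; r for permuted y is a dot product
    xs = (x - x.mean()) / (x.std() * math.sqrt(len(x)))
    ys = (y - y.mean()) / (y.std() * math.sqrt(len(y)))

    if mode == "exhaustive":
        perms = np.array(list(itertools.permutations(ys)))
    else:
        rng = np.random.default_rng(rng)
        perms = np.array([rng.permutation(ys) for _ in range(n_perm)])
    r_perm = perms @ xs
    if r_obs >= 0:
        hits = int(np.sum(r_perm >= r_obs - 1e-12))
    else:
        hits = int(np.sum(r_perm <= r_obs + 1e-12))
    if mode == "exhaustive":
        p = hits / len(perms)
    else:
        p = (1 + hits) / (n_perm + 1)
    return r_obs, float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def load_candidate_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column ``mirna_id<TAB>gene_id`` candidate list."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"candidate pair file {path} needs two columns")
    return [(m, g) for m, g in zip(df.iloc[:, 0], df.iloc[:, 1])]


def _pair_rng(seed: int | None, mirna: str, gene: str) -> np.random.Generator:
    """Deterministic per-pair substream, independent of pair order."""
    key = zlib.crc32(f"{mirna}\t{gene}".encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def build_template_graph(
    pairs: list[tuple[str, str]],
    genes: ExpressionMatrix,
    mirnas: ExpressionMatrix,
    samples: SampleTable,
    q_threshold: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "auto",
) -> nx.Graph:
    """Filter candidate pairs by correlation significance into a template graph.

    Correlations use every sample (tumor and non-tumor) where both vectors are
    observed; pairs referencing unknown features, with <3 joint observations or
    constant on the common support are skipped.  BH FDR runs per miRNA; edges
    with q <= q_threshold are kept and isolated nodes are dropped.

    Nodes carry ``type`` in {gene, miRNA}; edges carry ``sign`` ('+'/'-'),
    ``r``, ``p`` and ``q``.
    """
    sample_order = [s for s in samples.sample_ids if s in set(genes.sample_ids) and s in set(mirnas.sample_ids)]
    gvals = genes.values[sample_order]
    mvals = mirnas.values[sample_order]
    gene_set = set(genes.feature_ids)
    mirna_set = set(mirnas.feature_ids)

    n_unknown = 0
    n_skipped = 0
    rows: list[tuple[str, str, float, float]] = []
    for mirna, gene in dict.fromkeys(pairs):  # dedupe, keep order
        if mirna not in mirna_set or gene not in gene_set:
            n_unknown += 1
            continue
        x = mvals.loc[mirna].to_numpy()
        y = gvals.loc[gene].to_numpy()
        try:
            r, p = permutation_pvalue(
                x, y, n_perm=n_perm, rng=_pair_rng(seed, mirna, gene), mode=mode
            )
        except ValueError:
            n_skipped += 1
            continue
        rows.append((mirna, gene, r, p))

    graph = nx.Graph(
        q_threshold=q_threshold,
        n_perm=n_perm,
        n_unknown_pairs=n_unknown,
        n_skipped_pairs=n_skipped,
    )
    if not rows:
        return graph
    df = pd.DataFrame(rows, columns=["mirna", "gene", "r", "p"])
    df["q"] = np.nan  # FDR is controlled within each miRNA's target list

    for _, idx in df.groupby("mirna", sort=False).groups.items():
        df.loc[idx, "q"] = bh_fdr(df.loc[idx, "p"])
    for row in df.itertuples():
        if row.q <= q_threshold:
            graph.add_node(row.mirna, type=MIRNA)
            graph.add_node(row.gene, type=GENE)
            graph.add_edge(
                row.mirna,
                row.gene,
                sign="+" if row.r >= 0 else "-",
                r=float(row.r),
                p=float(row.p),
                q=float(row.q),
            )
    return graph


def template_to_edgelist(graph: nx.Graph) -> pd.DataFrame:
    """Edge-list view of a template graph (one row per kept pair)."""
    rows = []
    for u, v, d in graph.edges(data=True):
        mirna, gene = (u, v) if graph.nodes[u]["type"] == MIRNA else (v, u)
        rows.append((mirna, gene, d["sign"], d["r"], d["p"], d["q"]))
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "sign", "r", "p", "q"])


def write_template_graph(graph: nx.Graph, graphml_path: str | Path, tsv_path: str | Path | None = None) -> None:
    nx.write_graphml(graph, graphml_path)
    if tsv_path is not None:
        template_to_edgelist(graph).to_csv(tsv_path, sep="\t", index=False)
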