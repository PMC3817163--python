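"""Clustering robustness, partition agreement and clinical enrichment.

Stability: the cohort is resampled B times (70% without replacement by
default), the mixture model is refitted on each subset, refit labels are
aligned to the reference clustering by maximum-agreement matching, and each
patient's score is the fraction of subsets containing it in which the aligned
label equals the reference label.  Partition agreement uses the Rand index and
its chance-adjusted form; clinical enrichment uses Fisher's exact test
(right-tailed for cluster enrichment, two-sided for cohort comparisons).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import fisher_exact

from .mixture import em_fit


def align_labels(reference: np.ndarray, other: np.ndarray, n_clusters: int) -> np.ndarray:
    """Relabel ``other`` to maximize agreement with ``reference``.

    Maximum-agreement matching on the contingency table via the assignment
    problem; for K=2 this is just choosing the orientation that agrees on more
    than half of the shared patients.
    """
    contingency = np.zeros((n_clusters, n_clusters), dtype=int)
    for r, o in zip(reference, other):
        contingency[o, r] += 1
    _, mapping = linear_sum_assignment(-contingency)
    return mapping[np.asarray(other)]


def stability_from_replicates(
    reference: pd.Series,
    replicates: list[pd.Series],
    n_clusters: int | None = None,
) -> pd.DataFrame:
    """Per-patient stability from already-fitted subset clusterings.

    Each replicate covers a subset of the reference patients; its labels are
    aligned to the reference on the shared patients.  A patient's score is the
    fraction of replicates containing it whose aligned label matches the
    reference; patients in no replicate get a missing score.
    """
    if n_clusters is None:
        n_clusters = int(reference.max()) + 1
    hits = pd.Series(0, index=reference.index, dtype=float)
    counts = pd.Series(0, index=reference.index, dtype=int)
    for rep in replicates:
        shared = rep.index
        aligned = align_labels(
            reference.loc[shared].to_numpy(), rep.to_numpy(), n_clusters
        )
        hits.loc[shared] += aligned == reference.loc[shared].to_numpy()
        counts.loc[shared] += 1
    with np.errstate(invalid="ignore"):
        s = hits / counts.replace(0, np.nan)
    return pd.DataFrame({"s": s, "n_subsets": counts})


def bootstrap_stability(
    X_gene,
    X_mirna,
    reference: pd.Series,
    fraction: float = 0.7,
    B: int = 100,
    seed: int | None = None,
    replace: bool = False,
    **em_kwargs,
) -> pd.DataFrame:
    """Refit on B random subsets and score per-patient assignment stability.

    ``reference`` is the full-cohort clustering (patient -> cluster).  Subsets
    of size ceil(fraction*N) are drawn without replacement by default; the
    mixture is refitted with the reference K on each and aligned labels are
    compared patient by patient.  Returns columns ``s`` and ``n_subsets``
    indexed by patient.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if B < 1:
        raise ValueError("B must be >= 1")
    X_gene = np.asarray(X_gene, dtype=float)
    X_mirna = None if X_mirna is None else np.asarray(X_mirna, dtype=float)
    N = X_gene.shape[0]
    K = int(reference.max()) + 1
    size = math.ceil(fraction * N)
    if size < K:
        raise ValueError(f"subset size {size} smaller than K={K}")
    ss = np.random.SeedSequence(seed)
    replicates = []
    for b, child in enumerate(ss.spawn(B)):
        rng = np.random.default_rng(child)
        idx = rng.choice(N, size=size, replace=replace)
        if not replace:
            idx = np.sort(idx)
        sub_seed = int(rng.integers(2**31 - 1))
        _, result = em_fit(
            X_gene[idx],
            None if X_mirna is None else X_mirna[idx],
            K,
            seed=sub_seed,
            patient_ids=reference.index[idx],
            **em_kwargs,
        )
        rep = result.assignments
        if replace:  # score each resampled patient once per subset
            rep = rep[~rep.index.duplicated()]
        replicates.append(rep)
    return stability_from_replicates(reference, replicates, K)


def _pair_counts(a: np.ndarray, b: np.ndarray):
    contingency = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    comb2 = lambda x: x * (x - 1) / 2.0
    nij = comb2(contingency).sum()
    ai = comb2(contingency.sum(axis=1)).sum()
    bj = comb2(contingency.sum(axis=0)).sum()
    total = comb2(len(a))
    return nij, ai, bj, total


def _check_partitions(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be 1-d and of equal length")
    return a, b


def rand_index(a, b) -> float:
    """Fraction of patient pairs on which the two partitions agree."""
    a, b = _check_partitions(a, b)
    nij, ai, bj, total = _pair_counts(a, b)
    if total == 0:
        return 1.0
    return float((total + 2 * nij - ai - bj) / total)


def adjusted_rand_index(a, b) -> float:
    """Hubert-Arabie chance-corrected Rand index."""
    a, b = _check_partitions(a, b)
    nij, ai, bj, total = _pair_counts(a, b)
    if total == 0:
        return 1.0
    expected = ai * bj / total
    maximum = (ai + bj) / 2.0
    if maximum == expected:  # both partitions trivial: identical by construction
        return 1.0
    return float((nij - expected) / (maximum - expected))


def disagreement(a, b) -> tuple[int, float]:
    """(count, percent) of patients labeled differently after best alignment."""
    a, b = _check_partitions(a, b)
    K = int(max(a.max(), b.max())) + 1
    aligned = align_labels(a, b, K)
    n_diff = int(np.sum(aligned != a))
    return n_diff, 100.0 * n_diff / len(a)


def fisher_exact_2x2(table, alternative: str = "two_sided") -> float:
    """Exact hypergeometric p for a 2x2 table.

    ``two_sided`` sums all tables with point probability at most the observed
    one; ``right_tail`` is the upper tail on the (0,0) cell.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    alt = {"two_sided": "two-sided", "right_tail": "greater"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(fisher_exact(table, alternative=alt).pvalue)


def cluster_enrichment(
    assignments: pd.Series,
    clinical: pd.DataFrame,
    alternative: str = "right_tail",
) -> pd.DataFrame:
    """Per-covariate 2x2 cluster-vs-level tables with Fisher p-values.

    ``clinical`` is long-format (patient_id, covariate, value) with ``NA``
    allowed; NA patients are excluded per covariate, covariates with a single
    observed level are skipped with a warning.  Requires a 2-cluster
    assignment.
    """
    if assignments.nunique() != 2:
        raise ValueError("enrichment tables need exactly 2 clusters")
    rows = []
    for covariate, sub in clinical.groupby("covariate"):
        sub = sub.dropna(subset=["value"])
        sub = sub[sub["value"] != "NA"]
        sub = sub[sub["patient_id"].isin(assignments.index)]
        levels = sorted(sub["value"].unique())
        if len(levels) < 2:
            warnings.warn(f"covariate {covariate!r} has <2 observed levels; skipped")
            continue
        if len(levels) > 2:
            raise ValueError(
                f"covariate {covariate!r} has {len(levels)} levels; dichotomize first"
            )
        labels = assignments.loc[sub["patient_id"]].to_numpy()
        values = sub["value"].to_numpy()
        table = np.array(
            [
                [np.sum((labels == c) & (values == lv)) for lv in levels]
                for c in (0, 1)
            ]
        )
        rows.append(
            {
                "covariate": covariate,
                "a": table[0, 0],
                "b": table[0, 1],
                "c": table[1, 0],
                "d": table[1, 1],
                "p": fisher_exact_2x2(table, alternative),
            }
        )
    return pd.DataFrame(rows)
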