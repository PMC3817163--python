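"""Synthetic paired tumor/non-tumor cohorts with planted regulatory modules.

The generator emulates the data layout the pipeline consumes: log-scale gene
and miRNA expression matrices over paired tumor and adjacent non-tumor
samples, a candidate miRNA->gene target list, a clinical covariate table, and
a ground-truth record.  Patients fall into K subgroups; each planted module
(a small miRNA set regulating a gene set) is dysregulated in exactly one
subgroup, with negative coupling by default: the module's miRNAs shift down by
``effect`` and its target genes up in tumor samples of that subgroup (with
mild per-feature jitter on the shift), so miRNA and target expression
anti-correlate across the cohort.  Everything else is Gaussian noise around a
per-feature
baseline; cells go missing uniformly at random.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .expression import GENE, MIRNA, ExpressionMatrix, SampleTable
from .mining import CoModule


@dataclass
class PlantedModule:
    mirnas: list[str]
    genes: list[str]
    subgroup: int  # the subgroup in which this module is dysregulated
    direction: int  # +1: miRNAs down / genes up (negative regulation)


@dataclass
class SyntheticTruth:
    true_labels: dict[str, int]  # patient -> subgroup
    modules: list[PlantedModule]
    planted_pairs: list[tuple[str, str]]
    effect: float
    noise_sd: float
    missing_rate: float
    seed: int | None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            doc = json.load(fh)
        doc["modules"] = [PlantedModule(**m) for m in doc["modules"]]
        doc["planted_pairs"] = [tuple(p) for p in doc["planted_pairs"]]
        return cls(**doc)


@dataclass
class SyntheticCohort:
    genes: ExpressionMatrix
    mirnas: ExpressionMatrix
    samples: SampleTable
    candidate_pairs: list[tuple[str, str]]
    clinical: pd.DataFrame
    truth: SyntheticTruth


def generate_cohort(
    n_patients: int = 100,
    n_genes: int = 60,
    n_mirnas: int = 12,
    n_subgroups: int = 2,
    n_modules: int = 2,
    module_size: int = 6,
    mirnas_per_module: int = 2,
    effect: float = 3.0,
    noise_sd: float = 1.0,
    missing_rate: float = 0.05,
    decoy_pairs: int = 50,
    activity_sd: float = 0.3,
    covariate_rates: tuple[float, ...] = (0.75, 0.25),
    positive_coupling: bool = False,
    seed: int | None = None,
) -> SyntheticCohort:
    """Generate a paired tumor/non-tumor cohort with planted modules.

    Each patient contributes one tumor and one adjacent non-tumor sample.
    Module j is dysregulated in subgroup ``j % n_subgroups``: in those tumor
    samples its miRNAs shift by -effect and its genes by +effect (signs flip
    under ``positive_coupling``), multiplied by a per-sample activity factor
    ~N(1, activity_sd).  The candidate list contains every planted pair plus
    ``decoy_pairs`` pairs of unrelated features.  A binary clinical covariate
    is drawn per patient with subgroup-specific positive rates.
    """
    if n_subgroups < 1:
        raise ValueError("n_subgroups must be >= 1")
    if n_modules * module_size > n_genes:
        raise ValueError("n_modules * module_size exceeds n_genes")
    if n_modules * mirnas_per_module > n_mirnas:
        raise ValueError("n_modules * mirnas_per_module exceeds n_mirnas")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    patients = [f"P{i:03d}" for i in range(n_patients)]
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    mirna_ids = [f"miR-{i:03d}" for i in range(n_mirnas)]
    labels = rng.permutation(np.arange(n_patients) % n_subgroups)

    sample_rows = []
    for p in patients:
        sample_rows.append((f"{p}_T", p, "tumor"))
        sample_rows.append((f"{p}_N", p, "nontumor"))
    samples = SampleTable(
        pd.DataFrame(sample_rows, columns=["sample_id", "patient_id", "tissue"])
    )
    sample_ids = [s for s, _, _ in sample_rows]
    n_samples = len(sample_ids)

    # baseline log-expression per feature, shared by tumor and non-tumor
    gene_base = rng.normal(8.0, 1.0, size=n_genes)
    mirna_base = rng.normal(6.0, 1.0, size=n_mirnas)
    G = gene_base[:, None] + rng.normal(0, noise_sd, size=(n_genes, n_samples))
    M = mirna_base[:, None] + rng.normal(0, noise_sd, size=(n_mirnas, n_samples))

    sign = -1 if positive_coupling else +1
    modules: list[PlantedModule] = []
    planted: list[tuple[str, str]] = []
    tumor_col = {p: sample_ids.index(f"{p}_T") for p in patients}
    for j in range(n_modules):
        gsel = list(range(j * module_size, (j + 1) * module_size))
        msel = list(range(j * mirnas_per_module, (j + 1) * mirnas_per_module))
        subgroup = j % n_subgroups
        modules.append(
            PlantedModule(
                [mirna_ids[i] for i in msel], [gene_ids[i] for i in gsel],
                subgroup, +1,
            )
        )
        planted.extend((mirna_ids[m], gene_ids[g]) for m in msel for g in gsel)
        if effect != 0:
            for p, lab in zip(patients, labels):
                if lab != subgroup:
                    continue
                col = tumor_col[p]
                # per-feature jitter keeps features conditionally independent
                # given the subgroup, matching the mixture model's assumption
                M[msel, col] -= sign * effect * rng.normal(1.0, activity_sd, len(msel))
                G[gsel, col] += sign * effect * rng.normal(1.0, activity_sd, len(gsel))

    decoys: list[tuple[str, str]] = []
    planted_set = set(planted)
    module_m = {m for mod in modules for m in mod.mirnas}
    module_g = {g for mod in modules for g in mod.genes}
    free_m = [m for m in mirna_ids if m not in module_m] or mirna_ids
    free_g = [g for g in gene_ids if g not in module_g] or gene_ids
    while len(decoys) < decoy_pairs:
        pair = (
            free_m[rng.integers(len(free_m))],
            free_g[rng.integers(len(free_g))],
        )
        if pair not in planted_set and pair not in decoys:
            decoys.append(pair)

    if missing_rate > 0:
        G[rng.random(G.shape) < missing_rate] = np.nan
        M[rng.random(M.shape) < missing_rate] = np.nan

    rates = np.resize(np.asarray(covariate_rates, dtype=float), n_subgroups)
    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "covariate": "biomarker_high",
            "value": np.where(
                rng.random(n_patients) < rates[labels], "yes", "no"
            ),
        }
    )

    truth = SyntheticTruth(
        true_labels={p: int(l) for p, l in zip(patients, labels)},
        modules=modules,
        planted_pairs=planted,
        effect=effect,
        noise_sd=noise_sd,
        missing_rate=missing_rate,
        seed=seed,
    )
    return SyntheticCohort(
        genes=ExpressionMatrix(
            pd.DataFrame(G, index=gene_ids, columns=sample_ids), GENE
        ),
        mirnas=ExpressionMatrix(
            pd.DataFrame(M, index=mirna_ids, columns=sample_ids), MIRNA
        ),
        samples=samples,
        candidate_pairs=planted + decoys,
        clinical=clinical,
        truth=truth,
    )


def generate_mixture_cohort(
    n_patients: int = 100,
    n_genes: int = 20,
    n_mirnas: int = 5,
    n_subgroups: int = 2,
    offset: float = 3.0,
    noise_sd: float = 1.0,
    missing_rate: float = 0.1,
    seed: int | None = None,
):
    """Direct Gaussian-mixture draw for clustering tests.

    Cluster k's mean for every feature is ``k * offset`` (an offset of
    3*noise_sd between adjacent clusters); returns (X_gene, X_mirna, labels,
    means_gene, means_mirna) with NaN missing cells.
    """
    rng = np.random.default_rng(seed)
    labels = rng.permutation(np.arange(n_patients) % n_subgroups)
    mu_g = np.arange(n_subgroups)[:, None] * offset * np.ones((1, n_genes))
    mu_m = np.arange(n_subgroups)[:, None] * offset * np.ones((1, n_mirnas))
    X_gene = mu_g[labels] + rng.normal(0, noise_sd, size=(n_patients, n_genes))
    X_mirna = mu_m[labels] + rng.normal(0, noise_sd, size=(n_patients, n_mirnas))
    if missing_rate > 0:
        X_gene[rng.random(X_gene.shape) < missing_rate] = np.nan
        X_mirna[rng.random(X_mirna.shape) < missing_rate] = np.nan
    return X_gene, X_mirna, labels, mu_g, mu_m


def label_accuracy(true_labels: np.ndarray, predicted: np.ndarray) -> float:
    """Clustering accuracy maximized over label permutations."""
    true_labels = np.asarray(true_labels)
    predicted = np.asarray(predicted)
    if true_labels.shape != predicted.shape:
        raise ValueError("label vectors differ in length")
    K = int(max(true_labels.max(), predicted.max())) + 1
    contingency = np.zeros((K, K), dtype=int)
    for t, p in zip(true_labels, predicted):
        contingency[p, t] += 1
    rows, cols = linear_sum_assignment(-contingency)
    return float(contingency[rows, cols].sum() / len(true_labels))


def truth_metrics(
    truth: SyntheticTruth,
    template_edges: list[tuple[str, str]] | None = None,
    candidate_pairs: list[tuple[str, str]] | None = None,
    comodule: CoModule | None = None,
    assignments: pd.Series | None = None,
) -> dict:
    """Recovery metrics against the planted ground truth.

    Reports, for whichever artifacts are supplied: planted-pair recall and
    precision of the template edges (plus the surviving-decoy fraction when
    the candidate list is given), co-module recall of planted module nodes,
    and clustering label accuracy after the best label permutation.  Metrics
    over empty denominators are NaN.
    """
    metrics: dict[str, float] = {}
    planted = set(map(tuple, truth.planted_pairs))
    if template_edges is not None:
        kept = set(map(tuple, template_edges))
        metrics["pair_recall"] = (
            len(kept & planted) / len(planted) if planted else float("nan")
        )
        metrics["pair_precision"] = (
            len(kept & planted) / len(kept) if kept else float("nan")
        )
        if candidate_pairs is not None:
            decoys = set(map(tuple, candidate_pairs)) - planted
            metrics["decoy_retention"] = (
                len(kept & decoys) / len(decoys) if decoys else float("nan")
            )
    if comodule is not None:
        module_features = {m for mod in truth.modules for m in mod.mirnas} | {
            g for mod in truth.modules for g in mod.genes
        }
        recovered = {f for f, _, _ in comodule.nodes}
        metrics["module_node_recall"] = (
            len(recovered & module_features) / len(module_features)
            if module_features
            else float("nan")
        )
        metrics["module_node_precision"] = (
            len(recovered & module_features) / len(recovered)
            if recovered
            else float("nan")
        )
    if assignments is not None:
        missing = set(truth.true_labels) - set(assignments.index)
        if missing:
            raise ValueError(f"assignments missing patients: {sorted(missing)[:5]}")
        true = np.array([truth.true_labels[p] for p in assignments.index])
        metrics["label_accuracy"] = label_accuracy(true, assignments.to_numpy())
    return metrics


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Emit the TSV/JSON artifact set the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.tsv",
        "mirnas": outdir / "mirnas.tsv",
        "samples": outdir / "samples.tsv",
        "pairs": outdir / "candidate_pairs.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
    }
    cohort.genes.to_tsv(paths["genes"])
    cohort.mirnas.to_tsv(paths["mirnas"])
    cohort.samples.to_tsv(paths["samples"])
    pd.DataFrame(cohort.candidate_pairs).to_csv(
        paths["pairs"], sep="\t", index=False, header=False
    )
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    cohort.truth.to_json(paths["truth"])
    return paths
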