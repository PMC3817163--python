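"""Expression matrix IO, probe collapsing, and UP/DOWN discretization.

Expression values are log-scale intensities in a features x samples table with
``NA`` marking missing cells.  Discretization compares each tumor sample of a
feature against that feature's mean over *all* samples (tumor and adjacent
non-tumor): values above mean + t*sd are tagged UP, below mean - t*sd DOWN,
anything else (including missing values and zero-variance features) is left
untagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GENE = "gene"
MIRNA = "miRNA"
UP = "UP"
DOWN = "DOWN"
NONE = "NONE"

_TISSUES = ("tumor", "nontumor")


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, features x samples, NaN = missing."""

    values: pd.DataFrame
    feature_type: str

    def __post_init__(self) -> None:
        if self.feature_type not in (GENE, MIRNA):
            raise ValueError(f"feature_type must be {GENE!r} or {MIRNA!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample columns: {dups}")
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing(self) -> pd.DataFrame:
        """Boolean mask, True where the value is undefined."""
        return self.values.isna()

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


@dataclass
class SampleTable:
    """Maps samples to patients and tissue type (tumor / adjacent non-tumor)."""

    table: pd.DataFrame  # columns: sample_id, patient_id, tissue

    def __post_init__(self) -> None:
        required = {"sample_id", "patient_id", "tissue"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {dups.tolist()}")
        bad = set(self.table["tissue"]) - set(_TISSUES)
        if bad:
            raise ValueError(f"unknown tissue values: {sorted(bad)}")
        tumor = self.table[self.table["tissue"] == "tumor"]
        if tumor["patient_id"].duplicated().any():
            dups = tumor.loc[tumor["patient_id"].duplicated(), "patient_id"]
            raise ValueError(f"multiple tumor samples for patients: {dups.tolist()}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def patient_ids(self) -> list[str]:
        """Patients with a tumor sample, in table order."""
        return list(self.table.loc[self.table["tissue"] == "tumor", "patient_id"])

    def tumor_sample_of(self) -> pd.Series:
        """patient_id -> tumor sample_id."""
        tumor = self.table[self.table["tissue"] == "tumor"]
        return pd.Series(tumor["sample_id"].values, index=tumor["patient_id"].values)


def load_expression(
    path: str | Path,
    feature_type: str,
    samples: SampleTable | None = None,
) -> ExpressionMatrix:
    """Read a features x samples TSV with ``NA`` for missing cells.

    Rejects duplicate sample columns, non-numeric cells (with coordinates) and,
    when a :class:`SampleTable` is given, columns absent from it.
    """
    with open(path) as fh:  # pandas mangles duplicate headers, so check raw
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicate sample columns in {path}: {dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if samples is not None:
        unknown = [c for c in raw.columns if c not in set(samples.sample_ids)]
        if unknown:
            raise ValueError(
                f"sample columns in {path} absent from sample table: {unknown}"
            )
    cells = raw.where(raw != "NA")
    try:
        numeric = cells.astype(float)
    except ValueError:
        numeric = cells.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & cells.notna()
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric cell {cells.iat[r, c]!r} at feature "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r} in {path}"
        ) from None
    return ExpressionMatrix(numeric, feature_type)


def collapse_probes(
    matrix: ExpressionMatrix, probe_map: dict[str, str] | pd.Series
) -> ExpressionMatrix:
    """Collapse probe-level rows to features by the per-sample median.

    ``probe_map`` maps probe id -> feature id and may be partial: unmapped
    probes are dropped.  A collapsed cell is the median over the mapped probes'
    observed values and missing only when all of them are missing.
    """
    probe_map = pd.Series(dict(probe_map)) if not isinstance(probe_map, pd.Series) else probe_map
    if len(probe_map) == 0:
        raise ValueError("empty probe map")
    mapped = matrix.values.index.intersection(probe_map.index)
    sub = matrix.values.loc[mapped]
    collapsed = sub.groupby(probe_map.loc[mapped].values).median()
    collapsed.index.name = matrix.values.index.name
    return ExpressionMatrix(collapsed, matrix.feature_type)


def feature_stats(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature mean and sample sd (ddof=1) over all samples, ignoring missing.

    Features with fewer than two observed values get sd 0 and are therefore
    never tagged downstream.
    """
    values = matrix.values
    n_obs = values.notna().sum(axis=1)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1).where(n_obs >= 2, 0.0).fillna(0.0)
    return pd.DataFrame({"mean": mean, "sd": sd, "n_obs": n_obs})


def assign_tags(
    matrix: ExpressionMatrix,
    stats: pd.DataFrame,
    samples: SampleTable,
    t: float,
) -> pd.DataFrame:
    """Tag each (tumor patient, feature) as UP, DOWN or NONE at z-threshold t.

    UP iff value > mean + t*sd, DOWN iff value < mean - t*sd; missing tumor
    values and zero-sd features are NONE (no judgment is made on missing data).
    Returns a patients x features table of tag strings.
    """
    if t <= 0:
        raise ValueError("z-threshold t must be positive")
    tumor = samples.tumor_sample_of()
    sub = matrix.values[list(tumor.values)]
    sub.columns = list(tumor.index)
    mean = stats["mean"].reindex(matrix.values.index)
    sd = stats["sd"].reindex(matrix.values.index)
    upper = mean + t * sd
    lower = mean - t * sd
    taggable = (sd > 0).values[:, None] & sub.notna().values
    up = taggable & (sub.values > upper.values[:, None])
    down = taggable & (sub.values < lower.values[:, None])
    tags = np.where(up, UP, np.where(down, DOWN, NONE))
    return pd.DataFrame(tags, index=sub.index, columns=sub.columns).T
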