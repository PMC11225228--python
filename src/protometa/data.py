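"""Tabular containers and readers for intensity matrices and sample annotation.

Feature matrices hold label-free protein/peptide intensities or metabolite
concentrations with an explicit missing-value mask (NaN); missingness is
never encoded as zero.  Metabolite matrices carry a parallel quality-status
matrix with one categorical status per cell.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_TOKENS = {"", "NA"}

FEATURE_KINDS = ("protein", "peptide", "metabolite")

QUALITY_STATUSES = ("valid", "below_limit", "above_limit", "missing")


class DataFormatError(ValueError):
    """Malformed input table (duplicate ids, ragged rows, bad cells)."""


def _check_unique(ids, what: str) -> None:
    seen, dupes = set(), []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise DataFormatError(f"duplicate {what}: {sorted(set(dupes))}")


@dataclass
class FeatureMatrix:
    """Features x samples numeric matrix with explicit missing mask.

    ``values`` is a DataFrame indexed by feature id with sample-id columns;
    NaN marks a missing measurement.  ``is_log`` records whether the values
    are on a log scale (in which case all observed entries must be finite).
    """

    values: pd.DataFrame
    is_log: bool = False
    feature_kind: str = "protein"

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        vals = self.values.to_numpy(dtype=float)
        if self.is_log and np.any(np.isinf(vals)):
            raise ValueError("log-scale matrix contains non-finite values")

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the measurement is missing."""
        return self.values.isna()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class QualityMatrix:
    """Per-cell categorical quality statuses, congruent with a FeatureMatrix."""

    statuses: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(np.unique(self.statuses.to_numpy(dtype=object))) - set(QUALITY_STATUSES)
        if bad:
            raise ValueError(f"unknown quality statuses: {sorted(bad)}")

    def congruent_with(self, m: FeatureMatrix) -> bool:
        return (
            self.statuses.shape == m.values.shape
            and list(self.statuses.index) == m.feature_ids
            and list(self.statuses.columns) == m.sample_ids
        )


@dataclass
class SampleAnnotation:
    """Per-sample subject / condition / method / matrix-type labels."""

    table: pd.DataFrame  # columns: sample_id, subject_id, condition, method, matrix_type

    REQUIRED = ("sample_id", "subject_id", "condition", "method", "matrix_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataFormatError(f"annotation missing columns: {missing}")
        _check_unique(self.table["sample_id"], "sample ids")
        self.table = self.table.reset_index(drop=True)

    def for_samples(self, sample_ids) -> "SampleAnnotation":
        """Annotation rows for the given samples, in that order."""
        idx = self.table.set_index("sample_id")
        absent = [s for s in sample_ids if s not in idx.index]
        if absent:
            raise DataFormatError(f"samples without annotation: {absent}")
        sub = idx.loc[list(sample_ids)].reset_index()
        return SampleAnnotation(sub)

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])


# ---------------------------------------------------------------------------
# readers / writers


def _parse_table(path) -> tuple[list, list, list[list[str]]]:
    """Parse a TSV into (header, row_ids, cell rows) with shape validation."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)
    if not rows:
        raise DataFormatError(f"{path}: empty file")
    header = rows[0][1:]
    _check_unique(header, "sample ids in header")
    ncol = len(rows[0])
    ids, cells = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise DataFormatError(
                f"{path}: line {lineno} has {len(row)} fields, expected {ncol}"
            )
        ids.append(row[0])
        cells.append(row[1:])
    _check_unique(ids, "feature ids")
    return header, ids, cells


def read_feature_matrix(path, feature_kind: str = "protein") -> FeatureMatrix:
    """Read a features x samples TSV; empty cells and "NA" parse as missing."""
    header, ids, cells = _parse_table(path)
    data = np.empty((len(ids), len(header)), dtype=float)
    for i, row in enumerate(cells):
        for j, cell in enumerate(row):
            if cell in MISSING_TOKENS:
                data[i, j] = np.nan
            else:
                try:
                    data[i, j] = float(cell)
                except ValueError:
                    raise DataFormatError(
                        f"{path}: non-numeric cell {cell!r} at feature "
                        f"{ids[i]!r}, sample {header[j]!r}"
                    ) from None
    values = pd.DataFrame(data, index=ids, columns=header)
    return FeatureMatrix(values=values, is_log=False, feature_kind=feature_kind)


def write_feature_matrix(m: FeatureMatrix, path) -> None:
    out = m.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_quality_matrix(path) -> QualityMatrix:
    header, ids, cells = _parse_table(path)
    statuses = pd.DataFrame(cells, index=ids, columns=header, dtype=object)
    return QualityMatrix(statuses=statuses)


def write_quality_matrix(q: QualityMatrix, path) -> None:
    out = q.statuses.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_sample_annotation(path) -> SampleAnnotation:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return SampleAnnotation(table)


def write_sample_annotation(ann: SampleAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transforms and filters


def log_transform(m: FeatureMatrix, base: float = 2.0) -> FeatureMatrix:
    """Element-wise log to ``base``; the missing mask is unchanged.

    Raw label-free intensities are strictly positive, so a non-positive
    observed value indicates an upstream encoding problem (e.g. zeros used
    for missing) and is rejected with its coordinates.
    """
    if m.is_log:
        raise ValueError("matrix is already log-scaled")
    vals = m.values.to_numpy(dtype=float)
    bad = np.argwhere(~np.isnan(vals) & (vals <= 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive value {vals[i, j]!r} at feature {m.feature_ids[i]!r}, "
            f"sample {m.sample_ids[j]!r}; cannot log-transform"
        )
    out = pd.DataFrame(
        np.log(vals) / np.log(base), index=m.values.index, columns=m.values.columns
    )
    return replace(m, values=out, is_log=True)


def filter_completeness(m: FeatureMatrix, min_fraction: float = 0.5) -> FeatureMatrix:
    """Retain features observed in strictly more than ``min_fraction`` of samples.

    With 35 samples and the default 0.5 this keeps features quantified in at
    least 18 samples (the smallest count with 18/35 > 1/2).
    """
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must be in (0, 1)")
    if m.n_features == 0 or m.n_samples == 0:
        raise ValueError("cannot filter an empty matrix")
    frac = m.values.notna().sum(axis=1) / m.n_samples
    keep = frac > min_fraction
    return replace(m, values=m.values.loc[keep])


def filter_metabolite_validity(
    m: FeatureMatrix, q: QualityMatrix, min_valid_fraction: float = 2.0 / 3.0
) -> FeatureMatrix:
    """Retain metabolites whose fraction of 'valid' statuses is >= the threshold."""
    if not q.congruent_with(m):
        raise ValueError("quality matrix shape/ids do not match the feature matrix")
    valid_frac = (q.statuses == "valid").sum(axis=1) / m.n_samples
    keep = valid_frac >= min_valid_fraction
    return replace(m, values=m.values.loc[keep])
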