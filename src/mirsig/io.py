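"""Readers, writers and in-memory containers for expression and clinical tables.

The on-disk canonical layout for expression data is features-as-rows,
samples-as-columns (the usual microarray series-matrix convention); a flag
transposes on read.  Clinical tables are one row per sample with mandatory
``sample_id``, ``pfs_months`` and ``event`` columns; any further columns are
kept as covariates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

RESPONSE_LEVELS = ("CR", "PR", "SD", "PD")


class MirsigError(Exception):
    """Base class for all errors raised by this package."""


class DataFormatError(MirsigError):
    """An input file violates the expected format."""


@dataclasses.dataclass
class ExpressionMatrix:
    """A features x samples real-valued matrix with id metadata.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are features, columns are samples.  Values may be NaN; callers
        decide how missing values are handled (the pipeline drops features
        with any missing value in the active sample set).
    scale : str
        ``"log"`` for log-intensity / log-relative values, ``"linear"`` for
        raw relative expression such as 2^-dCt.
    """

    data: pd.DataFrame
    scale: str = "log"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = sorted(set(self.data.index[self.data.index.duplicated()]))
            raise DataFormatError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = sorted(set(self.data.columns[self.data.columns.duplicated()]))
            raise DataFormatError(f"duplicate sample ids: {dups}")
        if self.scale not in ("log", "linear"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values_for(self, sample_ids, feature_ids=None) -> np.ndarray:
        """Samples x features value block, in the requested order."""
        block = self.data if feature_ids is None else self.data.loc[list(feature_ids)]
        return block[list(sample_ids)].to_numpy(dtype=float).T

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(feature_ids)].copy(), scale=self.scale)

    def drop_missing(self) -> tuple["ExpressionMatrix", list[str]]:
        """Drop features with any missing value; return (matrix, dropped ids)."""
        mask = self.data.isna().any(axis=1)
        dropped = list(self.data.index[mask])
        return ExpressionMatrix(self.data.loc[~mask].copy(), scale=self.scale), dropped


@dataclasses.dataclass
class ClinicalCohort:
    """Per-sample survival outcome, covariates and best-response category.

    ``table`` is indexed by sample id and carries at least ``pfs_months``
    (positive, months) and ``event`` (1 = progression/death observed,
    0 = censored).  ``response`` holds RECIST best-response categories
    (CR/PR/SD/PD) when available.
    """

    table: pd.DataFrame
    name: str = "cohort"

    def __post_init__(self) -> None:
        t = self.table
        for col in ("pfs_months", "event"):
            if col not in t.columns:
                raise DataFormatError(f"clinical table lacks required column {col!r}")
        if t.index.has_duplicates:
            dups = sorted(set(t.index[t.index.duplicated()]))
            raise DataFormatError(f"duplicate sample ids: {dups}")
        bad = np.flatnonzero(~(t["pfs_months"].to_numpy(dtype=float) > 0))
        if bad.size:
            raise DataFormatError(
                f"non-positive pfs_months at row(s) {[int(i) + 1 for i in bad]} "
                f"(sample {list(t.index[bad])})"
            )
        ev = t["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            bad = np.flatnonzero(~np.isin(ev, [0, 1]))
            raise DataFormatError(f"event not in {{0,1}} at row(s) {[int(i) + 1 for i in bad]}")
        if "response" in t.columns:
            vals = t["response"].dropna()
            unknown = sorted(set(vals) - set(RESPONSE_LEVELS))
            if unknown:
                raise DataFormatError(f"unknown response categories: {unknown}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def n_events(self) -> int:
        return int(self.table["event"].sum())

    @property
    def time(self) -> np.ndarray:
        return self.table["pfs_months"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    def subset(self, sample_ids, name: str | None = None) -> "ClinicalCohort":
        return ClinicalCohort(self.table.loc[list(sample_ids)].copy(), name=name or self.name)


def _read_table(path, sep=None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype={0: str})


def read_expression(path, orientation: str = "features-rows", scale: str = "log") -> ExpressionMatrix:
    """Read a TSV/CSV expression table.

    ``orientation="features-rows"`` (default): first column holds feature ids,
    remaining columns are samples.  ``"samples-rows"`` transposes after read.
    Non-numeric body cells raise with the offending row/column address.
    """
    if orientation not in ("features-rows", "samples-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_table(path)
    ids = raw.iloc[:, 0].astype(str)
    body = raw.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"non-numeric value {body.iat[r, c]!r} at row {ids.iloc[r]!r}, "
            f"column {body.columns[c]!r} in {path}"
        )
    frame = numeric.set_axis(ids.rename(None), axis=0)
    frame.columns = [str(c) for c in frame.columns]
    if orientation == "samples-rows":
        frame = frame.T
    return ExpressionMatrix(frame, scale=scale)


def write_expression(matrix: ExpressionMatrix, path, orientation: str = "features-rows") -> None:
    frame = matrix.data if orientation == "features-rows" else matrix.data.T
    label = "feature_id" if orientation == "features-rows" else "sample_id"
    frame.rename_axis(label).to_csv(path, sep="\t", float_format="%.17g")


def read_clinical(path, name: str = "cohort") -> ClinicalCohort:
    raw = _read_table(path)
    if "sample_id" not in raw.columns:
        raise DataFormatError(f"clinical table {path} lacks a sample_id column")
    table = raw.set_index(raw["sample_id"].astype(str)).drop(columns="sample_id")
    table.index.name = None
    return ClinicalCohort(table, name=name)


def write_clinical(cohort: ClinicalCohort, path) -> None:
    cohort.table.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.17g")


def read_pairing(path) -> dict[str, tuple[str, str]]:
    """Read a pairing map: columns pair_id, tumour_sample, normal_sample."""
    raw = _read_table(path)
    for col in ("pair_id", "tumour_sample", "normal_sample"):
        if col not in raw.columns:
            raise DataFormatError(f"pairing table lacks column {col!r}")
    pairs = {}
    for _, row in raw.iterrows():
        pid = str(row["pair_id"])
        if pid in pairs:
            raise DataFormatError(f"duplicate pair id {pid!r}")
        pairs[pid] = (str(row["tumour_sample"]), str(row["normal_sample"]))
    return pairs


def write_pairing(pairs: dict[str, tuple[str, str]], path) -> None:
    rows = [{"pair_id": k, "tumour_sample": t, "normal_sample": n} for k, (t, n) in pairs.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
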