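"""Tabular containers and bit-faithful readers/writers.

Two in-memory containers carry quantitative data through the pipeline:

``IntensityTable``
    A features x samples matrix (pandas DataFrame, NaN marks missing) with a
    scale tag (``raw`` / ``log2`` / ``normalized``) and, for the proteome,
    per-feature peptide counts.  Feature ids are bare protein symbols for the
    proteome and ``PROTEIN_<residue><position>`` (e.g. ``RAB12_S106``) for
    collapsed phospho-sites.

``PhosphoLongTable``
    The pre-collapse long-form phospho report: one row per
    peptide x modification x sample with the PTM position in the protein and
    its localization confidence.

All on-disk formats are UTF-8, tab-delimited (sample sheets are CSV), LF line
endings.  Missing-value tokens follow common DIA export dialects:
empty cell, ``NaN``, ``NA`` and ``Filtered``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_MISSING_TOKENS
from .errors import FormatError

SCALES = ("raw", "log2", "normalized")

#: required columns of the long-form phospho report
PHOSPHO_COLUMNS = (
    "peptide_sequence",
    "protein_id",
    "ptm_position",
    "residue",
    "localization_confidence",
    "sample_id",
    "intensity",
)

SAMPLE_SHEET_COLUMNS = ("sample_id", "group", "centre", "sex", "age", "updrs3", "moca")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class IntensityTable:
    """Features x samples intensity matrix with missing mask and scale tag."""

    values: pd.DataFrame
    scale: str = "raw"
    peptide_counts: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise FormatError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        self.values.index.name = "feature_id"
        self.values.columns.name = None
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if self.scale == "raw":
            vals = self.values.to_numpy(dtype=float)
            bad = np.asarray((vals <= 0) & ~np.isnan(vals))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise FormatError(
                    f"non-positive raw intensity at feature {idx[i]!r}, "
                    f"sample {cols[j]!r}")
        if self.peptide_counts is not None:
            pc = self.peptide_counts.reindex(idx)
            if pc.isna().any():
                missing = pc.index[pc.isna()].tolist()
                raise FormatError(f"peptide counts missing for features: {missing[:5]}")
            self.peptide_counts = pc.astype(int)

    # -- convenience views ---------------------------------------------------
    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        return not bool(self.values.isna().to_numpy().any())

    def with_values(self, values: pd.DataFrame, scale: Optional[str] = None
                    ) -> "IntensityTable":
        """New table sharing metadata, restricted to ``values``' index."""
        pc = None
        if self.peptide_counts is not None:
            pc = self.peptide_counts.reindex(values.index)
        return IntensityTable(values=values, scale=scale or self.scale,
                              peptide_counts=pc)

    def copy(self) -> "IntensityTable":
        pc = None if self.peptide_counts is None else self.peptide_counts.copy()
        return IntensityTable(self.values.copy(), self.scale, pc)


@dataclass
class PhosphoLongTable:
    """Long-form phospho-peptide report, one row per peptide x mod x sample."""

    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=list(PHOSPHO_COLUMNS)))

    def __post_init__(self) -> None:
        missing = [c for c in PHOSPHO_COLUMNS if c not in self.rows.columns]
        if missing:
            raise FormatError(f"phospho long table is missing columns: {missing}")
        self.rows = self.rows.loc[:, list(PHOSPHO_COLUMNS)].reset_index(drop=True)
        if len(self.rows):
            conf = self.rows["localization_confidence"].astype(float)
            bad = (conf < 0) | (conf > 1) | conf.isna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise FormatError(
                    f"localization confidence outside [0,1] at row {i}: "
                    f"{self.rows['localization_confidence'].iloc[i]!r}")
            pos = self.rows["ptm_position"].astype(int)
            if (pos < 1).any():
                raise FormatError("ptm_position must be 1-based (>= 1)")
            res = self.rows["residue"]
            bad_res = ~res.isin(("S", "T", "Y"))
            if bad_res.any():
                raise FormatError(
                    f"residue must be S/T/Y, got {sorted(res[bad_res].unique())}")
            self.rows = self.rows.assign(
                ptm_position=pos, localization_confidence=conf,
                intensity=self.rows["intensity"].astype(float))

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv_raw(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                       na_values=[], encoding="utf-8")


def read_proteome_pivot(path, missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
                        scale: str = "raw") -> IntensityTable:
    """Read a wide pivot table: feature-id column, optional ``n_peptides``
    column, one column per sample.  Column order is preserved."""
    raw = _read_tsv_raw(path)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: pivot table needs a feature column and samples")
    feat_col = raw.columns[0]
    ids = raw[feat_col]
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature ids: {dups}")
    raw = raw.set_index(feat_col)
    raw.index.name = "feature_id"

    counts = None
    if "n_peptides" in raw.columns:
        counts = pd.to_numeric(raw["n_peptides"], errors="coerce")
        if counts.isna().any():
            bad = counts.index[counts.isna()][0]
            raise FormatError(f"{path}: non-numeric peptide count for {bad!r}")
        counts = counts.astype(int)
        raw = raw.drop(columns=["n_peptides"])

    token_set = set(missing_tokens)
    numeric = {}
    for col in raw.columns:
        s = raw[col].where(~raw[col].isin(token_set), other=np.nan)
        conv = pd.to_numeric(s, errors="coerce")
        bad = conv.isna() & s.notna()
        if bad.any():
            fid = s.index[bad][0]
            raise FormatError(
                f"{path}: non-numeric intensity {s[fid]!r} at feature {fid!r}, "
                f"sample column {col!r}")
        numeric[col] = conv
    values = pd.DataFrame(numeric, index=raw.index)[list(raw.columns)]
    return IntensityTable(values=values, scale=scale, peptide_counts=counts)


def write_proteome_pivot(table: IntensityTable, path) -> None:
    """Write a wide pivot table; missing cells become empty fields.

    Floats are serialized with ``repr`` (shortest round-trip) so that
    write -> read is an identity, including the missing mask.
    """
    out = table.values.copy()
    out.index.name = "feature_id"
    if table.peptide_counts is not None:
        out.insert(0, "n_peptides", table.peptide_counts)
    out.to_csv(path, sep="\t", na_rep="", encoding="utf-8", lineterminator="\n")


def read_phospho_longform(path) -> PhosphoLongTable:
    raw = _read_tsv_raw(path)
    missing = [c for c in PHOSPHO_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {missing}")
    if len(raw) == 0:
        return PhosphoLongTable()
    df = raw.loc[:, list(PHOSPHO_COLUMNS)].copy()
    for col in ("localization_confidence", "intensity"):
        conv = pd.to_numeric(df[col], errors="coerce")
        bad = conv.isna() & df[col].ne("")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"{path}: non-numeric {col} at row {i}: {df[col].iloc[i]!r}")
        df[col] = conv
    df["ptm_position"] = pd.to_numeric(df["ptm_position"], errors="raise").astype(int)
    return PhosphoLongTable(rows=df)


def write_phospho_longform(table: PhosphoLongTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False, encoding="utf-8",
                      lineterminator="\n")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample_id": str}, encoding="utf-8")
    missing = [c for c in ("sample_id", "group") if c not in sheet.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet is missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet["sample_id"][sheet["sample_id"].duplicated()].tolist()
        raise FormatError(f"{path}: duplicate sample ids: {dups}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


# ---------------------------------------------------------------------------
# result writer
# ---------------------------------------------------------------------------

def write_results(results: pd.DataFrame, path,
                  sort_by: Iterable[str] = ("adj_p", "feature_id")) -> None:
    """Write a result table deterministically.

    Rows are ordered by adjusted p ascending with lexicographic feature-id
    tie-break (columns absent from the frame are skipped); floats use 6
    significant digits so reruns are byte-identical.
    """
    out = results.copy()
    keys = [k for k in sort_by if k in out.columns]
    if keys:
        out = out.sort_values(keys, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g",
               encoding="utf-8", lineterminator="\n")


def align_samples(table: IntensityTable, sheet: pd.DataFrame) -> pd.DataFrame:
    """Return the sheet rows for the table's samples, aligned **by id**.

    Raises if any table sample is absent from the sheet; never relies on
    positional order.
    """
    sheet = sheet.set_index("sample_id", drop=False)
    unknown = [s for s in table.sample_ids if s not in sheet.index]
    if unknown:
        raise FormatError(f"samples absent from sample sheet: {unknown[:5]}")
    return sheet.loc[table.sample_ids]
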