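"""Filtering, site collapse, imputation and normalization.

Stage order mirrors the emulated workflow.  Proteome: two-peptide filter ->
row-missingness filter (>=70% drops) -> KNN imputation -> log2 -> optional
quantile normalization.  Phospho: column blank filter (>70% drops, strict) ->
site collapse at localization confidence >0.75 -> row filter (>=30% drops) ->
KNN imputation -> log2 -> quantile normalization.

The KNN imputer treats *features* (rows) as neighbors: a missing cell is the
inverse-distance-weighted mean of the k nearest feature rows, with Euclidean
distance computed over mutually observed samples and rescaled by the overlap
count (scikit-learn's ``nan_euclidean``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .errors import ConfigError, ImputationError, PipelineError
from .io import IntensityTable, PhosphoLongTable

log = logging.getLogger("lrrksig")


@dataclass
class FilterReport:
    """Per-stage audit trail: what went in, what was dropped."""
    stage: str
    n_in: int
    n_out: int
    dropped_ids: List[str] = field(default_factory=list)

    def as_row(self) -> dict:
        return {"stage": self.stage, "n_in": self.n_in, "n_out": self.n_out,
                "n_dropped": self.n_in - self.n_out}


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_min_peptides(table: IntensityTable, min_peptides: int = 2
                        ) -> Tuple[IntensityTable, FilterReport]:
    """Drop features identified by fewer than ``min_peptides`` peptides."""
    if table.peptide_counts is None:
        raise ConfigError("peptide counts are required for the peptide filter")
    keep = table.peptide_counts >= min_peptides
    dropped = table.peptide_counts.index[~keep].tolist()
    out = table.with_values(table.values.loc[keep])
    if out.n_features == 0:
        log.warning("peptide filter removed every feature (min_peptides=%d)",
                    min_peptides)
    rep = FilterReport("min_peptides", table.n_features, out.n_features, dropped)
    return out, rep


def filter_missingness(table: IntensityTable, axis: str = "feature",
                       cutoff: float = 0.70
                       ) -> Tuple[IntensityTable, FilterReport]:
    """Drop rows / columns by missing fraction.

    Features are dropped when their missing fraction is **>= cutoff** and
    samples when it is **strictly > cutoff** — the two rules the source
    workflow states for rows and columns respectively.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ConfigError(f"missingness cutoff must lie in [0,1], got {cutoff}")
    mask = table.missing_mask
    if axis == "feature":
        frac = mask.mean(axis=1)
        keep = frac < cutoff
        dropped = frac.index[~keep].tolist()
        out = table.with_values(table.values.loc[keep])
        stage = f"row_missingness(>={cutoff:g})"
    elif axis == "sample":
        frac = mask.mean(axis=0)
        keep = frac <= cutoff
        dropped = frac.index[~keep].tolist()
        out = table.with_values(table.values.loc[:, keep])
        stage = f"column_blanks(>{cutoff:g})"
    else:
        raise ConfigError(f"axis must be 'feature' or 'sample', got {axis!r}")
    n_in = table.n_features if axis == "feature" else table.n_samples
    n_out = out.n_features if axis == "feature" else out.n_samples
    return out, FilterReport(stage, n_in, n_out, dropped)


# ---------------------------------------------------------------------------
# phospho-site collapse
# ---------------------------------------------------------------------------

def collapse_ptm_sites(long: PhosphoLongTable, localization_cutoff: float = 0.75,
                       aggregation: str = "max") -> IntensityTable:
    """Collapse peptide records to one row per protein phospho-site.

    Records with localization confidence **<= cutoff** are discarded; the rest
    are grouped by (protein, residue, position) and aggregated per sample
    (default: maximum across contributing peptides, which avoids
    double-counting shared peptides).  Output ids are
    ``PROTEIN_<residue><position>``.  Sites with no surviving record anywhere
    are absent; sample columns keep first-appearance order.
    """
    if aggregation not in ("max", "sum", "mean"):
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    df = long.rows
    if len(df) == 0:
        return IntensityTable(pd.DataFrame(), scale="raw")
    kept = df[df["localization_confidence"] > localization_cutoff]
    if len(kept) == 0:
        return IntensityTable(pd.DataFrame(), scale="raw")
    site_id = (kept["protein_id"].astype(str) + "_" + kept["residue"].astype(str)
               + kept["ptm_position"].astype(str))
    agg = (kept.assign(site_id=site_id)
               .groupby(["site_id", "sample_id"], sort=False)["intensity"]
               .agg(aggregation))
    wide = agg.unstack("sample_id")
    # deterministic order: sites by first appearance, samples by first appearance
    site_order = site_id.drop_duplicates().tolist()
    sample_order = kept["sample_id"].drop_duplicates().tolist()
    wide = wide.reindex(index=site_order, columns=sample_order)
    wide.index.name = "feature_id"
    return IntensityTable(values=wide, scale="raw")


# ---------------------------------------------------------------------------
# imputation and transforms
# ---------------------------------------------------------------------------

def knn_impute(table: IntensityTable, k: int = 10) -> IntensityTable:
    """Impute missing cells from the k nearest feature rows (see module doc).

    Observed values are untouched.  A row that shares no observed sample with
    any other row cannot be imputed and raises :class:`ImputationError`.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    vals = table.values.to_numpy(dtype=float)
    n = vals.shape[0]
    if n == 0 or not np.isnan(vals).any():
        return table.copy()
    obs = ~np.isnan(vals)
    if (~obs).all(axis=1).any():
        fid = table.values.index[(~obs).all(axis=1)][0]
        raise ImputationError(f"feature {fid!r} has no observed value")
    rows_with_missing = np.flatnonzero((~obs).any(axis=1))
    overlap = obs[rows_with_missing].astype(np.int64) @ obs.T.astype(np.int64)
    overlap[np.arange(len(rows_with_missing)), rows_with_missing] = 0
    isolated = np.flatnonzero(overlap.max(axis=1) == 0)
    if isolated.size:
        fid = table.values.index[rows_with_missing[isolated[0]]]
        raise ImputationError(
            f"feature {fid!r} has zero observed overlap with every other "
            f"feature; cannot impute")
    k_eff = min(k, n - 1)
    if k_eff < k:
        log.info("knn_impute: clamping k from %d to %d available neighbors", k, k_eff)
    imputer = KNNImputer(n_neighbors=k_eff, weights="distance")
    filled = imputer.fit_transform(vals)
    if filled.shape[1] != vals.shape[1]:  # sklearn drops all-NaN columns
        raise ImputationError("a sample column has no observed value")
    out = pd.DataFrame(filled, index=table.values.index,
                       columns=table.values.columns)
    # imputation must not alter observed entries
    out_arr = out.to_numpy()
    out_arr[obs] = vals[obs]
    out = pd.DataFrame(out_arr, index=out.index, columns=out.columns)
    return table.with_values(out)


def log2_transform(table: IntensityTable) -> IntensityTable:
    """Replace raw intensities by their log2; requires a complete raw table."""
    if table.scale != "raw":
        raise PipelineError(f"log2_transform expects raw scale, got {table.scale}")
    vals = table.values.to_numpy(dtype=float)
    bad = (vals <= 0) | np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise PipelineError(
            f"non-positive or missing value at feature "
            f"{table.values.index[i]!r}, sample {table.values.columns[j]!r}; "
            f"impute before log2")
    return table.with_values(pd.DataFrame(np.log2(vals), index=table.values.index,
                                          columns=table.values.columns),
                             scale="log2")


def quantile_normalize(table: IntensityTable) -> IntensityTable:
    """Force every sample column onto the mean-of-order-statistics distribution.

    Within-column ties receive the mean of the target values their positions
    span, so the map is well defined and monotone.  Afterwards all columns
    share an identical empirical distribution.
    """
    vals = table.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise PipelineError("quantile normalization requires a complete table")
    n, m = vals.shape
    if n == 0 or m <= 1:
        return table.with_values(table.values.copy(), scale="normalized")
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    target = sorted_vals.mean(axis=1)  # mean of order statistics

    out = np.empty_like(vals)
    for j in range(m):
        col_sorted = sorted_vals[:, j]
        assigned = target.copy()
        # average target over runs of tied values
        start = 0
        for i in range(1, n + 1):
            if i == n or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    assigned[start:i] = target[start:i].mean()
                start = i
        out[order[:, j], j] = assigned
    return table.with_values(pd.DataFrame(out, index=table.values.index,
                                          columns=table.values.columns),
                             scale="normalized")


# ---------------------------------------------------------------------------
# layer-level drivers
# ---------------------------------------------------------------------------

def preprocess_proteome(table: IntensityTable, min_peptides: int = 2,
                        row_cutoff: float = 0.70, knn_k: int = 10,
                        normalize: bool = True
                        ) -> Tuple[IntensityTable, List[FilterReport]]:
    """Peptide filter -> row filter -> KNN impute -> log2 (-> quantile norm)."""
    reports = []
    table, rep = filter_min_peptides(table, min_peptides)
    reports.append(rep)
    table, rep = filter_missingness(table, "feature", row_cutoff)
    reports.append(rep)
    table = knn_impute(table, knn_k)
    table = log2_transform(table)
    if normalize:
        table = quantile_normalize(table)
    return table, reports


def preprocess_phospho(long: PhosphoLongTable, localization_cutoff: float = 0.75,
                       col_cutoff: float = 0.70, row_cutoff: float = 0.30,
                       knn_k: int = 10, aggregation: str = "max"
                       ) -> Tuple[IntensityTable, List[FilterReport]]:
    """Collapse -> column blank filter -> row filter -> impute -> log2 -> QN."""
    reports = []
    table = collapse_ptm_sites(long, localization_cutoff, aggregation)
    if table.n_features == 0:
        return table, reports
    table, rep = filter_missingness(table, "sample", col_cutoff)
    reports.append(rep)
    table, rep = filter_missingness(table, "feature", row_cutoff)
    reports.append(rep)
    table = knn_impute(table, knn_k)
    table = log2_transform(table)
    table = quantile_normalize(table)
    return table, reports
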