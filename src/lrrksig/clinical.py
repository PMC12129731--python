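"""Correlation of differential features with motor severity (UPDRS-III).

Spearman's rho (average-rank, tie-corrected) with a two-sided p from the t
approximation on n-2 df; BH adjustment across the tested feature set of each
comparison; a feature passes at |rho| > 0.5 and adjusted P < 0.05 (both
strict).  The ``rho_margin`` knob lets users reproduce looser published calls
(e.g. rho = 0.49 reported as a positive correlate).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .differential import bh_adjust
from .io import IntensityTable, align_samples

log = logging.getLogger("lrrksig")


def spearman_correlate(feature_values: Sequence[float],
                       scores: Sequence[float]) -> tuple:
    """(rho, two-sided p) for one feature against severity scores."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ConfigError("paired vectors of length >= 4 required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfigError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def correlate_features(table: IntensityTable, sheet: pd.DataFrame,
                       features: Optional[Iterable[str]] = None,
                       groups: Optional[Iterable[str]] = None,
                       score_column: str = "updrs3",
                       rho_cutoff: float = 0.5, adjp_cutoff: float = 0.05,
                       rho_margin: float = 0.0) -> pd.DataFrame:
    """Correlate each feature with the severity score over selected samples.

    ``groups`` restricts to the comparison's patient + control groups (None =
    all samples with a score).  Constant features are skipped with a log
    entry.  Returns feature_id, rho, p, adj_p, passes, direction.
    """
    aligned = align_samples(table, sheet)
    sel = aligned[score_column].notna()
    if groups is not None:
        sel &= aligned["group"].isin(set(groups))
    sample_ids = aligned.index[sel].tolist()
    if len(sample_ids) < 4:
        raise ConfigError(f"only {len(sample_ids)} samples with scores; need >= 4")
    scores = aligned.loc[sample_ids, score_column].to_numpy(dtype=float)

    feats = list(features) if features is not None else table.feature_ids
    unknown = [f for f in feats if f not in table.values.index]
    if unknown:
        raise ConfigError(f"features absent from table: {unknown[:5]}")

    rows = []
    for fid in feats:
        vals = table.values.loc[fid, sample_ids].to_numpy(dtype=float)
        if np.ptp(vals[~np.isnan(vals)]) == 0 or np.isnan(vals).any():
            log.info("skipping %s: constant or incomplete over the score cohort",
                     fid)
            continue
        rho, p = spearman_correlate(vals, scores)
        rows.append({"feature_id": fid, "rho": rho, "p": p})
    if not rows:
        return pd.DataFrame(columns=["feature_id", "rho", "p", "adj_p",
                                     "passes", "direction"])
    res = pd.DataFrame(rows)
    res["adj_p"] = bh_adjust(res["p"].to_numpy())
    return correlation_filter(res, rho_cutoff, adjp_cutoff, rho_margin)


def correlation_filter(results: pd.DataFrame, rho_cutoff: float = 0.5,
                       adjp_cutoff: float = 0.05, rho_margin: float = 0.0
                       ) -> pd.DataFrame:
    """Set pass flags (|rho| > cutoff - margin AND adj_p < cutoff, strict)."""
    res = results.copy()
    res["passes"] = (res["rho"].abs() > (rho_cutoff - rho_margin)) & \
                    (res["adj_p"] < adjp_cutoff)
    res["direction"] = np.where(res["rho"] > 0, "positive", "inverse")
    return res
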