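"""Moderated differential testing, BH-FDR, significance calls, ANOVA screen.

The per-feature two-group test is the empirical-Bayes moderated t: the
feature's residual variance ``s_g^2`` (pooled across the two groups,
``d_g = n - 2`` df) is shrunk toward a prior ``s_0^2`` estimated from all
features, giving

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_mod  = log2FC / (s~_g * sqrt(1/n_a + 1/n_b)),   df = d0 + d_g.

The hyperparameters (d0, s0^2) are estimated by moment-matching the marginal
scaled-F distribution of the sample variances on the log scale (digamma /
trigamma inversion), the standard formulation.  ``d0 = 0`` reduces to the
ordinary pooled-variance t; ``d0 = inf`` pools completely.

Significance follows the strict rule |log2FC| > 0.6 and BH-adjusted P < 0.05,
applied within each contrast separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConfigError, DesignError
from .io import IntensityTable, align_samples

log = logging.getLogger("lrrksig")


@dataclass
class Contrast:
    """A two-sided group comparison; each side pools one or more group labels."""
    name: str
    group_a: Set[str]
    group_b: Set[str]

    def __post_init__(self) -> None:
        self.group_a, self.group_b = set(self.group_a), set(self.group_b)
        if not self.group_a or not self.group_b:
            raise ConfigError(f"contrast {self.name!r}: empty side")
        if self.group_a & self.group_b:
            raise ConfigError(f"contrast {self.name!r}: sides overlap")


# ---------------------------------------------------------------------------
# empirical-Bayes variance squeezing
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple:
    """Moment estimates of (prior df d0, prior variance s0^2).

    Matches the marginal distribution of log s_g^2 under the scaled-F model:
    with e = log(s^2) - digamma(df/2) + log(df/2), E[e] = log(s0^2) +
    digamma(d0/2) - log(d0/2) and Var[e] = trigamma(df/2) + trigamma(d0/2).
    If the trigamma equation has no positive solution, d0 = inf (full pooling).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    e = np.log(pos) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        # no excess dispersion beyond sampling noise: fully pooled variance
        # (arithmetic mean of the sample variances)
        log.info("prior-df estimate unbounded; using fully pooled variance")
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def squeeze_var(s2: np.ndarray, df: float, prior_df: Optional[float] = None,
                prior_s2: Optional[float] = None) -> tuple:
    """Posterior variances s~^2 and the (d0, s0^2) used."""
    if prior_df is None:
        d0, s0_sq = estimate_prior(s2, df)
    else:
        d0 = float(prior_df)
        s0_sq = prior_s2 if prior_s2 is not None else (
            estimate_prior(s2, df)[1] if d0 > 0 else 0.0)
    if np.isinf(d0):
        post = np.full_like(np.asarray(s2, dtype=float), s0_sq)
    elif d0 == 0:
        post = np.asarray(s2, dtype=float)
    else:
        post = (d0 * s0_sq + df * np.asarray(s2, dtype=float)) / (d0 + df)
    return post, d0, s0_sq


# ---------------------------------------------------------------------------
# moderated t-test
# ---------------------------------------------------------------------------

def moderated_t_test(table: IntensityTable, sheet: pd.DataFrame,
                     contrast: Contrast, prior_df: Optional[float] = None,
                     log2fc_cutoff: float = 0.6, adjp_cutoff: float = 0.05,
                     adjp_inclusive: bool = False) -> pd.DataFrame:
    """Per-feature moderated t-test of ``group_a`` minus ``group_b``.

    Pooled contrasts (several labels per side) are fit by relabeling each side
    to a single pseudo-group, i.e. a two-group one-way design with
    ``d_g = n_a + n_b - 2`` residual df.  ``prior_df`` overrides the estimated
    d0 (0 = ordinary t, inf = fully pooled).
    """
    if table.scale == "raw":
        raise DesignError("moderated t expects log2 or normalized data")
    if not table.is_complete():
        raise DesignError("moderated t expects a complete (imputed) table")
    aligned = align_samples(table, sheet)
    groups = aligned["group"]
    in_a = groups.isin(contrast.group_a).to_numpy()
    in_b = groups.isin(contrast.group_b).to_numpy()
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    if n_a < 2 or n_b < 2:
        raise DesignError(
            f"contrast {contrast.name!r}: needs >= 2 samples per side "
            f"(got {n_a} vs {n_b})")
    df_resid = n_a + n_b - 2
    if df_resid < 1:
        raise DesignError(f"contrast {contrast.name!r}: zero residual df")

    vals = table.values.to_numpy(dtype=float)
    a, b = vals[:, in_a], vals[:, in_b]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + \
         ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    post_s2, d0, s0_sq = squeeze_var(s2, df_resid, prior_df=prior_df)
    log2fc = mean_a - mean_b
    se = np.sqrt(post_s2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, 0.0)
    t_mod = np.where((se == 0) & (log2fc == 0), 0.0, t_mod)
    # total df is capped at the pooled df across all features: even with an
    # unbounded prior the information cannot exceed what the data contain
    df_total = min(d0 + df_resid, vals.shape[0] * df_resid)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)

    res = pd.DataFrame({
        "feature_id": table.feature_ids,
        "log2fc": log2fc,
        "t_mod": t_mod,
        "p": p,
        "adj_p": bh_adjust(p),
    })
    res.attrs.update({"contrast": contrast.name, "n_a": n_a, "n_b": n_b,
                      "prior_df": d0, "prior_s2": s0_sq, "df_resid": df_resid})
    return classify_hits(res, log2fc_cutoff, adjp_cutoff, adjp_inclusive)


# ---------------------------------------------------------------------------
# BH adjustment and hit classification
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    adj_i = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def classify_hits(results: pd.DataFrame, log2fc_cutoff: float = 0.6,
                  adjp_cutoff: float = 0.05, adjp_inclusive: bool = False
                  ) -> pd.DataFrame:
    """Set significance flags and up/down directions (strict inequalities)."""
    res = results.copy()
    p_ok = (res["adj_p"] <= adjp_cutoff) if adjp_inclusive else \
           (res["adj_p"] < adjp_cutoff)
    res["significant"] = (res["log2fc"].abs() > log2fc_cutoff) & p_ok
    res["direction"] = np.where(res["log2fc"] > 0, "up", "down")
    res.attrs.update(results.attrs)
    res.attrs["n_up"] = int((res["significant"] & (res["direction"] == "up")).sum())
    res.attrs["n_down"] = int((res["significant"] & (res["direction"] == "down")).sum())
    return res


# ---------------------------------------------------------------------------
# ANOVA screen
# ---------------------------------------------------------------------------

def anova_screen(table: IntensityTable, sheet: pd.DataFrame,
                 groups: Iterable[str]) -> pd.DataFrame:
    """Per-feature one-way fixed-effects ANOVA across the named groups.

    Features constant across all samples get F = 0, p = 1 by convention.
    Returns feature_id, F, p and a BH-adjusted column.
    """
    groups = list(dict.fromkeys(groups))
    if len(groups) < 2:
        raise DesignError("ANOVA needs at least two groups")
    aligned = align_samples(table, sheet)
    masks = []
    for g in groups:
        m = (aligned["group"] == g).to_numpy()
        if m.sum() < 2:
            raise DesignError(f"group {g!r} has < 2 samples")
        masks.append(m)
    vals = table.values.to_numpy(dtype=float)
    sel = np.logical_or.reduce(masks)
    x = vals[:, sel]
    n_tot = x.shape[1]
    grand = x.mean(axis=1)

    ss_between = np.zeros(vals.shape[0])
    ss_within = np.zeros(vals.shape[0])
    for m in masks:
        grp = vals[:, m]
        gm = grp.mean(axis=1)
        ss_between += m.sum() * (gm - grand) ** 2
        ss_within += ((grp - gm[:, None]) ** 2).sum(axis=1)
    df_b = len(groups) - 1
    df_w = n_tot - len(groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    degenerate = ss_within <= 1e-300
    F = np.where(degenerate & (ss_between <= 1e-300), 0.0, F)
    F = np.where(degenerate & (ss_between > 1e-300), np.inf, F)
    p = stats.f.sf(F, df_b, df_w)
    p = np.where(F == 0.0, 1.0, p)
    p = np.where(np.isinf(F), 0.0, p)

    out = pd.DataFrame({"feature_id": table.feature_ids, "F": F, "p": p,
                        "adj_p": bh_adjust(p)})
    out.attrs["groups"] = groups
    return out
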