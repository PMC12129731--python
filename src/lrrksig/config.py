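"""Pipeline configuration.

All thresholds used by the analysis live here with the defaults applied in the
study this pipeline reproduces: a two-peptide minimum per protein, a >=70% row
missingness cutoff for the proteome and >=30% for collapsed phospho-sites, a
>70% column-blank cutoff (strict, to satisfy the KNN imputer's <80% blank
requirement), a phospho-site localization-confidence cutoff of >0.75, and the
significance rule |log2FC| > 0.6 with BH-adjusted P < 0.05.  Spearman
correlations with UPDRS-III motor scores are called at |rho| > 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .errors import ConfigError

log = logging.getLogger("lrrksig")

#: Missing-value tokens accepted in tab-delimited exports (common DIA dialects).
DEFAULT_MISSING_TOKENS = ("", "NaN", "NA", "Filtered")


@dataclass
class MCTSConfig:
    """Settings for the Monte-Carlo tree search over feature subsets.

    ``depth`` bounds the lookahead (five, to manage combinatorial growth);
    ``trees_factor`` scales the per-round simulation budget as
    ``trees_factor * n_candidates``; subsets scoring above ``accept_threshold``
    balanced accuracy are collected for frequency-based refinement.
    """

    depth: int = 5
    trees_factor: int = 10
    accept_threshold: float = 0.90
    improvement_epsilon: float = 1e-3
    ucb_c: float = math.sqrt(2.0)
    seed: int = 0
    #: size of the top-frequency initial set used for refinement (None -> depth)
    refine_init_size: Optional[int] = None

    def validate(self) -> None:
        if self.depth < 1:
            raise ConfigError("MCTS depth must be >= 1")
        if self.trees_factor < 1:
            raise ConfigError("MCTS trees_factor must be >= 1")
        if not 0.0 < self.accept_threshold < 1.0:
            raise ConfigError("MCTS accept_threshold must lie in (0, 1)")
        if self.ucb_c < 0:
            raise ConfigError("MCTS ucb_c must be non-negative")


@dataclass
class PipelineConfig:
    """Thresholds and knobs for every pipeline stage (see module docstring)."""

    min_peptides: int = 2
    row_missing_cutoff_proteome: float = 0.70
    row_missing_cutoff_phospho: float = 0.30
    col_blank_cutoff: float = 0.70
    localization_cutoff: float = 0.75
    knn_k: int = 10
    log2fc_cutoff: float = 0.6
    adjp_cutoff: float = 0.05
    #: treat adj_p == adjp_cutoff as significant (off: strict inequality)
    adjp_inclusive: bool = False
    anova_p_cutoff: float = 0.05
    #: screen ML candidates on BH-adjusted rather than raw ANOVA p
    anova_use_adjusted: bool = False
    rho_cutoff: float = 0.5
    #: subtracted from rho_cutoff to reproduce looser published calls
    rho_inclusive_margin: float = 0.0
    #: quantile-normalize the proteome after log2 (the phospho layer always is)
    normalize_proteome: bool = True
    #: per-(site, sample) aggregation across contributing peptides
    site_aggregation: str = "max"
    n_folds: int = 5
    smote_k: int = 5
    missing_tokens: tuple = DEFAULT_MISSING_TOKENS
    seed: int = 0
    mcts: MCTSConfig = field(default_factory=MCTSConfig)

    def validate(self) -> None:
        for name in ("row_missing_cutoff_proteome", "row_missing_cutoff_phospho",
                     "col_blank_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.localization_cutoff <= 1.0:
            raise ConfigError("localization_cutoff must lie in [0, 1]")
        if self.min_peptides < 1:
            raise ConfigError("min_peptides must be >= 1")
        if self.knn_k < 1:
            raise ConfigError("knn_k must be >= 1")
        if self.log2fc_cutoff <= 0 or self.adjp_cutoff <= 0:
            raise ConfigError("significance cutoffs must be positive")
        if self.site_aggregation not in ("max", "sum", "mean"):
            raise ConfigError(
                f"site_aggregation must be max/sum/mean, got {self.site_aggregation}")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        self.mcts.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["missing_tokens"] = list(self.missing_tokens)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        mcts = d.pop("mcts", {})
        if "missing_tokens" in d:
            d["missing_tokens"] = tuple(d["missing_tokens"])
        cfg = cls(**d, mcts=MCTSConfig(**mcts) if isinstance(mcts, dict) else mcts)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
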