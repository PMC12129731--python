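"""End-to-end orchestration: simulate -> preprocess -> differential -> ANOVA
screen -> signature search -> evaluation -> clinical correlation.

Every run writes the intermediate tables, result TSVs and a JSON run manifest
(config snapshot, per-stage row counts, seeds, version, wall-clock) to the
output directory.  Identical (config, seed) reproduces identical outputs,
manifests differing only in the timing fields.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .clinical import correlate_features
from .config import PipelineConfig
from .cohort import (CohortBundle, generate_bundle)
from .differential import Contrast, anova_screen, moderated_t_test
from .errors import PipelineError
from .io import (IntensityTable, read_phospho_longform, read_proteome_pivot,
                 read_sample_sheet, write_phospho_longform,
                 write_proteome_pivot, write_results, write_sample_sheet)
from .preprocess import preprocess_phospho, preprocess_proteome
from .signature import find_signature

log = logging.getLogger("lrrksig")

#: the study's comparisons: each group vs controls, within-mutation, pooled
DEFAULT_CONTRASTS = [
    Contrast("G2019S_L2PD_vs_CTRL", {"G2019S_L2PD"}, {"CTRL"}),
    Contrast("G2019S_L2NMC_vs_CTRL", {"G2019S_L2NMC"}, {"CTRL"}),
    Contrast("G2019S_carriers_vs_CTRL", {"G2019S_L2PD", "G2019S_L2NMC"}, {"CTRL"}),
    Contrast("G2019S_L2PD_vs_L2NMC", {"G2019S_L2PD"}, {"G2019S_L2NMC"}),
    Contrast("R1441G_L2PD_vs_CTRL", {"R1441G_L2PD"}, {"CTRL"}),
    Contrast("iPD_vs_CTRL", {"iPD"}, {"CTRL"}),
]

PROFILES = {
    "small": {"n_proteins": 800, "n_sites": 1500},
    "paper-scale": {"n_proteins": 3815, "n_sites": 10288},
}


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    stages: List[dict] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, seconds: float) -> None:
        self.stages.append({"stage": stage, "rows_in": int(n_in),
                            "rows_out": int(n_out),
                            "wall_clock_s": round(seconds, 3)})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "seed": self.seed,
                       "version": self.version, "stages": self.stages},
                      fh, indent=2)


def run_pipeline(config: Optional[PipelineConfig] = None,
                 outdir: str = "results", inputs: str = "simulate",
                 profile: str = "small", seed: Optional[int] = None,
                 contrasts: Optional[List[Contrast]] = None,
                 signature_groups=("G2019S_L2PD", "G2019S_L2NMC", "CTRL"),
                 max_signature_candidates: int = 15) -> RunManifest:
    """Run the full analysis and write all outputs under ``outdir``.

    ``inputs`` is either ``"simulate"`` or a directory containing
    ``proteome.tsv``, ``phospho_long.tsv`` and ``samples.csv``.
    """
    cfg = config or PipelineConfig()
    if seed is not None:
        cfg.seed = int(seed)
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.to_dict(), seed=cfg.seed)
    contrasts = contrasts if contrasts is not None else DEFAULT_CONTRASTS

    try:
        # ------------------------------------------------------------------
        t0 = time.perf_counter()
        if inputs == "simulate":
            prof = PROFILES.get(profile)
            if prof is None:
                raise PipelineError(f"unknown profile {profile!r}")
            bundle = generate_bundle(seed=cfg.seed, **prof)
            sheet, proteome, phospho_long = (bundle.sheet, bundle.proteome,
                                             bundle.phospho_long)
            write_sample_sheet(sheet, out / "samples.csv")
            write_proteome_pivot(proteome, out / "proteome.tsv")
            write_phospho_longform(phospho_long, out / "phospho_long.tsv")
            bundle.truth.to_json(out / "truth.json")
        else:
            src = Path(inputs)
            sheet = read_sample_sheet(src / "samples.csv")
            proteome = read_proteome_pivot(src / "proteome.tsv")
            phospho_long = read_phospho_longform(src / "phospho_long.tsv")
        manifest.record("inputs", 0, proteome.n_features + len(phospho_long.rows),
                        time.perf_counter() - t0)

        # ------------------------------------------------------------------
        t0 = time.perf_counter()
        prot_norm, prot_reports = preprocess_proteome(
            proteome, cfg.min_peptides, cfg.row_missing_cutoff_proteome,
            cfg.knn_k, cfg.normalize_proteome)
        phos_norm, phos_reports = preprocess_phospho(
            phospho_long, cfg.localization_cutoff, cfg.col_blank_cutoff,
            cfg.row_missing_cutoff_phospho, cfg.knn_k, cfg.site_aggregation)
        audit = pd.DataFrame([r.as_row() for r in prot_reports + phos_reports])
        audit.insert(0, "layer", ["proteome"] * len(prot_reports)
                     + ["phospho"] * len(phos_reports))
        audit.to_csv(out / "filter_audit.tsv", sep="\t", index=False,
                     lineterminator="\n")
        manifest.record("preprocess", proteome.n_features + len(phospho_long.rows),
                        prot_norm.n_features + phos_norm.n_features,
                        time.perf_counter() - t0)

        # ------------------------------------------------------------------
        t0 = time.perf_counter()
        diff_hits: Dict[str, pd.DataFrame] = {}
        present = set(sheet["group"].unique())
        for layer_name, layer in (("proteome", prot_norm), ("phospho", phos_norm)):
            for contrast in contrasts:
                if not (contrast.group_a <= present and contrast.group_b <= present):
                    continue
                res = moderated_t_test(layer, sheet, contrast,
                                       log2fc_cutoff=cfg.log2fc_cutoff,
                                       adjp_cutoff=cfg.adjp_cutoff,
                                       adjp_inclusive=cfg.adjp_inclusive)
                key = f"{layer_name}_{contrast.name}"
                diff_hits[key] = res
                write_results(res, out / f"diff_{key}.tsv")
        manifest.record("differential", prot_norm.n_features + phos_norm.n_features,
                        sum(int(r["significant"].sum()) for r in diff_hits.values()),
                        time.perf_counter() - t0)

        # ------------------------------------------------------------------
        t0 = time.perf_counter()
        sig_groups = [g for g in signature_groups if g in present]
        sub_sheet = sheet[sheet["group"].isin(sig_groups)]
        X_parts = []
        for prefix, layer in (("prot:", prot_norm), ("phos:", phos_norm)):
            sub = layer.values.loc[:, layer.values.columns.isin(
                sub_sheet["sample_id"])]
            sub = sub.rename(index=lambda f: prefix + f)
            X_parts.append(sub)
        X = pd.concat(X_parts).T  # samples x features, namespaced ids
        y = sub_sheet.set_index("sample_id").loc[X.index, "group"].to_numpy()
        screen = anova_screen(
            IntensityTable(pd.concat(X_parts), scale="normalized"),
            sheet, sig_groups)
        write_results(screen, out / "anova_screen.tsv")
        manifest.record("anova_screen", X.shape[1],
                        int((screen["p"] < cfg.anova_p_cutoff).sum()),
                        time.perf_counter() - t0)

        t0 = time.perf_counter()
        cfg.mcts.seed = cfg.seed
        sig = find_signature(X, y, cfg=cfg.mcts, n_folds=cfg.n_folds,
                             anova_p_cutoff=cfg.anova_p_cutoff,
                             smote_k=cfg.smote_k,
                             max_candidates=max_signature_candidates)
        sig_table = pd.DataFrame({"feature_id": sig.features})
        sig_table["balanced_accuracy"] = sig.balanced_accuracy
        write_results(sig_table, out / "signature.tsv", sort_by=("feature_id",))
        pd.DataFrame(sig.search_trace,
                     columns=["iteration", "action", "reward"]).to_csv(
            out / "signature_trace.tsv", sep="\t", index=False,
            lineterminator="\n")
        if sig.pca_coordinates is not None:
            sig.pca_coordinates.to_csv(out / "signature_pca.tsv", sep="\t",
                                       index=False, float_format="%.6g",
                                       lineterminator="\n")
        auc_rows = pd.DataFrame(sorted(sig.per_class_auc.items()),
                                columns=["class", "auc_ovr"])
        auc_rows.to_csv(out / "signature_auc.tsv", sep="\t", index=False,
                        float_format="%.6g", lineterminator="\n")
        manifest.record("signature", X.shape[1], len(sig.features),
                        time.perf_counter() - t0)

        # ------------------------------------------------------------------
        t0 = time.perf_counter()
        diff_features = {"prot": set(), "phos": set()}
        for key, res in diff_hits.items():
            layer = "prot" if key.startswith("proteome") else "phos"
            diff_features[layer] |= set(res.loc[res["significant"], "feature_id"])
        corr_inputs = []
        for prefix, layer in (("prot", prot_norm), ("phos", phos_norm)):
            hit = [f for f in layer.feature_ids if f in diff_features[prefix]]
            if hit:
                corr_inputs.append(layer.values.loc[hit])
        n_corr = 0
        if corr_inputs:
            corr_table = IntensityTable(pd.concat(corr_inputs),
                                        scale="normalized")
            corr = correlate_features(corr_table, sheet,
                                      rho_cutoff=cfg.rho_cutoff,
                                      adjp_cutoff=cfg.adjp_cutoff,
                                      rho_margin=cfg.rho_inclusive_margin)
            write_results(corr, out / "clinical_correlation.tsv")
            n_corr = int(corr["passes"].sum()) if len(corr) else 0
        manifest.record("clinical_correlation",
                        sum(len(v) for v in diff_features.values()), n_corr,
                        time.perf_counter() - t0)

        manifest.write(out / "manifest.json")
        return manifest
    except PipelineError:
        # remove partial outputs so a failed run leaves no half-written state
        for f in out.glob("*.tsv"):
            f.unlink()
        (out / "manifest.json").unlink(missing_ok=True)
        raise
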