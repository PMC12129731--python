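"""Moderated t, BH-FDR, significance rule and ANOVA screen."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import lrrksig as L
from lrrksig.differential import estimate_prior
from lrrksig.errors import ConfigError, DesignError


def _normal_table(seed, n_feat=500, n_a=20, n_b=20, shift=None):
    rng = np.random.default_rng(seed)
    vals = rng.normal(20.0, 1.0, (n_feat, n_a + n_b))
    if shift is not None:
        vals[0, :n_a] += shift
    df = pd.DataFrame(vals, index=[f"F{i}" for i in range(n_feat)],
                      columns=[f"s{i}" for i in range(n_a + n_b)])
    sheet = pd.DataFrame({"sample_id": df.columns,
                          "group": ["A"] * n_a + ["B"] * n_b})
    return L.IntensityTable(df, scale="log2"), sheet


CONTRAST = L.Contrast("A_vs_B", {"A"}, {"B"})


class TestModeratedT:
    def test_prior_df_zero_reduces_to_ordinary_t(self):
        table, sheet = _normal_table(0)
        res = L.moderated_t_test(table, sheet, CONTRAST, prior_df=0)
        a = table.values.iloc[:, :20].to_numpy()
        b = table.values.iloc[:, 20:].to_numpy()
        t_ref, p_ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_mod"].to_numpy(), t_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p"].to_numpy(), p_ref, rtol=1e-10)

    def test_identical_group_means_give_zero_t(self):
        vals = pd.DataFrame(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], index=["F0"],
            columns=[f"s{i}" for i in range(6)])
        sheet = pd.DataFrame({"sample_id": vals.columns,
                              "group": ["A", "A", "A", "B", "B", "B"]})
        res = L.moderated_t_test(L.IntensityTable(vals, scale="log2"),
                                 sheet, CONTRAST)
        assert res["t_mod"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_null_pvalues_uniform_by_ks(self):
        table, sheet = _normal_table(1, n_feat=2000)
        res = L.moderated_t_test(table, sheet, CONTRAST)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_moderated_t_bracketing(self):
        """t_mod lies between the ordinary t (per-feature variance) and the
        fully pooled t (prior variance), sign-consistent per feature."""
        table, sheet = _normal_table(2, n_feat=300)
        res = L.moderated_t_test(table, sheet, CONTRAST)
        res0 = L.moderated_t_test(table, sheet, CONTRAST, prior_df=0)
        res_inf = L.moderated_t_test(table, sheet, CONTRAST, prior_df=np.inf)
        lo = np.minimum(res0["t_mod"], res_inf["t_mod"])
        hi = np.maximum(res0["t_mod"], res_inf["t_mod"])
        assert ((res["t_mod"] >= lo - 1e-12) & (res["t_mod"] <= hi + 1e-12)).all()

    def test_small_contrast_side_rejected(self):
        table, sheet = _normal_table(3, n_feat=10, n_a=1, n_b=5)
        with pytest.raises(DesignError, match=">= 2 samples"):
            L.moderated_t_test(table, sheet, CONTRAST)

    def test_posterior_variance_between_prior_and_sample(self):
        rng = np.random.default_rng(4)
        s2 = rng.chisquare(5, size=400) / 5
        post, d0, s0_sq = L.squeeze_var(s2, df=10)
        lo = np.minimum(s2, s0_sq)
        hi = np.maximum(s2, s0_sq)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()
        assert d0 > 0

    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: the R limma package produces the same moderated
        t statistics, p-values and prior df on a shared matrix."""
        table, sheet = _normal_table(5, n_feat=200, n_a=8, n_b=8, shift=1.5)
        mat = tmp_path / "mat.tsv"
        table.values.to_csv(mat, sep="\t")
        out = tmp_path / "limma.tsv"
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{mat}", row.names=1))
            design <- model.matrix(~0 + factor(rep(c("A","B"), each=8)))
            colnames(design) <- c("A","B")
            fit <- lmFit(x, design)
            fit <- contrasts.fit(fit, makeContrasts(A-B, levels=design))
            fit <- eBayes(fit)
            res <- data.frame(t=fit$t[,1], p=fit$p.value[,1], d0=fit$df.prior)
            write.table(res, "{out}", sep="\\t", quote=FALSE)
        """)
        r = subprocess.run(["Rscript", "-e", script], capture_output=True,
                           text=True)
        assert r.returncode == 0, r.stderr
        ref = pd.read_csv(out, sep="\t")
        res = L.moderated_t_test(table, sheet, CONTRAST)
        np.testing.assert_allclose(res["t_mod"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(res["p"], ref["p"], rtol=1e-6)
        assert res.attrs["prior_df"] == pytest.approx(ref["d0"].iloc[0],
                                                      rel=1e-4)


def _bh_bruteforce(p):
    """Literal step-up: adj_i = min over j >= i of m * p_(j) / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        vals = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        adj[idx] = min(1.0, min(vals))
    return adj


class TestBH:
    def test_toy_example(self):
        np.testing.assert_allclose(L.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert L.bh_adjust([0.2]).tolist() == [0.2]
        assert L.bh_adjust([1.0, 1.0]).tolist() == [1.0, 1.0]
        assert L.bh_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            L.bh_adjust([0.5, 1.5])

    def test_oracle_equivalence_many_random_vectors(self):
        """bh_adjust matches the brute-force step-up and the statsmodels
        implementation on 1000 random p-vectors."""
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 201))
            p = rng.random(n)
            mine = L.bh_adjust(p)
            np.testing.assert_allclose(mine, _bh_bruteforce(p), atol=1e-12)
            sm = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(mine, sm, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=60))
    def test_monotone_in_p(self, p):
        adj = L.bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestClassifyHits:
    @pytest.mark.parametrize("log2fc,adj_p,expect_sig,expect_dir", [
        (0.97, 0.036, True, "up"),      # reported up-regulated hit
        (-0.77, 0.038, True, "down"),   # reported down-regulated hit
        (0.71, 0.999, False, "up"),     # reported non-hit (large p)
        (0.6, 0.01, False, "up"),       # boundary: strict |log2fc| > 0.6
        (0.61, 0.05, False, "up"),      # boundary: strict adj_p < 0.05
    ])
    def test_strict_rule(self, log2fc, adj_p, expect_sig, expect_dir):
        res = pd.DataFrame({"feature_id": ["X"], "log2fc": [log2fc],
                            "adj_p": [adj_p]})
        out = L.classify_hits(res, 0.6, 0.05)
        assert bool(out["significant"].iloc[0]) is expect_sig
        assert out["direction"].iloc[0] == expect_dir

    def test_inclusive_flag_admits_boundary_p(self):
        res = pd.DataFrame({"feature_id": ["X"], "log2fc": [1.25],
                            "adj_p": [0.05]})
        assert not L.classify_hits(res, 0.6, 0.05)["significant"].iloc[0]
        assert L.classify_hits(res, 0.6, 0.05,
                               adjp_inclusive=True)["significant"].iloc[0]


class TestAnovaScreen:
    def _three_groups(self, vals):
        df = pd.DataFrame(vals, index=[f"F{i}" for i in range(len(vals))],
                          columns=[f"s{i}" for i in range(len(vals[0]))])
        n = len(vals[0]) // 3
        sheet = pd.DataFrame({"sample_id": df.columns,
                              "group": ["A"] * n + ["B"] * n + ["C"] * n})
        return L.IntensityTable(df, scale="log2"), sheet

    def test_constant_feature_gets_f_zero_p_one(self):
        table, sheet = self._three_groups([[5.0] * 9])
        out = L.anova_screen(table, sheet, ["A", "B", "C"])
        assert out["F"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_strong_separation_tiny_p(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 0.1, 10),
                               rng.normal(0, 0.1, 10),
                               rng.normal(10, 0.1, 10)])
        table, sheet = self._three_groups([vals])
        out = L.anova_screen(table, sheet, ["A", "B", "C"])
        assert out["p"].iloc[0] < 1e-6

    def test_matches_textbook_decomposition_and_scipy(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, (20, 15))
        table, sheet = self._three_groups(vals)
        out = L.anova_screen(table, sheet, ["A", "B", "C"])
        groups = [vals[:, :5], vals[:, 5:10], vals[:, 10:]]
        F_ref, p_ref = stats.f_oneway(*groups, axis=1)
        np.testing.assert_allclose(out["F"], F_ref, rtol=1e-10)
        np.testing.assert_allclose(out["p"], p_ref, rtol=1e-10)

    def test_small_group_rejected(self):
        table, sheet = self._three_groups([[1.0] * 9])
        sheet.loc[sheet["group"] == "B", "group"] = "A"
        sheet.loc[0, "group"] = "B"
        with pytest.raises(DesignError, match="B"):
            L.anova_screen(table, sheet, ["A", "B", "C"])


def test_planted_pooled_carrier_effect_is_top_hit_across_seeds():
    """The carrier-wide hyperphosphorylated site (planted log2 shift 0.95) is
    the smallest-adj_p hit of the pooled-carriers contrast in >= 90% of
    seeded cohorts."""
    wins = 0
    n_seeds = 20
    contrast = L.Contrast("carriers_vs_ctrl",
                          {"G2019S_L2PD", "G2019S_L2NMC"}, {"CTRL"})
    for seed in range(n_seeds):
        b = L.generate_bundle(seed=seed, n_proteins=50, n_sites=1500)
        phos, _ = L.preprocess_phospho(b.phospho_long)
        res = L.moderated_t_test(phos, b.sheet, contrast)
        top = res.sort_values(["adj_p", "p"]).iloc[0]["feature_id"]
        planted = [f for f, eff in b.truth.planted_phospho_effects.items()
                   if set(eff) == {"G2019S_L2PD", "G2019S_L2NMC"}]
        wins += int(top in planted)
    assert wins >= int(0.9 * n_seeds)
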