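"""Variance components, heritability, G x C ANOVA, correlations, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ionuptake as iu
from ionuptake.errors import ValidationError
from ionuptake.quantgen_stats import anova_gxc, correlation_matrix, pca_summary


class TestHeritability:
    def test_direct_substitution(self):
        # sigma_g2=3, sigma_e2=6, r=6 -> 3/(3+1) = 0.75
        assert iu.heritability(3.0, 6.0, 6.0) == pytest.approx(0.75)

    def test_no_genetic_variance_gives_zero(self):
        assert iu.heritability(0.0, 6.0, 6.0) == 0.0

    def test_vanishing_residual_limit(self):
        assert iu.heritability(1.0, 1e-9, 1.0) > 0.999

    def test_nonpositive_r_rejected(self):
        with pytest.raises(ValidationError):
            iu.heritability(1.0, 1.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        sg=st.floats(min_value=0.01, max_value=100),
        se=st.floats(min_value=0.01, max_value=100),
        r=st.integers(min_value=1, max_value=20),
    )
    def test_monotonicity(self, sg, se, r):
        h = iu.heritability(sg, se, r)
        assert iu.heritability(sg * 1.1, se, r) > h
        assert iu.heritability(sg, se * 1.1, r) < h
        assert iu.heritability(sg, se, r + 1) > h
        assert 0.0 <= h <= 1.0


class TestVarianceComponents:
    def brute_force_mean_squares(self, df):
        """Independent direct sums-of-squares computation."""
        grand = df["value"].mean()
        groups = df.groupby("genotype")["value"]
        ss_b = sum(len(g) * (g.mean() - grand) ** 2 for _, g in groups)
        ss_w = sum(((g - g.mean()) ** 2).sum() for _, g in groups)
        g = df["genotype"].nunique()
        return ss_b / (g - 1), ss_w / (len(df) - g)

    def test_toy_table_matches_brute_force(self):
        df = pd.DataFrame(
            {"genotype": ["a", "a", "b", "b", "c", "c"],
             "value": [1.0, 2.0, 4.0, 6.0, 3.0, 7.0]}
        )
        vc = iu.variance_components(df, "value")
        ms_g, ms_e = self.brute_force_mean_squares(df)
        assert vc.ms_genotype == pytest.approx(ms_g)
        assert vc.ms_residual == pytest.approx(ms_e)
        assert vc.r == pytest.approx(2.0)
        assert vc.h2 == pytest.approx(
            max(0, (ms_g - ms_e) / 2) / (max(0, (ms_g - ms_e) / 2) + ms_e / 2)
        )

    def test_identical_genotype_means_truncates_to_zero(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"genotype": np.repeat([f"g{i}" for i in range(10)], 4),
             "value": np.tile(rng.normal(size=4), 10)}
        )
        vc = iu.variance_components(df, "value")
        assert vc.sigma_g2 == 0.0
        assert vc.sigma_g2_raw < 0.0
        assert vc.h2 == 0.0

    def test_parameter_recovery_balanced(self):
        # generated at sigma_g2=3, sigma_e2=6, G=26, r=6
        rng = np.random.default_rng(123)
        est_g, est_e = [], []
        for _ in range(300):
            df = iu.simulate_genotype_trait(3.0, 6.0, 26, 6, rng)
            vc = iu.variance_components(df, "value")
            est_g.append(vc.sigma_g2)
            est_e.append(vc.sigma_e2)
        # moment estimators are (nearly) unbiased; Monte-Carlo SE ~ 0.06
        assert np.mean(est_g) == pytest.approx(3.0, abs=0.2)
        assert np.mean(est_e) == pytest.approx(6.0, abs=0.1)

    def test_reml_close_to_moments_on_balanced_data(self):
        rng = np.random.default_rng(5)
        df = iu.simulate_genotype_trait(3.0, 6.0, 26, 6, rng)
        mom = iu.variance_components(df, "value", method="moments")
        reml = iu.variance_components(df, "value", method="reml")
        assert reml.sigma_e2 == pytest.approx(mom.sigma_e2, rel=0.05)
        assert reml.h2 == pytest.approx(mom.h2, abs=0.1)

    def test_single_genotype_rejected(self):
        df = pd.DataFrame({"genotype": ["a"] * 4, "value": [1.0, 2, 3, 4]})
        with pytest.raises(ValidationError):
            iu.variance_components(df, "value")

    def test_constant_trait_rejected(self):
        df = pd.DataFrame({"genotype": ["a", "a", "b", "b"], "value": [1.0] * 4})
        with pytest.raises(ValidationError):
            iu.variance_components(df, "value")

    def test_harmonic_r_mode_under_missingness(self):
        df = pd.DataFrame(
            {"genotype": ["a"] * 6 + ["b"] * 2,
             "value": [1.0, 2, 3, 4, 5, 6, 2, 4]}
        )
        mean_r = iu.variance_components(df, "value", r_mode="mean").r
        harm_r = iu.variance_components(df, "value", r_mode="harmonic").r
        assert mean_r == pytest.approx(4.0)
        assert harm_r == pytest.approx(2 / (1 / 6 + 1 / 2))


class TestAnovaGxC:
    def balanced_toy(self):
        # 2 genotypes x 2 concentrations x 3 reps with planted effects
        rows = []
        rng = np.random.default_rng(9)
        for g, ge in (("g1", 0.0), ("g2", 2.0)):
            for c, ce in (("low", 0.0), ("high", 1.0)):
                inter = 1.5 if (g, c) == ("g2", "high") else 0.0
                for rep in range(3):
                    rows.append(
                        {"genotype": g, "treatment": c, "block": f"b{rep}",
                         "value": ge + ce + inter + rng.normal(0, 0.3)}
                    )
        return pd.DataFrame(rows)

    def brute_force_two_way(self, df):
        """Direct balanced two-way ANOVA sums of squares (no block)."""
        grand = df["value"].mean()
        n = len(df)
        ss_a = sum(
            len(g) * (g["value"].mean() - grand) ** 2
            for _, g in df.groupby("genotype")
        )
        ss_b = sum(
            len(g) * (g["value"].mean() - grand) ** 2
            for _, g in df.groupby("treatment")
        )
        ss_cells = sum(
            len(g) * (g["value"].mean() - grand) ** 2
            for _, g in df.groupby(["genotype", "treatment"])
        )
        ss_ab = ss_cells - ss_a - ss_b
        ss_tot = ((df["value"] - grand) ** 2).sum()
        ss_err = ss_tot - ss_cells
        a = df["genotype"].nunique()
        b = df["treatment"].nunique()
        df_err = n - a * b
        return {
            "genotype": (ss_a / (a - 1)) / (ss_err / df_err),
            "concentration": (ss_b / (b - 1)) / (ss_err / df_err),
            "genotype:concentration": (ss_ab / ((a - 1) * (b - 1))) / (ss_err / df_err),
        }

    def test_balanced_f_statistics_match_brute_force(self):
        df = self.balanced_toy()
        table = anova_gxc(df, "value", block=None)
        expect = self.brute_force_two_way(df)
        for term, f in expect.items():
            assert table.loc[term, "F"] == pytest.approx(f, rel=1e-9)

    def test_planted_interaction_detected(self):
        hits = 0
        rng = np.random.default_rng(17)
        for _ in range(40):
            rows = []
            inter = rng.normal(0.0, 1.0, size=(26, 2))  # interaction SD = resid SD
            for i in range(26):
                for j, c in enumerate(("low", "high")):
                    for _rep in range(6):
                        rows.append(
                            {"genotype": f"g{i}", "treatment": c,
                             "value": inter[i, j] + rng.normal(0, 1.0)}
                        )
            tab = anova_gxc(pd.DataFrame(rows), "value", block=None)
            hits += tab.loc["genotype:concentration", "PR(>F)"] < 0.05
        assert hits / 40 >= 0.8

    def test_single_concentration_level_reduces_to_one_way(self):
        df = self.balanced_toy()
        df = df[df["treatment"] == "high"]
        table = anova_gxc(df, "value", block=None)
        assert "genotype" in table.index
        assert "genotype:concentration" not in table.index

    def test_constant_response_rejected(self):
        df = self.balanced_toy().assign(value=1.0)
        with pytest.raises(ValidationError):
            anova_gxc(df, "value")

    def test_aliased_block_rejected(self):
        df = self.balanced_toy().assign(block=lambda d: d["treatment"])
        with pytest.raises(ValidationError, match="aliased"):
            anova_gxc(df, "value")


class TestCorrelations:
    def test_perfect_linear_relation(self):
        df = pd.DataFrame({"x": [0.0, 1, 2, 3], "y": [1.0, 3, 5, 7]})
        out = correlation_matrix(df, ["x", "y"])
        assert out.r.loc["x", "y"] == pytest.approx(1.0)

    def test_perfect_negative(self):
        df = pd.DataFrame({"x": [0.0, 1, 2], "y": [0.0, -1, -2]})
        assert correlation_matrix(df, ["x", "y"]).r.loc["x", "y"] == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        df = pd.DataFrame({"x": [0.0, 1, 2], "y": [0.0, 2, 1]})
        assert correlation_matrix(df, ["x", "y"]).r.loc["x", "y"] == pytest.approx(0.5)

    def test_constant_trait_flagged_missing(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [0.0, 1, 2, 3]})
        out = correlation_matrix(df, ["x", "y"])
        assert np.isnan(out.r.loc["x", "y"])
        assert out.flags["x|y"] == "constant_trait"

    def test_pairwise_complete_counts(self):
        df = pd.DataFrame(
            {"x": [1.0, 2, 3, np.nan, 5], "y": [2.0, 4, 5, 7, np.nan]}
        )
        out = correlation_matrix(df, ["x", "y"])
        assert out.n.loc["x", "y"] == 3

    def test_bh_adjustment_not_smaller_than_raw(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        raw = correlation_matrix(df, list("abcd"))
        adj = correlation_matrix(df, list("abcd"), adjust="bh")
        off = ~np.eye(4, dtype=bool)
        assert (adj.p.to_numpy()[off] >= raw.p.to_numpy()[off] - 1e-15).all()


class TestPCA:
    def test_two_perfectly_correlated_traits_pc1_explains_all(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        out = pca_summary(df, ["a", "b"])
        assert out.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        out = pca_summary(df, list("abcde"))
        assert out.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_isotropic_gaussian_splits_evenly(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        out = pca_summary(df, ["a", "b"])
        assert out.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.02)

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(ValidationError):
            pca_summary(pd.DataFrame({"a": [1.0], "b": [2.0]}), ["a", "b"])
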