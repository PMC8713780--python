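"""Trait derivations and the statistical model stages."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trawlscan as ts
from trawlscan.phenostats import multivariate_glm


class TestSgr:
    def test_conventional_zero_growth(self):
        assert ts.sgr(0.25, 0.25, 90) == pytest.approx(0.0)

    def test_as_printed_unit_mass_difference(self):
        assert ts.sgr(0.2, 1.2, 90, variant="as_printed") == pytest.approx(0.0)

    def test_conventional_hand_value(self):
        assert ts.sgr(0.2, 0.3, 90) == pytest.approx(100 * np.log(1.5) / 90)

    def test_as_printed_requires_positive_gain(self):
        with pytest.raises(ValueError):
            ts.sgr(0.3, 0.2, 90, variant="as_printed")

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            ts.sgr(0.2, 0.3, 0)
        with pytest.raises(ValueError):
            ts.sgr(0.2, 0.3, 90, variant="nope")


class TestMo2:
    def test_blank_equals_slope_gives_zero(self):
        assert ts.mo2_from_slope(1.3, 0.022, 0.0003, blank_slope=1.3) == 0.0

    def test_definition(self):
        assert ts.mo2_from_slope(2.0, 0.022, 0.002) == pytest.approx(2.0 * 0.02)

    def test_per_minute_conversion_and_toy_series(self):
        # toy: slope 0.05 mg/L/min, blank 0.01, chamber 22 mL, fish 0.3 mL
        got = ts.mo2_from_slope(0.05, 0.022, 0.0003, 0.01, per_hour_factor=60.0)
        assert got == pytest.approx((0.05 - 0.01) * (0.022 - 0.0003) * 60)

    def test_fish_larger_than_chamber_rejected(self):
        with pytest.raises(ValueError):
            ts.mo2_from_slope(1.0, 0.02, 0.03)


class TestSmrMmr:
    def test_constant_series(self):
        smr, mmr, aerobic = ts.smr_mmr([2.0] * 8, [2.0] * 4)
        assert (smr, mmr, aerobic) == (2.0, 2.0, 0.0)

    def test_type7_quantile_on_1_to_10(self):
        smr, _, _ = ts.smr_mmr(np.arange(1.0, 11.0), [5.0])
        assert smr == pytest.approx(2.8)

    def test_mmr_is_the_windowed_maximum(self):
        _, mmr, _ = ts.smr_mmr([1.0], [5.0, 9.0, 7.0])
        assert mmr == 9.0
        _, mmr, _ = ts.smr_mmr(
            [1.0], [5.0, 9.0, 7.0], window=30, post_exercise_times=[5, 40, 10]
        )
        assert mmr == 7.0  # the 9.0 falls outside the 30-min window

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ts.smr_mmr([], [1.0])


class TestRankTransform:
    def test_order_preserved(self):
        assert list(ts.rank_transform([3, 1, 2])) == [3, 1, 2]

    def test_ties_share_mean_rank(self):
        assert list(ts.rank_transform([5, 5])) == [1.5, 1.5]

    def test_matches_sort_reconstruction(self, rng):
        x = rng.normal(size=200)
        ranks = ts.rank_transform(x)
        order = np.argsort(x)
        expect = np.empty_like(ranks)
        expect[order] = np.arange(1, len(x) + 1)
        assert np.allclose(ranks, expect)  # no ties in continuous data


def _design(rng, n_per_cell=8, effect=0.0):
    rows = []
    for sex in ("M", "F"):
        for density in ("baseline", "reduced"):
            for vuln in ("captured", "escaped"):
                for _ in range(n_per_cell):
                    y = rng.normal() + (effect if vuln == "escaped" else 0.0)
                    rows.append(
                        {
                            "sex": sex,
                            "density": density,
                            "vulnerability": vuln,
                            "mass": rng.normal(0.3, 0.03),
                            "y": y,
                        }
                    )
    return pd.DataFrame(rows)


class TestFactorialGlm:
    def test_balanced_two_group_equals_squared_t(self, rng):
        df = _design(rng, effect=0.8)
        table = ts.factorial_glm(
            df, "y", factors=("vulnerability",), covariate=None, interactions=False
        )
        a = df.loc[df["vulnerability"] == "captured", "y"]
        b = df.loc[df["vulnerability"] == "escaped", "y"]
        t, p = stats.ttest_ind(a, b)
        f_row = table.loc["C(vulnerability, Sum)"]
        assert f_row["F"] == pytest.approx(t**2, rel=1e-9)
        assert f_row["p_value"] == pytest.approx(p, rel=1e-9)

    def test_covariate_consumes_one_residual_df(self, rng):
        df = _design(rng)
        with_cov = ts.factorial_glm(df, "y", covariate="mass")
        without = ts.factorial_glm(df, "y", covariate=None)
        assert without.attrs["resid_df"] - with_cov.attrs["resid_df"] == 1

    def test_type3_equals_sequential_on_balanced_design(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = _design(rng, effect=0.5)
        t3 = ts.factorial_glm(df, "y", covariate=None, interactions=False)
        seq = sm.stats.anova_lm(
            ols(
                "y ~ C(sex, Sum) + C(density, Sum) + C(vulnerability, Sum)", df
            ).fit(),
            typ=1,
        )
        for term in ("C(sex, Sum)", "C(density, Sum)", "C(vulnerability, Sum)"):
            assert t3.loc[term, "F"] == pytest.approx(seq.loc[term, "F"], rel=1e-8)

    def test_rank_model_invariant_to_monotone_transform(self, rng):
        df = _design(rng, effect=0.7)
        base = ts.factorial_glm(df, "y", covariate=None, rank_response=True)
        df2 = df.assign(y=np.exp(df["y"]))
        trans = ts.factorial_glm(df2, "y", covariate=None, rank_response=True)
        assert np.allclose(base["F"].dropna(), trans["F"].dropna())

    def test_aliased_term_is_named(self, rng):
        df = _design(rng)
        df["vulnerability"] = df["density"].map(
            {"baseline": "captured", "reduced": "escaped"}
        )  # perfectly confounded factors
        with pytest.raises(ValueError, match="aliased"):
            ts.factorial_glm(df, "y", covariate=None)


class TestMultivariateGlm:
    def test_single_trait_reduces_to_univariate_f(self, rng):
        df = _design(rng, effect=0.9)
        uni = ts.factorial_glm(df, "y", covariate="mass")
        multi = multivariate_glm(df, ("y",), covariate="mass")
        row = [t for t in multi.index if "vulnerability" in t and ":" not in t][0]
        assert multi.loc[row, "F"] == pytest.approx(
            uni.loc["C(vulnerability, Sum)", "F"], rel=1e-6
        )

    def test_null_type_one_error_rate(self, rng):
        hits = 0
        reps = 300
        for _ in range(reps):
            df = _design(rng, n_per_cell=5)
            df["y2"] = rng.normal(size=len(df))
            multi = multivariate_glm(
                df, ("y", "y2"), factors=("vulnerability",), covariate=None
            )
            row = [t for t in multi.index if "vulnerability" in t][0]
            hits += multi.loc[row, "p_value"] < 0.05
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se + 1e-9

    def test_planted_shift_strengthens_evidence(self, rng):
        # same noise realisation at every effect size: evidence must grow
        base = _design(rng, n_per_cell=10, effect=0.0)
        noise2 = rng.normal(size=len(base))
        pvals = []
        for effect in (0.0, 0.8, 2.0):
            df = base.copy()
            shift = (df["vulnerability"] == "escaped") * effect
            df["y"] = base["y"] + shift
            df["y2"] = df["y"] * 0.5 + noise2
            multi = multivariate_glm(
                df, ("y", "y2"), factors=("vulnerability",), covariate=None
            )
            row = [t for t in multi.index if "vulnerability" in t][0]
            pvals.append(multi.loc[row, "p_value"])
        assert pvals[0] > pvals[1] > pvals[2]

    def test_singular_responses_rejected(self, rng):
        df = _design(rng)
        df["y2"] = df["y"]  # perfectly collinear responses
        with pytest.raises(ValueError, match="singular"):
            multivariate_glm(df, ("y", "y2"), covariate=None)


class TestPcTraitCorrelation:
    def test_collinear_pair(self, rng):
        score = rng.normal(size=30)
        labels = np.array(["baseline", "reduced"] * 15)
        out = ts.pc_trait_correlation(score, 2.0 * score, labels)
        assert out["combined"]["r"] == pytest.approx(1.0)
        assert out["combined"]["p"] < 1e-20

    def test_r2_identity_per_stratum(self, rng):
        score = rng.normal(size=60)
        trait = 0.4 * score + rng.normal(size=60)
        labels = np.repeat(["baseline", "reduced"], 30)
        out = ts.pc_trait_correlation(score, trait, labels)
        for key in ("combined", "baseline", "reduced"):
            assert out[key]["r2"] == pytest.approx(out[key]["r"] ** 2)

    def test_recovery_within_fisher_interval(self, rng):
        # analytic sampling oracle: Fisher z interval around the true r
        a, n = 0.8, 48
        true_r = a / np.sqrt(a**2 + 1.0)
        score = rng.normal(size=n)
        trait = a * score + rng.normal(size=n)
        labels = np.repeat(["baseline"], n)
        out = ts.pc_trait_correlation(
            np.concatenate([score, score]),
            np.concatenate([trait, a * score + rng.normal(size=n)]),
            np.repeat(["baseline", "reduced"], n),
        )
        z = np.arctanh(out["baseline"]["r"])
        z_true = np.arctanh(true_r)
        assert abs(z - z_true) < 3.5 / np.sqrt(n - 3)

    def test_interaction_detected_when_slopes_differ(self, rng):
        n = 60
        score = rng.normal(size=2 * n)
        labels = np.repeat(["baseline", "reduced"], n)
        slope = np.where(labels == "baseline", 1.2, -1.2)
        trait = slope * score + rng.normal(size=2 * n) * 0.5
        out = ts.pc_trait_correlation(score, trait, labels)
        assert out["interaction_p"] < 1e-6

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            ts.pc_trait_correlation(
                np.ones(10), rng.normal(size=10), np.repeat(["baseline"], 10)
            )
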