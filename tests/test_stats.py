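"""Cleaning, imputation, and two-group characterization statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiclust.cohort import CohortSpec, generate_cohort, inject_missingness
from epiclust.stats import (
    StatsConfig,
    bonferroni_adjust,
    characterize,
    chi2_2x2,
    clean_and_impute,
    shapiro_wilk,
    summary_t,
    two_sample_t,
)


class TestCleanAndImpute:
    def test_majority_missing_subjects_are_removed(self, study_spec):
        """205 subjects, 5 with >50% missing, leaves a 200-subject table."""
        table, _ = generate_cohort(CohortSpec(n=205), seed=0)
        data_cols = [c for c in table.columns if c != "subject_id"]
        spoiled = table.copy()
        victims = spoiled.index[:5]
        n_spoil = int(len(data_cols) * 0.6)
        spoiled.loc[victims, data_cols[:n_spoil]] = np.nan
        cleaned, removed = clean_and_impute(spoiled, seed=1)
        assert len(cleaned) == 200
        assert set(removed["subject_id"]) == set(table.loc[victims, "subject_id"])
        assert not cleaned.drop(columns="subject_id").isna().any().any()

    def test_no_missing_is_identity(self, study_cohort):
        table, _ = study_cohort
        cleaned, removed = clean_and_impute(table, seed=0)
        assert cleaned.equals(table.reset_index(drop=True))
        assert removed.empty

    def test_imputed_values_come_from_observed_support(self, study_cohort):
        table, _ = study_cohort
        holed = inject_missingness(table, 0.15, seed=2)
        cleaned, _ = clean_and_impute(holed, seed=3)
        for c in cleaned.columns:
            if c == "subject_id":
                continue
            observed = set(holed[c].dropna())
            assert set(cleaned[c]) <= observed

    def test_exactly_half_missing_is_kept(self):
        table = pd.DataFrame(
            {"subject_id": ["a", "b"], "x": [np.nan, 1.0], "y": [2.0, 3.0]}
        )
        cleaned, removed = clean_and_impute(table, seed=0)
        assert len(cleaned) == 2 and removed.empty


class TestTTests:
    def test_welch_t_matches_published_externalizing_row(self):
        res = summary_t(102, 47.1, 6.51, 98, 58.9, 7.10, variant="welch")
        assert abs(res.statistic) == pytest.approx(12.24, abs=0.005)
        assert res.kind == "welch_t"

    def test_pooled_t_matches_published_igf2_row(self):
        res = summary_t(102, 39.05, 3.86, 98, 37.65, 5.29, variant="pooled")
        assert abs(res.statistic) == pytest.approx(2.14, abs=0.005)
        assert res.effect == pytest.approx(0.30, abs=0.005)  # Cohen's d, pooled SD

    def test_identical_samples_give_zero(self):
        x = np.arange(10.0)
        res = two_sample_t(x, x)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    def test_summary_and_raw_agree_on_moment_matched_input(self, rng):
        """Standardize raw samples to exact moments; the two entry points
        must agree to near machine precision."""
        for variant in ("welch", "pooled"):
            x = rng.normal(size=40)
            y = rng.normal(size=55)
            x = (x - x.mean()) / x.std(ddof=1) * 2.5 + 10.0
            y = (y - y.mean()) / y.std(ddof=1) * 3.1 + 11.2
            raw = two_sample_t(x, y, variant=variant)
            summ = summary_t(40, 10.0, 2.5, 55, 11.2, 3.1, variant=variant)
            assert raw.statistic == pytest.approx(summ.statistic, abs=1e-10)
            assert raw.df == pytest.approx(summ.df, abs=1e-8)

    @given(
        n1=st.integers(3, 40), n2=st.integers(3, 40),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=30, deadline=None)
    def test_welch_df_bounded_by_pooled_df(self, n1, n2, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=n1), r.normal(0.5, 2.0, size=n2)
        res = two_sample_t(x, y, variant="welch")
        assert res.df <= n1 + n2 - 2 + 1e-9


class TestChi2:
    def test_matches_published_perinatal_contrast(self):
        """Counts rebuilt from cluster sizes 102/98 at 46%/66% prevalence."""
        res = chi2_2x2(47, 55, 65, 33, yates=True)
        assert res.statistic == pytest.approx(7.51, abs=0.01)
        assert res.p_raw == pytest.approx(0.006, abs=0.0005)
        assert res.effect == pytest.approx(0.20, abs=0.005)  # Phi, uncorrected

    def test_equal_proportions_give_zero(self):
        res = chi2_2x2(30, 70, 30, 70, yates=False)
        assert res.statistic == pytest.approx(0.0)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(ValueError):
            chi2_2x2(0, 0, 5, 5)

    @given(
        a=st.integers(1, 200), b=st.integers(1, 200),
        c=st.integers(1, 200), d=st.integers(1, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_yates_never_exceeds_uncorrected(self, a, b, c, d):
        assert (
            chi2_2x2(a, b, c, d, yates=True).statistic
            <= chi2_2x2(a, b, c, d, yates=False).statistic + 1e-12
        )


class TestBonferroni:
    def test_examples(self):
        adj, sig = bonferroni_adjust([0.01, 0.5, 0.002], alpha=0.05)
        # m = 3 comparisons
        assert adj == pytest.approx([0.03, 1.0, 0.006])
        assert list(sig) == [True, False, True]

    def test_single_comparison_scaling(self):
        adj, _ = bonferroni_adjust([0.01] * 5)
        assert adj == pytest.approx([0.05] * 5)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform(self, ps):
        adj, _ = bonferroni_adjust(ps)
        order = np.argsort(ps, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestShapiroWilk:
    def test_normal_quantiles_are_nearly_perfect(self):
        from scipy.stats import norm

        q = norm.ppf((np.arange(1, 51) - 0.5) / 50)
        w, p = shapiro_wilk(q)
        assert w > 0.99

    def test_w_bounded_by_one(self, rng):
        for _ in range(5):
            w, _ = shapiro_wilk(rng.exponential(size=30))
            assert w <= 1.0

    def test_matches_r_reference_value(self):
        """Frozen from R's shapiro.test on the same vector (AS R94)."""
        x = [2.1, 3.4, 1.9, 5.6, 4.4, 3.3, 2.8, 6.1, 0.9, 3.7,
             4.0, 2.2, 5.1, 3.9, 2.6]
        w, p = shapiro_wilk(x)
        assert w == pytest.approx(0.983133, abs=1e-3)
        assert p == pytest.approx(0.986466, abs=1e-3)

    def test_constant_input_is_degenerate(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0] * 10)


class TestCharacterize:
    def test_report_covers_every_variable(self, study_cohort):
        table, labels = study_cohort
        report = characterize(table, labels)
        # 3 binary + age/ses/internalizing/externalizing + 54 CpGs
        assert len(report.table) == 3 + 4 + 54
        assert report.table["p_bonferroni"].notna().sum() == 54
        assert sum(report.cluster_sizes) == len(table)

    def test_tscore_rows_significant_after_bonferroni(self, study_cohort):
        """The clusters are defined by their T-scores, so the internalizing
        and externalizing contrasts must survive correction."""
        table, labels = study_cohort
        report = characterize(
            table, labels, StatsConfig(bonferroni_family="all")
        ).table
        for var in ("internalizing", "externalizing"):
            row = report[report["variable"] == var].iloc[0]
            assert row["significant"]
            assert row["p_bonferroni"] < 0.001

    def test_sign_convention_is_high_minus_low(self, study_cohort):
        table, labels = study_cohort
        report = characterize(table, labels).table
        row = report[report["variable"] == "internalizing"].iloc[0]
        assert row["statistic"] > 0  # HIGH cluster scores higher
        assert row["high_mean"] > row["low_mean"]

    def test_string_labels_accepted(self, study_cohort):
        table, labels = study_cohort
        names = np.where(labels == 0, "LOW", "HIGH")
        r1 = characterize(table, labels).table
        r2 = characterize(table, names).table
        pd.testing.assert_frame_equal(r1, r2)

    def test_null_methylation_calibration(self):
        """With no between-component methylation differences the raw-p
        rejection rate at alpha=0.05 stays within 3 binomial SDs."""
        null_spec = CohortSpec()
        null_spec.methylation_means = np.repeat(
            null_spec.methylation_means[:1], 2, axis=0
        )
        null_spec.methylation_sds = np.repeat(
            null_spec.methylation_sds[:1], 2, axis=0
        )
        rejections, total = 0, 0
        for seed in range(12):
            table, labels = generate_cohort(null_spec, seed=seed)
            rep = characterize(table, labels).table
            meth = rep[rep["group"] == "methylation"]
            rejections += int((meth["p_raw"] < 0.05).sum())
            total += len(meth)
        rate = rejections / total
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / total)
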