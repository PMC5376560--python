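import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from masticnet.stats import (
    chi_square_2x2,
    identify_hubs,
    median_split,
    partial_correlation,
    pearson_correlation,
    screen_edges,
    two_sample_t,
)


def precision_matrix_partial_r(x, y, z):
    """Independent oracle: r_xy.z = -Omega_xy / sqrt(Omega_xx * Omega_yy)
    from the inverse covariance of [x, y, z...]."""
    m = np.column_stack([x, y, np.asarray(z)])
    omega = np.linalg.inv(np.cov(m, rowvar=False))
    return -omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1])


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        res = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r_partial == pytest.approx(r_ref, abs=1e-12)
        assert res.p_two_tailed == pytest.approx(p_ref, abs=1e-12)
        assert res.df == 38

    def test_matches_precision_matrix_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            m = rng.standard_normal((30, 4)) @ rng.standard_normal((4, 4))
            x, y, z = m[:, 0], m[:, 1], m[:, 2:]
            res = partial_correlation(x, y, z)
            assert res.r_partial == pytest.approx(
                precision_matrix_partial_r(x, y, z), abs=1e-10
            )

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((60, 4)), columns=list("xyzw"))
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z", "w"])
        res = partial_correlation(df.x, df.y, df[["z", "w"]])
        assert res.r_partial == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.p_two_tailed == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-10)

    def test_null_p_values_uniform(self):
        """y depends only on the covariates; x is independent."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            z = rng.standard_normal((50, 2))
            y = z @ np.array([1.5, -2.0]) + rng.standard_normal(50)
            x = rng.standard_normal(50)
            pvals.append(partial_correlation(x, y, z).p_two_tailed)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_pure_noise_covariate_changes_little(self):
        rng = np.random.default_rng(4)
        n = 1000
        z = rng.standard_normal((n, 1))
        x = z[:, 0] + rng.standard_normal(n)
        y = 0.5 * z[:, 0] + rng.standard_normal(n)
        base = partial_correlation(x, y, z)
        noisy = partial_correlation(x, y, np.column_stack([z, rng.standard_normal(n)]))
        assert abs(base.r_partial - noisy.r_partial) < 0.05

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match="n >= k"):
            partial_correlation([1, 2, 3], [3, 2, 1], np.ones((3, 1)) * [[1], [2], [3]])

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((20, 1))
        zz = np.column_stack([z, 2 * z])
        with pytest.raises(ValueError, match="rank"):
            partial_correlation(rng.standard_normal(20), rng.standard_normal(20), zz)


class TestMedianSplit:
    def test_emulated_cohort_splits_26_26_at_54_5(self):
        rng = np.random.default_rng(6)
        older = rng.uniform(55, 74, 26)
        younger = rng.uniform(23, 54, 26)
        older[0], younger[0] = 55.0, 54.0  # pin the middle pair -> median 54.5
        phen = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(52)],
             "age": np.concatenate([older, younger])}
        )
        split = median_split(phen)
        assert split.threshold_age == pytest.approx(54.5)
        groups = pd.Series(split.assignment)
        assert (groups == "older").sum() == 26
        assert (groups == "younger").sum() == 26

    def test_small_example(self):
        phen = pd.DataFrame({"subject_id": list("abcd"), "age": [1.0, 2.0, 3.0, 4.0]})
        split = median_split(phen)
        assert split.threshold_age == 2.5
        assert {s for s, g in split.assignment.items() if g == "older"} == {"c", "d"}

    def test_tie_at_median_is_an_error(self):
        phen = pd.DataFrame({"subject_id": ["a", "b"], "age": [5.0, 5.0]})
        with pytest.raises(ValueError, match="tie"):
            median_split(phen)


class TestTwoSampleT:
    def test_identical_groups(self):
        t, df, p = two_sample_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", ["welch", "pooled"])
    def test_printed_group_summaries_highly_significant(self, mode):
        # chewing-performance means 70.5 +/- 3.3 vs 73.3 +/- 1.6, n=26 each
        _, _, p = two_sample_t(mode=mode, from_summary=((70.5, 3.3, 26), (73.3, 1.6, 26)))
        assert p < 0.001

    @pytest.mark.parametrize("mode", ["welch", "pooled"])
    def test_raw_equals_summary_mode(self, mode):
        rng = np.random.default_rng(7)
        a, b = rng.standard_normal(20) + 0.5, rng.standard_normal(25)
        t1, df1, p1 = two_sample_t(a, b, mode=mode)
        summ = ((a.mean(), a.std(ddof=1), 20), (b.mean(), b.std(ddof=1), 25))
        t2, df2, p2 = two_sample_t(mode=mode, from_summary=summ)
        assert t1 == pytest.approx(t2, abs=1e-10)
        assert df1 == pytest.approx(df2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)

    @pytest.mark.parametrize("mode,equal_var", [("welch", False), ("pooled", True)])
    def test_matches_scipy(self, mode, equal_var):
        rng = np.random.default_rng(8)
        a, b = rng.standard_normal(15) + 1, rng.standard_normal(30) * 2
        t, _, p = two_sample_t(a, b, mode=mode)
        ref = sps.ttest_ind(a, b, equal_var=equal_var)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestChiSquare2x2:
    def test_printed_gender_counts(self):
        # older 7M/19F vs younger 12M/14F
        chi2, df, p = chi_square_2x2([[7, 19], [12, 14]])
        assert df == 1
        assert round(chi2, 2) == 1.33
        assert round(p, 2) == 0.25

    def test_balanced_table_clamps_to_zero(self):
        chi2, _, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_uncorrected_pearson_value(self):
        chi2, _, _ = chi_square_2x2([[7, 19], [12, 14]], continuity_correction=False)
        assert round(chi2, 2) == 2.07

    def test_matches_scipy_contingency(self):
        table = [[8, 17], [15, 12]]
        chi2, _, p = chi_square_2x2(table)
        ref = sps.chi2_contingency(np.array(table), correction=True)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 6]])


class TestPearsonCorrelation:
    def test_perfectly_correlated(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0, abs=1e-12)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0, abs=1e-12)

    def test_planted_age_decline_recovered(self, older_decline_cohort):
        phen = older_decline_cohort
        older = phen[phen.group == "older"]
        r, p = pearson_correlation(older.age, older.mpi)
        assert r < 0
        assert p < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation(np.ones(10), np.arange(10.0))


@pytest.fixture(scope="module")
def older_decline_cohort():
    from masticnet.io import phenotypes_to_frame
    from masticnet.synthetic import CohortSpec, generate_cohort

    spec = CohortSpec(n_subjects=200, seed=42, n_timepoints=40, coupling_plan=())
    phenos, *_ = generate_cohort(spec)
    return phenotypes_to_frame(phenos)


class TestHubIdentification:
    def test_planted_hub_recovered(self, planted_hub_cohort):
        phen, dc, _, _ = planted_hub_cohort
        hubs = identify_hubs(dc, phen)
        assert len(hubs) == 24
        row = hubs[hubs.label == "CAnt_L"].iloc[0]
        assert row.is_hub
        assert row.r_partial > 0
        assert row.p < 0.05

    def test_nonplanted_nodes_near_nominal_rate(self, planted_hub_cohort):
        phen, dc, _, _ = planted_hub_cohort
        hubs = identify_hubs(dc, phen)
        others = hubs[hubs.label != "CAnt_L"]
        assert (others.p < 0.05).mean() <= 0.15

    def test_constant_behavior_rejected(self, planted_hub_cohort):
        phen, dc, _, _ = planted_hub_cohort
        flat = phen.copy()
        flat["mpi"] = 70.0
        with pytest.raises(ValueError, match="variance"):
            identify_hubs(dc, flat)

    def test_subject_order_invariance(self, planted_hub_cohort):
        phen, dc, _, _ = planted_hub_cohort
        shuffled = phen.sample(frac=1.0, random_state=11)
        a = identify_hubs(dc, phen)
        b = identify_hubs(dc, shuffled)
        pd.testing.assert_frame_equal(a, b, check_exact=False, atol=1e-12)

    def test_missing_phenotype_named(self, planted_hub_cohort):
        phen, dc, _, _ = planted_hub_cohort
        broken = phen.copy()
        broken.loc[3, "age"] = np.nan
        with pytest.raises(ValueError, match=str(broken.loc[3, "subject_id"])):
            identify_hubs(dc, broken)

    def test_null_cohort_false_positive_rate_in_binomial_bounds(self, null_cohort):
        phen, dc, _, _ = null_cohort
        hubs = identify_hubs(dc, phen)
        n_sig = int((hubs.p < 0.05).sum())
        hi = int(sps.binom.ppf(0.975, 24, 0.05))
        assert n_sig <= max(hi, 3)


class TestEdgeScreening:
    def test_276_rows_for_24_nodes(self, null_cohort):
        phen, _, weights, _ = null_cohort
        table = screen_edges(weights, phen)
        assert len(table) == 276
        assert not table.isna().any().any()

    def test_null_fraction_significant_near_alpha(self, null_cohort):
        phen, _, weights, _ = null_cohort
        table = screen_edges(weights, phen)
        frac = (table.p < 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_planted_edge_has_smallest_p(self, planted_edge_cohort):
        phen, _, weights, _ = planted_edge_cohort
        table = screen_edges(weights, phen)
        best = table.sort_values("p").iloc[0]
        assert {best.node_i, best.node_j} == {"M1_L", "CPost8_R"}
        assert best.r_partial > 0
        assert best.significant
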