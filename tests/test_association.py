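"""Association tests against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

from metapqtl.association import (
    additive_test,
    anova3_test,
    peptide_level_tests,
    qq_points,
    recessive_test,
    scan,
    variance_explained,
)
from metapqtl.errors import CollinearityError, InvalidInputError, UndefinedTestError

from conftest import make_table


def _instance(seed=0, n=12):
    rng = np.random.default_rng(seed)
    allele = rng.integers(0, 3, size=n).astype(float)
    cov = pd.DataFrame(
        {"sex_male": rng.integers(0, 2, n).astype(float),
         "race_caucasian": rng.integers(0, 2, n).astype(float)}
    )
    y = 0.8 * allele + 0.5 * cov["sex_male"].to_numpy() + rng.standard_normal(n)
    return y, allele, cov


def brute_force_ols(y, X):
    """Normal-equations fit with t-test p for each coefficient."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    t = beta / se
    p = 2 * st.t.sf(np.abs(t), dof)
    return beta, se, p


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_additive_matches_normal_equations(seed):
    y, allele, cov = _instance(seed)
    res = additive_test(y, allele, cov)
    X = np.column_stack([np.ones(len(y)), allele, cov.to_numpy()])
    beta, se, p = brute_force_ols(y, X)
    assert res.beta == pytest.approx(beta[1], abs=1e-8)
    assert res.se == pytest.approx(se[1], abs=1e-8)
    assert res.p_value == pytest.approx(p[1], abs=1e-8)


def test_recessive_matches_normal_equations():
    y, allele, cov = _instance(7)
    res = recessive_test(y, allele, cov)
    indicator = (allele < 2).astype(float)
    X = np.column_stack([np.ones(len(y)), indicator, cov.to_numpy()])
    beta, se, p = brute_force_ols(y, X)
    assert res.beta == pytest.approx(beta[1], abs=1e-8)
    assert res.p_value == pytest.approx(p[1], abs=1e-8)


def test_constant_response_gives_null_result():
    allele = np.array([0, 1, 2, 0, 1, 2, 0, 1.0])
    res = additive_test(np.full(8, 3.14), allele)
    assert res.beta == 0.0 and res.p_value == 1.0 and res.r2_genotype == 0.0


def test_additive_equals_recessive_for_binary_genotype():
    rng = np.random.default_rng(3)
    allele = rng.choice([1.0, 2.0], size=30)
    y = rng.standard_normal(30) + allele
    add = additive_test(y, allele)
    rec = recessive_test(y, allele)
    # indicator = 2 - allele here, so slopes are equal and opposite
    assert abs(add.beta) == pytest.approx(abs(rec.beta), abs=1e-10)
    assert add.p_value == pytest.approx(rec.p_value, abs=1e-10)


def test_recessive_no_covariates_equals_pooled_t_test():
    rng = np.random.default_rng(5)
    allele = np.array([2.0] * 10 + [1.0] * 10)
    y = np.concatenate([rng.standard_normal(10) + 1.0, rng.standard_normal(10)])
    res = recessive_test(y, allele)
    t_oracle = st.ttest_ind(y[allele < 2], y[allele == 2], equal_var=True)
    assert res.p_value == pytest.approx(t_oracle.pvalue, abs=1e-12)


def test_all_cc_is_undefined():
    with pytest.raises(UndefinedTestError):
        recessive_test(np.arange(8.0), np.full(8, 2.0))


def test_collinear_covariate_named():
    y, allele, cov = _instance(9)
    cov = cov.assign(dup=allele)  # duplicates the genotype column
    with pytest.raises(CollinearityError, match="dup"):
        additive_test(y, allele, cov)


class TestVarianceExplained:
    def test_exact_linear_function(self):
        allele = np.array([0, 1, 2, 0, 1, 2.0])
        assert variance_explained(2.0 * allele + 1.0, allele) == pytest.approx(1.0)

    def test_six_sample_hand_computation(self):
        allele = np.array([0, 0, 1, 1, 2, 2.0])
        y = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        # hand OLS: slope = Sxy/Sxx, r2 = 1 - SSE/SST
        slope = np.sum((allele - 1) * (y - y.mean())) / np.sum((allele - 1) ** 2)
        fitted = y.mean() + slope * (allele - 1)
        r2_hand = 1 - np.sum((y - fitted) ** 2) / np.sum((y - y.mean()) ** 2)
        assert variance_explained(y, allele) == pytest.approx(r2_hand, abs=1e-12)

    def test_null_r2_vanishes_at_large_n(self):
        rng = np.random.default_rng(11)
        allele = rng.integers(0, 3, 1000).astype(float)
        y = rng.standard_normal(1000)
        assert variance_explained(y, allele) <= 0.05


@given(shift=hst.floats(-50, 50), scale=hst.floats(0.01, 100))
@settings(max_examples=25, deadline=None)
def test_affine_invariance_of_p_and_scaling_of_beta(shift, scale):
    y, allele, cov = _instance(13)
    base = additive_test(y, allele, cov)
    trans = additive_test(scale * y + shift, allele, cov)
    assert trans.p_value == pytest.approx(base.p_value, rel=1e-6)
    assert trans.beta == pytest.approx(scale * base.beta, rel=1e-6)


def test_anova3_reduces_to_f_test():
    y, allele, cov = _instance(17, n=30)
    res = anova3_test(y, allele, cov)
    assert res.model == "anova3" and np.isnan(res.beta)
    assert 0 < res.p_value <= 1


class TestScan:
    def test_single_column_threshold(self):
        rng = np.random.default_rng(19)
        scores = pd.DataFrame({"A": rng.standard_normal(20)})
        allele = rng.integers(0, 3, 20).astype(float)
        result = scan(scores, allele, family_alpha=0.05)
        assert result.bonferroni_alpha == pytest.approx(0.05)
        assert result.n_tests == 1

    def test_failed_column_is_skipped_not_fatal(self):
        rng = np.random.default_rng(23)
        n = 20
        scores = pd.DataFrame(
            {"good": rng.standard_normal(n), "bad": np.full(n, np.nan)}
        )
        allele = rng.integers(0, 3, n).astype(float)
        result = scan(scores, allele)
        assert result.n_tests == 1
        assert result.skipped and result.skipped[0][0] == "bad"

    def test_bonferroni_alpha_scales_with_columns(self, default_sim):
        _, _, cohort, truth = default_sim
        result = scan(truth.protein_scores, cohort.allele_counts, cohort.covariates)
        assert result.n_tests == 10
        assert result.bonferroni_alpha == pytest.approx(0.005)
        assert [r.target_id for r in result.significant] == ["PROT000"]


class TestQQ:
    def test_single_midpoint(self):
        points = qq_points([0.5])
        assert points[0][0] == pytest.approx(np.log10(2), abs=1e-12)
        assert points[0][1] == pytest.approx(np.log10(2), abs=1e-12)

    def test_headline_p_at_k110(self):
        rng = np.random.default_rng(29)
        p = np.concatenate([[9.2e-6], rng.uniform(0.01, 1, 109)])
        points = qq_points(p)
        assert points[0][1] == pytest.approx(-np.log10(9.2e-6), abs=1e-4)
        assert round(points[0][1], 3) == 5.036
        assert points[0][0] == pytest.approx(-np.log10(0.5 / 110), abs=1e-12)

    def test_uniform_p_tracks_identity(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(size=1000)
        points = np.array(qq_points(p))
        # KS-consistency on the original scale
        assert st.kstest(p, "uniform").pvalue > 0.01
        assert np.max(np.abs(points[:, 0] - points[:, 1])[points[:, 0] < 2]) < 0.35

    def test_permutation_invariance_and_domain(self):
        p = np.array([0.9, 0.1, 0.5])
        assert qq_points(p) == qq_points(np.sort(p))
        with pytest.raises(InvalidInputError):
            qq_points([0.0, 0.5])
        with pytest.raises(InvalidInputError):
            qq_points([])


def test_peptide_level_matches_direct_test(default_sim):
    _, table, cohort, _ = default_sim
    members = table.feature_ids[:3]
    result = peptide_level_tests(
        table, members, cohort.allele_counts, cohort.covariates
    )
    assert result.n_tests == 3
    assert result.bonferroni_alpha == pytest.approx(0.05 / 3)
    direct = additive_test(
        table.intensities.loc[members[0]].to_numpy(),
        cohort.allele_counts,
        cohort.covariates,
        target_id=members[0],
    )
    assert result.results[0].beta == pytest.approx(direct.beta, abs=1e-12)
    assert result.results[0].p_value == pytest.approx(direct.p_value, abs=1e-12)


def test_peptide_level_unknown_member_rejected(default_sim):
    _, table, cohort, _ = default_sim
    with pytest.raises(InvalidInputError, match="NOPE"):
        peptide_level_tests(table, ["NOPE"], cohort.allele_counts)
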