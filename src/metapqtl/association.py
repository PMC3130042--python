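"""Genotype association for metaprotein scores and individual peptides.

Association is a covariate-adjusted linear model fit by ordinary least
squares, with the genotype coded either additively (count of C alleles,
0/1/2) or recessively (indicator of the non-CC group, so a negative beta
means TT/TC samples sit lower).  The reported p-value is the two-sided
t-test on the genotype coefficient; a 3-level genotype ANOVA (2-df F test)
is also available.  Scan results carry a Bonferroni threshold over the
number of metaproteins tested, and QQ coordinates are provided for the
usual -log10 p diagnostic against the uniform null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, InvalidInputError, UndefinedTestError
from .tables import IsotopeGroupTable

__all__ = [
    "AssociationResult",
    "ScanResult",
    "additive_test",
    "recessive_test",
    "anova3_test",
    "variance_explained",
    "scan",
    "qq_points",
    "peptide_level_tests",
]


@dataclass
class AssociationResult:
    """One genotype-association test.

    ``beta`` is the effect per C allele (additive) or for the non-CC
    indicator (recessive); ``r2_genotype`` the variance in the target
    explained by the genotype term alone (no covariates), with the
    covariate-adjusted partial R^2 as a secondary field.
    """

    target_id: str
    model: str
    beta: float
    se: float
    p_value: float
    r2_genotype: float
    n_used: int
    covariates: list[str] = field(default_factory=list)
    r2_partial: float = np.nan


@dataclass
class ScanResult:
    """Association results for every score column plus Bonferroni control."""

    results: list[AssociationResult]
    n_tests: int
    bonferroni_alpha: float
    significant: list[AssociationResult]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def sorted_by_p(self) -> list[AssociationResult]:
        return sorted(self.results, key=lambda r: r.p_value)


def _prepare(y, geno_term, covariates):
    y = np.asarray(y, dtype=float)
    geno_term = np.asarray(geno_term, dtype=float)
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        cov_mat = cov.to_numpy(dtype=float)
        cov_names = list(cov.columns)
    else:
        cov_mat = np.empty((len(y), 0))
        cov_names = []
    if not (len(y) == len(geno_term) == cov_mat.shape[0]):
        raise InvalidInputError("y, genotype and covariates have unequal lengths")
    mask = np.isfinite(y) & np.isfinite(geno_term)
    if cov_mat.shape[1]:
        mask &= np.isfinite(cov_mat).all(axis=1)
    return y[mask], geno_term[mask], cov_mat[mask], cov_names


def _check_design(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        offending = []
        for j in range(X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(X):
                offending.append(names[j])
        raise CollinearityError(
            f"rank-deficient design; dependent columns: {offending or names}"
        )


def _linear_test(y, geno_term, covariates, model: str, target_id: str) -> AssociationResult:
    y, g, cov, cov_names = _prepare(y, geno_term, covariates)
    if np.unique(g).size < 2:
        raise UndefinedTestError(f"{target_id}: genotype term is constant in used samples")
    n_params = 2 + cov.shape[1]
    if len(y) <= n_params + 1:
        raise UndefinedTestError(
            f"{target_id}: only {len(y)} usable samples for {n_params} parameters"
        )

    X = np.column_stack([np.ones(len(y)), g, cov])
    names = ["const", "genotype", *cov_names]
    _check_design(X, names)

    if np.ptp(y) == 0.0:  # constant response: no effect, no evidence
        return AssociationResult(
            target_id=target_id,
            model=model,
            beta=0.0,
            se=0.0,
            p_value=1.0,
            r2_genotype=0.0,
            n_used=len(y),
            covariates=cov_names,
            r2_partial=0.0,
        )

    fit = sm.OLS(y, X).fit()
    beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]

    r2_marginal = sm.OLS(y, np.column_stack([np.ones(len(y)), g])).fit().rsquared
    if cov.shape[1]:
        sse_cov = sm.OLS(y, np.column_stack([np.ones(len(y)), cov])).fit().ssr
        r2_partial = (sse_cov - fit.ssr) / sse_cov if sse_cov > 0 else 0.0
    else:
        r2_partial = r2_marginal

    return AssociationResult(
        target_id=target_id,
        model=model,
        beta=float(beta),
        se=float(se),
        p_value=float(p),
        r2_genotype=float(r2_marginal),
        n_used=len(y),
        covariates=cov_names,
        r2_partial=float(r2_partial),
    )


def additive_test(y, allele_count, covariates=None, target_id: str = "score") -> AssociationResult:
    """Linear trend test: y ~ intercept + C-allele count (+ covariates)."""
    return _linear_test(y, allele_count, covariates, "additive", target_id)


def recessive_test(y, allele_count, covariates=None, target_id: str = "score") -> AssociationResult:
    """Recessive contrast: y ~ intercept + 1{non-CC} (+ covariates)."""
    allele_count = np.asarray(allele_count, dtype=float)
    indicator = np.where(np.isfinite(allele_count), (allele_count < 2).astype(float), np.nan)
    return _linear_test(y, indicator, covariates, "recessive", target_id)


def anova3_test(y, allele_count, covariates=None, target_id: str = "score") -> AssociationResult:
    """Genotype as three unordered levels: 2-df F test (one-way ANOVA with covariates)."""
    allele_count = np.asarray(allele_count, dtype=float)
    y, g, cov, cov_names = _prepare(y, allele_count, covariates)
    levels = np.unique(g)
    if levels.size < 2:
        raise UndefinedTestError(f"{target_id}: genotype is constant in used samples")
    dummies = np.column_stack([(g == lv).astype(float) for lv in levels[1:]])
    n_params = 1 + dummies.shape[1] + cov.shape[1]
    if len(y) <= n_params + 1:
        raise UndefinedTestError(f"{target_id}: too few samples for 3-level ANOVA")
    X_full = np.column_stack([np.ones(len(y)), dummies, cov])
    names = ["const", *[f"geno=={lv:g}" for lv in levels[1:]], *cov_names]
    _check_design(X_full, names)
    full = sm.OLS(y, X_full).fit()
    reduced = sm.OLS(y, np.column_stack([np.ones(len(y)), cov])).fit()
    if np.ptp(y) == 0.0:
        f_p = 1.0
    else:
        f_stat, f_p, _ = full.compare_f_test(reduced)
        f_p = float(f_p)
    r2_marginal = (
        0.0
        if np.ptp(y) == 0.0
        else sm.OLS(y, np.column_stack([np.ones(len(y)), dummies])).fit().rsquared
    )
    return AssociationResult(
        target_id=target_id,
        model="anova3",
        beta=np.nan,
        se=np.nan,
        p_value=f_p,
        r2_genotype=float(r2_marginal),
        n_used=len(y),
        covariates=cov_names,
    )


def variance_explained(y, allele_count, model: str = "additive") -> float:
    """R^2 of the target on the genotype term alone (no covariates)."""
    allele_count = np.asarray(allele_count, dtype=float)
    if model == "recessive":
        geno = np.where(np.isfinite(allele_count), (allele_count < 2).astype(float), np.nan)
    elif model == "additive":
        geno = allele_count
    else:
        raise InvalidInputError(f"unknown model {model!r}")
    y, g, _, _ = _prepare(y, geno, None)
    if np.unique(g).size < 2:
        raise UndefinedTestError("genotype term is constant")
    if np.ptp(y) == 0.0:
        return 0.0
    fit = sm.OLS(y, np.column_stack([np.ones(len(y)), g])).fit()
    return float(fit.rsquared)


_TEST_FUNCS = {"additive": additive_test, "recessive": recessive_test, "anova3": anova3_test}


def scan(
    scores: pd.DataFrame,
    allele_count,
    covariates=None,
    model: str = "additive",
    family_alpha: float = 0.05,
) -> ScanResult:
    """Test every score column against genotype with Bonferroni control.

    The Bonferroni threshold is ``family_alpha`` divided by the number of
    tests actually performed; per-column failures are recorded as skipped.
    """
    if model not in _TEST_FUNCS:
        raise InvalidInputError(f"unknown model {model!r}")
    if scores.shape[1] < 1:
        raise InvalidInputError("scores matrix has no columns")
    test = _TEST_FUNCS[model]
    results, skipped = [], []
    for column in scores.columns:
        try:
            results.append(
                test(scores[column].to_numpy(), allele_count, covariates, target_id=str(column))
            )
        except (UndefinedTestError, CollinearityError) as exc:
            skipped.append((str(column), str(exc)))
    if not results:
        raise UndefinedTestError("every column failed: " + "; ".join(m for _, m in skipped))
    n_tests = len(results)
    bonferroni_alpha = family_alpha / n_tests
    significant = [r for r in results if r.p_value <= bonferroni_alpha]
    return ScanResult(
        results=results,
        n_tests=n_tests,
        bonferroni_alpha=bonferroni_alpha,
        significant=sorted(significant, key=lambda r: r.p_value),
        skipped=skipped,
    )


def qq_points(p_values) -> list[tuple[float, float]]:
    """(expected, observed) -log10 p pairs for a QQ plot, largest first.

    Expected quantiles use the midpoint rule: for rank i of K (most extreme
    first), expected_i = -log10((i - 0.5) / K).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InvalidInputError("no p-values given")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in (0, 1]")
    k = p.size
    observed = -np.log10(np.sort(p))
    expected = -np.log10((np.arange(1, k + 1) - 0.5) / k)
    return list(zip(expected.tolist(), observed.tolist()))


def peptide_level_tests(
    table: IsotopeGroupTable,
    member_ids: list[str],
    allele_count,
    covariates=None,
    model: str = "additive",
    family_alpha: float = 0.05,
) -> ScanResult:
    """Apply the genotype test to each member peptide's intensity vector.

    The Bonferroni threshold is taken over the member count, mirroring the
    component-peptide analysis of a significant metaprotein.
    """
    missing = [fid for fid in member_ids if fid not in table.features.index]
    if missing:
        raise InvalidInputError(f"member features not in table: {missing}")
    intensities = table.intensities.loc[member_ids].T
    return scan(intensities, allele_count, covariates, model=model, family_alpha=family_alpha)
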