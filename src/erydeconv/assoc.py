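"""Cohort genetic association and fixed-effect meta-analysis.

Per cohort, the binary outcome (three or more severe pain episodes requiring
emergency care or hospitalization in 12 months) is regressed on allele dosage
with covariates age, sex, alpha-thalassemia deletion copies, and optional
population-stratification PCs, by maximum-likelihood logistic regression; the
dosage coefficient is reported as a log odds ratio with its Wald standard
error and p-value.  Cohort estimates are pooled with the fixed-effect
inverse-variance method; the pooled p-value can be flagged against a
Bonferroni threshold for the number of SNPs tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import CohortTable
from .stats import EffectEstimate, ci_to_effect, inverse_variance_pool

__all__ = ["AssociationResult", "SeparationError", "logistic_fit", "meta_analyze",
           "result_from_summary"]


class SeparationError(RuntimeError):
    """Raised when the dosage coefficient diverges (perfect separation)."""


@dataclass
class AssociationResult:
    """One cohort's (or the pooled) dosage association."""

    cohort: str
    effect: EffectEstimate  # log-OR with Wald SE

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.effect.estimate)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        lo, hi = self.effect.ci(level)
        return (math.exp(lo), math.exp(hi))

    @property
    def p(self) -> float:
        return self.effect.p

    @property
    def n(self) -> int:
        return self.effect.n


def result_from_summary(cohort: str, odds_ratio: float, ci_low: float,
                        ci_high: float, n: int) -> AssociationResult:
    """Build a result from published summary cells (OR with 95% CI).

    The SE is back-derived as (ln U - ln L) / (2 * 1.96).
    """
    return AssociationResult(cohort=cohort,
                             effect=ci_to_effect(odds_ratio, ci_low, ci_high, n=n))


def logistic_fit(cohort: CohortTable, covariates=("age", "sex", "alpha_thal_copies"),
                 beta_max: float = 10.0) -> AssociationResult:
    """Maximum-likelihood logistic regression of outcome on dosage plus covariates.

    Wald SE and p-value for the dosage coefficient.  Raises SeparationError
    when the fit diverges (|log-OR| > ``beta_max`` or non-convergence), and
    ValueError when only one outcome class is present.
    """
    tab = cohort.table
    y = tab["outcome"].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"cohort {cohort.name}: outcome has a single class")
    cols = ["dosage"] + [c for c in covariates if c in tab.columns]
    X = sm.add_constant(tab[cols].to_numpy(float))
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        raise SeparationError(f"cohort {cohort.name}: logistic fit failed ({exc})")
    beta = fit.params[1]
    se = fit.bse[1]
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > beta_max:
        raise SeparationError(
            f"cohort {cohort.name}: dosage coefficient diverged (|beta|={abs(beta):.2f})")
    return AssociationResult(cohort=cohort.name,
                             effect=EffectEstimate(float(beta), float(se), n=cohort.n))


def meta_analyze(results, bonferroni_m: int = 1,
                 alpha: float = 0.05) -> tuple[AssociationResult, bool]:
    """Fixed-effect inverse-variance pooling of cohort log-OR estimates.

    Returns the pooled result (cohort name "Combined") and a flag indicating
    whether the pooled p-value survives Bonferroni correction for
    ``bonferroni_m`` tests.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one cohort result")
    if bonferroni_m < 1:
        raise ValueError("bonferroni_m must be >= 1")
    pooled, _, p = inverse_variance_pool([r.effect for r in results])
    flag = (p * bonferroni_m) < alpha
    return AssociationResult(cohort="Combined", effect=pooled), bool(flag)


def association_table(results, pooled: AssociationResult | None = None) -> pd.DataFrame:
    """Cohort-per-row summary table (OR, 95% CI, Wald p, n)."""
    rows = list(results) + ([pooled] if pooled is not None else [])
    return pd.DataFrame(
        [{"cohort": r.cohort, "or": r.odds_ratio, "ci_low": r.ci()[0],
          "ci_high": r.ci()[1], "p": r.p, "n": r.n} for r in rows]
    ).set_index("cohort")
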