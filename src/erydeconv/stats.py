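"""Shared statistical primitives.

Self-contained building blocks used throughout the pipeline: Benjamini–Hochberg
FDR control, Fisher's exact test on 2x2 tables, the Cochran–Armitage test for
trend in proportions, the exact test of Hardy–Weinberg equilibrium, quantile
normalization, empirical-Bayes batch adjustment, and fixed-effect
inverse-variance pooling of effect estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "ContingencyTable2x2",
    "EffectEstimate",
    "bh_fdr",
    "fisher_exact",
    "trend_in_proportions",
    "hwe_exact",
    "quantile_normalize",
    "batch_adjust",
    "inverse_variance_pool",
    "ci_to_effect",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 contingency table laid out as [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("table entries must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have at least one non-zero margin")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class EffectEstimate:
    """A log-scale effect estimate with its standard error.

    The universal currency for Wald tests and inverse-variance meta-analysis.
    ``estimate`` is on the log scale for ratio measures (log odds ratio,
    log fold change); ``se`` must be positive.
    """

    estimate: float
    se: float
    n: int = 0

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError(f"se must be positive, got {self.se}")

    @property
    def z(self) -> float:
        return self.estimate / self.se

    @property
    def p(self) -> float:
        return 2.0 * scipy.stats.norm.sf(abs(self.z))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        zq = scipy.stats.norm.ppf(0.5 + level / 2.0)
        return (self.estimate - zq * self.se, self.estimate + zq * self.se)


def ci_to_effect(estimate_ratio: float, ci_low: float, ci_high: float,
                 n: int = 0, z: float = 1.96) -> EffectEstimate:
    """Back-transform a ratio estimate with a 95% CI into (log estimate, SE).

    Uses se = (ln(upper) - ln(lower)) / (2 z) with z = 1.96 exactly, the
    standard reconstruction for published odds ratios.
    """
    if not (0 < ci_low <= estimate_ratio <= ci_high):
        raise ValueError("CI must bracket the estimate and be positive")
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)
    return EffectEstimate(estimate=math.log(estimate_ratio), se=se, n=n)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.  NaN entries are
    propagated and excluded from the number of tests m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return q
    order = np.argsort(ps, kind="mergesort")
    scaled = ps[order] * m / np.arange(1, m + 1)
    stepup = np.minimum.accumulate(scaled[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(stepup, 1.0)
    q[ok] = qs
    return q


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns the sample odds ratio (a d)/(b c) and the two-sided p-value from
    summing hypergeometric tables (same margins) whose probability does not
    exceed that of the observed table.  Extreme tables give OR 0 or inf; a
    degenerate margin (an all-zero row or column) returns (nan, 1.0).
    """
    t = table.as_array()
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return (float("nan"), 1.0)
    a, b, c, d = table.a, table.b, table.c, table.d
    if b == 0 or c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    _, p = scipy.stats.fisher_exact(t, alternative="two-sided")
    return (float(odds), float(min(p, 1.0)))


def trend_in_proportions(successes, totals, scores=None) -> tuple[float, float]:
    """Cochran–Armitage-style chi-square test for trend in proportions.

    Weighted least-squares slope of the group proportions on the scores, on
    1 df; matches R's ``prop.trend.test``.  Scores default to 1..k.
    """
    x = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 groups")
    if np.any(n <= 0):
        raise ValueError("group totals must be positive")
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("successes must lie in [0, total] per group")
    s = np.arange(1, x.size + 1, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    if np.any(np.diff(s) == 0):
        raise ValueError("scores must be distinct")
    N = n.sum()
    pbar = x.sum() / N
    if pbar in (0.0, 1.0):
        warnings.warn("all proportions are 0 or 1; trend statistic is 0")
        return (0.0, 1.0)
    num = (np.sum(x * s) - pbar * np.sum(n * s)) ** 2
    den = pbar * (1 - pbar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / N)
    chi2 = num / den
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return (float(chi2), p)


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact test of Hardy–Weinberg equilibrium.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts (same parity) whose probability does not exceed that
    of the observed configuration.  Monomorphic sites return p = 1.
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0 or int(v) != v:
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # rare allele count
    if n_rare == 0:
        return 1.0
    # probabilities over het counts h with h ≡ n_rare (mod 2), via recurrence
    h_vals = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.zeros(h_vals.size)
    # start at mid het count and recurse both directions for stability
    mid = n_rare * (2 * n - n_rare) / (2 * n - 1)
    start = int(h_vals[np.argmin(np.abs(h_vals - mid))])
    idx0 = int(np.searchsorted(h_vals, start))
    probs[idx0] = 1.0
    # recurrence ratios of P(h) ∝ 2^h / (n_hom_rare! h! n_hom_com!)
    for i in range(idx0, probs.size - 1):
        h = h_vals[i]
        n_hom_rare = (n_rare - h) // 2
        n_hom_com = n - h - n_hom_rare
        probs[i + 1] = probs[i] * 4.0 * n_hom_rare * n_hom_com / ((h + 2.0) * (h + 1.0))
    for i in range(idx0, 0, -1):
        h = h_vals[i]
        n_hom_rare = (n_rare - h) // 2
        n_hom_com = n - h - n_hom_rare
        probs[i - 1] = probs[i] * h * (h - 1.0) / (4.0 * (n_hom_rare + 1.0) * (n_hom_com + 1.0))
    probs /= probs.sum()
    p_obs = probs[int(np.searchsorted(h_vals, n_Aa))]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def quantile_normalize(matrix) -> np.ndarray:
    """Quantile-normalize columns so every column has the same distribution.

    Each column's sorted values are replaced by the across-column means of the
    sorted values.  Ties are resolved by stable ordinal ranks, which makes the
    operation exactly idempotent.  Accepts an array or DataFrame (values are
    genes x samples with samples in columns); returns the same type.
    """
    is_df = hasattr(matrix, "values") and hasattr(matrix, "index")
    X = np.asarray(matrix, dtype=float) if not is_df else matrix.values.astype(float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples (columns)")
    order = np.argsort(X, axis=0, kind="mergesort")
    ref = np.mean(np.sort(X, axis=0), axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[order[:, j], j] = ref
    if is_df:
        import pandas as pd

        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def _eb_iterate(ghat, dhat, g_bar, t2, a_prior, b_prior, n_b, tol=1e-5, max_iter=200):
    # standard parametric ComBat iterative solution for one batch
    g_new, d_new = ghat.copy(), dhat.copy()
    sum_sq = dhat * (n_b - 1)
    for _ in range(max_iter):
        g_old, d_old = g_new.copy(), d_new.copy()
        g_new = (t2 * n_b * ghat + d_new * g_bar) / (t2 * n_b + d_new)
        resid_sq = sum_sq + n_b * (ghat - g_new) ** 2
        d_new = (resid_sq / 2.0 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
        change = max(np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)),
                     np.max(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-12)))
        if change < tol:
            break
    return g_new, d_new


def batch_adjust(matrix, batches, mode: str = "mean-variance"):
    """Empirical-Bayes batch adjustment (parametric ComBat-style).

    Per-batch gene locations (and scales in ``mean-variance`` mode) are shrunk
    toward pooled priors estimated across genes, then batches are standardized
    to the pooled model.  A single batch returns the input unchanged.

    Parameters
    ----------
    matrix : genes x samples array or DataFrame of continuous values.
    batches : per-sample batch labels.
    mode : ``"mean-only"`` adjusts locations only; ``"mean-variance"``
        additionally shrinks and removes per-batch scale differences.
    """
    if mode not in ("mean-only", "mean-variance"):
        raise ValueError("mode must be 'mean-only' or 'mean-variance'")
    is_df = hasattr(matrix, "values") and hasattr(matrix, "index")
    X = matrix.values.astype(float) if is_df else np.asarray(matrix, dtype=float)
    batches = np.asarray(batches)
    if batches.size != X.shape[1]:
        raise ValueError("one batch label per sample (column) required")
    labels = [b for b in dict.fromkeys(batches)]
    if len(labels) < 2:
        return matrix
    groups = [np.flatnonzero(batches == b) for b in labels]
    n_bs = np.array([g.size for g in groups], dtype=float)
    if mode == "mean-variance" and np.any(n_bs < 2):
        raise ValueError("each batch needs >= 2 samples for mean-variance mode")
    N = X.shape[1]

    batch_means = np.column_stack([X[:, g].mean(axis=1) for g in groups])
    grand = batch_means @ (n_bs / N)  # weighted grand mean per gene
    # pooled variance of residuals about batch means
    pooled_var = np.zeros(X.shape[0])
    for i, g in enumerate(groups):
        pooled_var += ((X[:, g] - batch_means[:, [i]]) ** 2).sum(axis=1)
    pooled_var /= N
    pooled_var = np.maximum(pooled_var, 1e-12)
    sd = np.sqrt(pooled_var)

    Z = (X - grand[:, None]) / sd[:, None]
    out = np.empty_like(Z)
    for i, g in enumerate(groups):
        zb = Z[:, g]
        ghat = zb.mean(axis=1)
        g_bar, t2 = ghat.mean(), max(ghat.var(ddof=1), 1e-12)
        if mode == "mean-only" or g.size < 2:
            gstar = (t2 * g.size * ghat + 1.0 * g_bar) / (t2 * g.size + 1.0)
            dstar = np.ones_like(ghat)
        else:
            dhat = zb.var(axis=1, ddof=1)
            m, v = dhat.mean(), max(dhat.var(ddof=1), 1e-12)
            a_prior = (2.0 * v + m**2) / v
            b_prior = (m * v + m**3) / v
            gstar, dstar = _eb_iterate(ghat, dhat, g_bar, t2, a_prior, b_prior, g.size)
            dstar = np.maximum(dstar, 1e-12)
        out[:, g] = (zb - gstar[:, None]) / np.sqrt(dstar)[:, None]
    out = out * sd[:, None] + grand[:, None]
    if is_df:
        import pandas as pd

        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def inverse_variance_pool(estimates) -> tuple[EffectEstimate, float, float]:
    """Fixed-effect inverse-variance pooling of effect estimates.

    Returns (pooled EffectEstimate, z, two-sided normal p).  Weights are
    1/se^2; the pooled SE is 1/sqrt(sum of weights).
    """
    ests = list(estimates)
    if not ests:
        raise ValueError("need at least one estimate")
    w = np.array([1.0 / e.se**2 for e in ests])
    b = np.array([e.estimate for e in ests])
    pooled_est = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    n = int(sum(e.n for e in ests))
    pooled = EffectEstimate(estimate=pooled_est, se=pooled_se, n=n)
    return pooled, pooled.z, pooled.p
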