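"""Erythroid-signature deconvolution of PBMC expression.

PBMCs contain a minority erythroid-progenitor component that is elevated in
sickle cell anemia.  The per-sample abundance of that component is
approximated by the first principal component of a 16-gene erythroid marker
panel; erythroid-specific expression of a gene is then read off the
gene x phenotype interaction in the linear model

    y = u + x_ery b_ery + x_pheno b_pheno + x_hemo b_hemo
        + (x_ery * x_pheno) b_int + (x_ery * x_hemo) b_int_hemo + eps

where x_pheno is hemoglobin (or hematocrit) coded in quartiles and x_hemo is
the square-root of percent reticulocytes (a hemolysis proxy).  A significant
interaction means the gene's association with the erythroid signature grows
with the phenotype, i.e. its erythroid expression tracks erythropoiesis
efficiency.  Fits are stratified by hydroxyurea treatment, restricted to
non-transfused patients, and pooled per gene by inverse variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import ExpressionMatrix, Phenotypes
from .stats import EffectEstimate, bh_fdr, inverse_variance_pool

__all__ = [
    "ErythroidSignature",
    "quartile_code",
    "erythroid_signature",
    "select_deconvolvable_genes",
    "fit_interaction",
    "fit_interaction_all",
    "pool_strata",
    "call_consistent_genes",
]


@dataclass
class ErythroidSignature:
    """Per-sample erythroid-progenitor score from the marker-gene PC1.

    Scores have zero mean and unit variance; the sign convention makes the
    mean marker loading positive, so higher score means more erythroid
    progenitors.
    """

    scores: pd.Series
    marker_ids: list
    loadings: pd.Series
    explained_variance_share: float


def quartile_code(values, reference=None) -> np.ndarray:
    """Code values into quartile indices 0-3.

    Cuts are the 25/50/75% sample quantiles of ``reference`` (defaults to
    ``values``); a value equal to a cut is assigned to the lower quartile.
    """
    v = np.asarray(values, dtype=float)
    ref = v if reference is None else np.asarray(reference, dtype=float)
    ref = ref[~np.isnan(ref)]
    if ref.size == 0:
        raise ValueError("no non-missing values to define quartiles")
    cuts = np.quantile(ref, [0.25, 0.5, 0.75])
    return np.searchsorted(cuts, v, side="left").astype(int)


def erythroid_signature(expr: ExpressionMatrix, marker_ids) -> ErythroidSignature:
    """First principal component of the marker-gene submatrix, sample-scored.

    Markers are centered per gene; samples are scored on PC1, standardized to
    zero mean and unit variance, and oriented so the mean loading is positive.
    Markers absent from the expression matrix are dropped (at least 2 must
    remain; at least 3 samples required).
    """
    present = [m for m in marker_ids if m in expr.values.index]
    if len(present) < 2:
        raise ValueError("need at least 2 marker genes present in the expression matrix")
    if expr.values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sub = expr.values.loc[present].to_numpy(float)  # markers x samples
    centered = sub - sub.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValueError("marker submatrix has zero variance")
    # SVD on samples x markers
    U, S, Vt = np.linalg.svd(centered.T, full_matrices=False)
    loadings = Vt[0]
    scores = centered.T @ loadings
    if loadings.mean() < 0:
        loadings, scores = -loadings, -scores
    sd = scores.std()
    if sd == 0:
        raise ValueError("degenerate marker submatrix: constant PC1 scores")
    scores = (scores - scores.mean()) / sd
    share = float(S[0] ** 2 / np.sum(S**2))
    return ErythroidSignature(
        scores=pd.Series(scores, index=expr.values.columns, name="ery_score"),
        marker_ids=present,
        loadings=pd.Series(loadings, index=present, name="loading"),
        explained_variance_share=share,
    )


def _ols_scan(X: np.ndarray, Y: np.ndarray, test_col: int):
    """OLS of every row of Y on the common design X; F test of one coefficient.

    Returns (beta, se, F, p) arrays over rows of Y.  With a single tested
    coefficient the F statistic is the squared t statistic on
    (1, n - p) degrees of freedom.
    """
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough samples for the design")
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T
    B = Y @ H.T  # genes x p
    resid = Y - B @ X.T
    dof = n - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(sigma2, 0.0)[:, None] * np.diag(XtX_inv)[None, :])
    beta = B[:, test_col]
    se_t = se[:, test_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (beta / se_t) ** 2
    pval = scipy.stats.f.sf(F, 1, dof)
    return B, se, F, pval, dof


def select_deconvolvable_genes(expr: ExpressionMatrix, signature: ErythroidSignature,
                               candidate_ids, fdr_q: float = 0.05) -> list:
    """Genes whose PBMC expression tracks the erythroid signature.

    Per-gene regression of expression on the signature score; keeps candidates
    with a positive slope and BH q < ``fdr_q`` within the candidate set.
    """
    candidates = [g for g in candidate_ids]
    if not candidates:
        raise ValueError("empty candidate set")
    missing = [g for g in candidates if g not in expr.values.index]
    if missing:
        raise ValueError(f"candidates absent from expression matrix: {missing[:5]}")
    Y = expr.values.loc[candidates].to_numpy(float)
    x = signature.scores.reindex(expr.values.columns).to_numpy(float)
    X = np.column_stack([np.ones_like(x), x])
    B, se, F, p, _ = _ols_scan(X, Y, test_col=1)
    q = bh_fdr(p)
    keep = (B[:, 1] > 0) & (q < fdr_q)
    return [g for g, k in zip(candidates, keep) if k]


@dataclass
class DeconvolutionFit:
    """Per-gene, per-stratum interaction-model fit."""

    gene_id: str
    stratum: object
    phenotype: str
    beta_ery: float
    beta_pheno: float
    beta_hemo: float
    beta_int: float
    se_int: float
    beta_int_hemo: float
    f_int: float
    p_int: float
    n: int
    q_int: float = np.nan
    ok: bool = True


def _stratum_design(signature_scores, pheno_sub: pd.DataFrame, phenotype: str):
    q = quartile_code(pheno_sub[phenotype].to_numpy(float))
    hemo = np.sqrt(pheno_sub["retic_pct"].to_numpy(float))
    ery = signature_scores.reindex(pheno_sub.index).to_numpy(float)
    X = np.column_stack([np.ones(len(q)), ery, q, hemo, ery * q, ery * hemo])
    return X


def fit_interaction(expr_row, signature: ErythroidSignature, phenotypes: Phenotypes,
                    phenotype: str = "hgb", stratum: int | None = None,
                    min_samples: int = 10) -> DeconvolutionFit:
    """Fit the deconvolution interaction model for one gene in one stratum.

    OLS of the full model; the erythroid x phenotype interaction is tested by
    an F test (1 numerator df, equal to the squared t test of that
    coefficient).  Samples flagged as transfused are excluded before fitting.
    """
    if phenotype not in ("hgb", "hct"):
        raise ValueError("phenotype must be 'hgb' or 'hct'")
    tab = phenotypes.table
    keep = tab["transfused"] == 0
    if stratum is not None:
        keep &= tab["hydroxyurea"] == stratum
    sub = tab.loc[keep]
    if len(sub) < min_samples:
        raise ValueError(f"stratum has {len(sub)} samples (< {min_samples})")
    if np.unique(quartile_code(sub[phenotype].to_numpy(float))).size < 2:
        raise ValueError("phenotype quartiles are constant in this stratum")
    y = pd.Series(expr_row).reindex(sub.index).to_numpy(float)[None, :]
    X = _stratum_design(signature.scores, sub, phenotype)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return DeconvolutionFit(gene_id=str(getattr(expr_row, "name", "?")),
                                stratum=stratum, phenotype=phenotype,
                                beta_ery=np.nan, beta_pheno=np.nan, beta_hemo=np.nan,
                                beta_int=np.nan, se_int=np.nan, beta_int_hemo=np.nan,
                                f_int=np.nan, p_int=np.nan, n=len(sub), ok=False)
    B, se, F, p, _ = _ols_scan(X, y, test_col=4)
    return DeconvolutionFit(
        gene_id=str(getattr(expr_row, "name", "?")), stratum=stratum,
        phenotype=phenotype,
        beta_ery=float(B[0, 1]), beta_pheno=float(B[0, 2]), beta_hemo=float(B[0, 3]),
        beta_int=float(B[0, 4]), se_int=float(se[0, 4]), beta_int_hemo=float(B[0, 5]),
        f_int=float(F[0]), p_int=float(p[0]), n=len(sub),
    )


def fit_interaction_all(expr: ExpressionMatrix, signature: ErythroidSignature,
                        phenotypes: Phenotypes, gene_ids=None,
                        phenotype: str = "hgb", stratify: bool = True,
                        min_samples: int = 10) -> pd.DataFrame:
    """Vectorized interaction fits for many genes, one row per gene x stratum.

    Returns a DataFrame with columns gene_id, stratum, phenotype, beta_int,
    se_int, f_int, p_int, n (all genes share the stratum design, so the scan
    is a single matrix solve per stratum).
    """
    genes = list(gene_ids) if gene_ids is not None else list(expr.values.index)
    tab = phenotypes.table
    strata = [0, 1] if stratify else [None]
    rows = []
    for s in strata:
        keep = tab["transfused"] == 0
        if s is not None:
            keep &= tab["hydroxyurea"] == s
        sub = tab.loc[keep]
        if len(sub) < min_samples:
            continue
        X = _stratum_design(signature.scores, sub, phenotype)
        Y = expr.values.loc[genes, sub.index].to_numpy(float)
        B, se, F, p, _ = _ols_scan(X, Y, test_col=4)
        rows.append(pd.DataFrame({
            "gene_id": genes, "stratum": s, "phenotype": phenotype,
            "beta_ery": B[:, 1], "beta_pheno": B[:, 2], "beta_hemo": B[:, 3],
            "beta_int": B[:, 4], "se_int": se[:, 4], "beta_int_hemo": B[:, 5],
            "f_int": F, "p_int": p, "n": len(sub),
        }))
    if not rows:
        raise ValueError("no stratum had enough samples to fit")
    return pd.concat(rows, ignore_index=True)


def pool_strata(fits: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance pooling of per-stratum interaction estimates per gene.

    Returns one row per gene with pooled beta_int, se_int, z, p_int and BH
    q_int across the pooled gene set.
    """
    recs = []
    for gene, grp in fits.groupby("gene_id", sort=False):
        ok = grp.dropna(subset=["beta_int", "se_int"])
        ok = ok[ok["se_int"] > 0]
        if ok.empty:
            recs.append((gene, np.nan, np.nan, np.nan, np.nan, 0))
            continue
        ests = [EffectEstimate(b, s, int(n)) for b, s, n in
                zip(ok["beta_int"], ok["se_int"], ok["n"])]
        pooled, z, p = inverse_variance_pool(ests)
        recs.append((gene, pooled.estimate, pooled.se, z, p, pooled.n))
    out = pd.DataFrame(recs, columns=["gene_id", "beta_int", "se_int", "z", "p_int", "n"])
    out["q_int"] = bh_fdr(out["p_int"].to_numpy())
    return out


def call_consistent_genes(fits_hgb: pd.DataFrame, fits_hct: pd.DataFrame,
                          fdr_q: float = 0.05) -> list:
    """Genes whose erythroid expression tracks both hemoglobin and hematocrit.

    Per-stratum fits are pooled by inverse variance; a gene is called iff the
    pooled interaction is significant at BH q < ``fdr_q`` for BOTH phenotypes
    and the pooled interaction signs agree.
    """
    pooled_hgb = pool_strata(fits_hgb).set_index("gene_id")
    pooled_hct = pool_strata(fits_hct).set_index("gene_id")
    common = pooled_hgb.index.intersection(pooled_hct.index)
    calls = []
    for g in common:
        a, b = pooled_hgb.loc[g], pooled_hct.loc[g]
        if (a["q_int"] < fdr_q and b["q_int"] < fdr_q
                and np.sign(a["beta_int"]) == np.sign(b["beta_int"])
                and np.sign(a["beta_int"]) != 0):
            calls.append(g)
    return calls
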