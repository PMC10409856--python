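"""Genotype QC and erythroid eQTL mapping.

An "erythroid eQTL" is a SNP whose allele dosage modifies the association
between a gene's PBMC expression and the erythroid-progenitor signature, i.e.
the dosage x signature interaction in

    y = u + x_ery b_ery + x_dose b_dose + (x_ery * x_dose) b_int
        + x_sv b_sv + eps

localizes the genetic effect to the erythroid component of the mixture.  Local
SNPs are those less than 100 kb from either gene end (strict inequality;
distance 0 inside the gene body).  Surrogate variables capture residual
expression structure after known covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import ExpressionMatrix, GeneCoords, GenotypeMatrix
from .stats import bh_fdr, hwe_exact

__all__ = [
    "QcThresholds",
    "qc_filter",
    "local_snps",
    "surrogate_variables",
    "genotype_pcs",
    "eqtl_scan",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    """Genotype QC thresholds (study defaults)."""

    call_rate_min: float = 0.95
    hwe_p: float = 1e-4
    maf_min: float = 0.01
    eqtl_maf_min: float = 0.1
    eqtl_r2_min: float = 0.9


def _snp_stats(dosages: pd.DataFrame) -> pd.DataFrame:
    stats = []
    for snp in dosages.index:
        d = dosages.loc[snp]
        n_miss = int(d.isna().sum())
        call_rate = 1.0 - n_miss / len(d)
        obs = d.dropna()
        if obs.empty:
            stats.append((call_rate, np.nan, np.nan))
            continue
        af = float(obs.mean() / 2.0)
        maf = min(af, 1.0 - af)
        hard = obs.round().astype(int)
        p_hwe = hwe_exact(int((hard == 0).sum()), int((hard == 1).sum()),
                          int((hard == 2).sum()))
        stats.append((call_rate, maf, p_hwe))
    return pd.DataFrame(stats, columns=["call_rate", "maf", "hwe_p"], index=dosages.index)


def qc_filter(genos: GenotypeMatrix, thresholds: QcThresholds = QcThresholds(),
              eqtl_stage: bool = False) -> GenotypeMatrix:
    """Sample and SNP quality control.

    Samples with genotype call rate below the threshold are dropped first;
    then SNPs failing the Hardy–Weinberg exact test (p < 1e-4) or with
    MAF < 0.01 are removed.  For the eQTL stage, SNPs must additionally have
    MAF > 0.1 and imputation r^2 > 0.9.  Remaining missing dosages are imputed
    to the SNP mean.  Idempotent.
    """
    d = genos.dosages
    sample_rate = 1.0 - d.isna().sum(axis=0) / len(d)
    keep_samples = sample_rate >= thresholds.call_rate_min
    n_dropped = int((~keep_samples).sum())
    if n_dropped:
        log.info("qc_filter: dropped %d samples below call rate %.2f",
                 n_dropped, thresholds.call_rate_min)
    d = d.loc[:, keep_samples]

    stats = _snp_stats(d)
    keep = (stats["hwe_p"] >= thresholds.hwe_p) & (stats["maf"] >= thresholds.maf_min)
    if eqtl_stage:
        keep &= stats["maf"] > thresholds.eqtl_maf_min
        if "imputation_r2" in genos.info.columns:
            keep &= genos.info["imputation_r2"] > thresholds.eqtl_r2_min
    keep &= keep.notna() & stats["maf"].notna()
    log.info("qc_filter: removed %d of %d SNPs", int((~keep).sum()), len(keep))
    if not keep.any():
        raise ValueError("all SNPs removed by QC")
    d = d.loc[keep]
    d = d.apply(lambda row: row.fillna(row.mean()), axis=1)
    info = genos.info.loc[keep].copy()
    info["call_rate"] = stats.loc[keep, "call_rate"]
    info["maf"] = stats.loc[keep, "maf"]
    info["hwe_p"] = stats.loc[keep, "hwe_p"]
    return GenotypeMatrix(dosages=d, info=info)


def local_snps(gene, genos: GenotypeMatrix, window_bp: int = 100_000) -> pd.DataFrame:
    """SNPs inside the gene body or strictly less than ``window_bp`` from a gene end.

    ``gene`` is a row of a GeneCoords table (0-based half-open start/end); SNP
    positions are 1-based.  Distance is 0 inside the body, otherwise the
    distance to the nearer gene end; strand is ignored.  Returns a DataFrame
    of snp_id, distance_bp (possibly empty).
    """
    chrom, start, end = gene["chrom"], int(gene["start"]), int(gene["end"])
    info = genos.info
    on_chrom = info[info["chrom"] == chrom]
    pos = on_chrom["pos"].to_numpy(int)
    first_base = start + 1  # 1-based first base of the body
    dist = np.where(pos < first_base, first_base - pos,
                    np.where(pos > end, pos - end, 0))
    keep = dist < window_bp
    return pd.DataFrame({"snp_id": on_chrom.index[keep], "distance_bp": dist[keep]}
                        ).set_index("snp_id")


def _residualize(Y: np.ndarray, C: np.ndarray) -> np.ndarray:
    B, *_ = np.linalg.lstsq(C, Y.T, rcond=None)
    return Y - (C @ B).T


def surrogate_variables(expr: ExpressionMatrix, known_covariates=None,
                        k: int | str = "auto", n_perm: int = 20,
                        quantile: float = 0.95, seed: int = 0) -> pd.DataFrame:
    """Surrogate variables: top left singular vectors of residual expression.

    Expression is residualized on the known covariates (plus an intercept);
    the SVs are the leading right-singular sample vectors of the residual
    matrix.  ``k='auto'`` keeps components whose singular values exceed the
    ``quantile`` of the matched permuted spectra (rows permuted independently,
    Buja–Eyuboglu style), stopping at the first failure.
    """
    Y = expr.values.to_numpy(float)
    n = Y.shape[1]
    C = np.ones((n, 1))
    if known_covariates is not None:
        kc = np.asarray(known_covariates, dtype=float)
        if kc.ndim == 1:
            kc = kc[:, None]
        C = np.column_stack([C, kc])
    if isinstance(k, int) and k >= n:
        raise ValueError("k must be smaller than the number of samples")
    R = _residualize(Y, C)
    max_k = min(n - C.shape[1] - 1, Y.shape[0])
    if max_k < 1:
        raise ValueError("not enough samples for surrogate variables")
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    if k == "auto":
        rng = np.random.default_rng(seed)
        perm_S = np.empty((n_perm, S.size))
        for i in range(n_perm):
            P = np.array([rng.permutation(row) for row in R])
            P = _residualize(P, C)
            perm_S[i] = np.linalg.svd(P, compute_uv=False)
        thresh = np.quantile(perm_S, quantile, axis=0)
        k_eff = 0
        for i in range(min(max_k, S.size)):
            if S[i] > thresh[i]:
                k_eff += 1
            else:
                break
    else:
        k_eff = int(k)
    cols = [f"sv{i + 1}" for i in range(k_eff)]
    return pd.DataFrame(Vt[:k_eff].T, index=expr.values.columns, columns=cols)


def genotype_pcs(genos: GenotypeMatrix, n_pcs: int = 2) -> pd.DataFrame:
    """Top principal components of the centered dosage matrix (samples scored)."""
    D = genos.dosages.to_numpy(float)
    D = np.where(np.isnan(D), np.nanmean(D, axis=1, keepdims=True), D)
    centered = (D - D.mean(axis=1, keepdims=True)).T  # samples x snps
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    scores = U[:, :n_pcs] * S[:n_pcs]
    return pd.DataFrame(scores, index=genos.sample_ids,
                        columns=[f"pc{i + 1}" for i in range(n_pcs)])


def eqtl_scan(expr: ExpressionMatrix, signature: pd.Series, genos: GenotypeMatrix,
              coords: GeneCoords, svs: pd.DataFrame | None = None,
              window_bp: int = 100_000, fdr_q: float = 0.05,
              keep_all: bool = False) -> pd.DataFrame:
    """Erythroid eQTL scan over every gene x local-SNP pair.

    Per pair, OLS of the interaction model; the signature x dosage interaction
    is tested by an F test (1 numerator df); BH correction is applied across
    all tested pairs study-wide.  Monomorphic SNPs within the analysis samples
    are skipped.  Returns pairs at q < ``fdr_q`` (or all pairs when
    ``keep_all``), with the interaction coefficient reported per copy of the
    VCF alternate allele.
    """
    samples = expr.values.columns
    if not set(samples) <= set(genos.sample_ids):
        raise ValueError("expression samples missing from genotype matrix")
    ery = signature.reindex(samples).to_numpy(float)
    if np.isnan(ery).any():
        raise ValueError("signature scores missing for some samples")
    sv_arr = None
    if svs is not None and svs.shape[1] > 0:
        sv_arr = svs.reindex(samples).to_numpy(float)
    recs = []
    for gene, grec in coords.table.iterrows():
        if gene not in expr.values.index:
            continue
        y = expr.values.loc[gene].to_numpy(float)
        near = local_snps(grec, genos, window_bp=window_bp)
        for snp, srec in near.iterrows():
            dose = genos.dosages.loc[snp, samples].to_numpy(float)
            if np.nanstd(dose) == 0:
                log.info("eqtl_scan: %s monomorphic in analysis samples; skipped", snp)
                continue
            parts = [np.ones_like(y), ery, dose, ery * dose]
            if sv_arr is not None:
                parts.append(sv_arr)
            X = np.column_stack(parts)
            n, p = X.shape
            XtX = X.T @ X
            try:
                XtX_inv = np.linalg.inv(XtX)
            except np.linalg.LinAlgError:
                continue
            beta = XtX_inv @ (X.T @ y)
            resid = y - X @ beta
            dof = n - p
            if dof < 1:
                raise ValueError("not enough samples for the eQTL design")
            sigma2 = resid @ resid / dof
            se = np.sqrt(sigma2 * np.diag(XtX_inv))
            with np.errstate(divide="ignore", invalid="ignore"):
                f_int = (beta[3] / se[3]) ** 2
            p_int = float(scipy.stats.f.sf(f_int, 1, dof))
            recs.append((gene, snp, int(srec["distance_bp"]), beta[1], beta[2],
                         beta[3], se[3], float(f_int), p_int,
                         0 if sv_arr is None else sv_arr.shape[1]))
    out = pd.DataFrame(recs, columns=["gene_id", "snp_id", "distance_bp", "beta_ery",
                                      "beta_dose", "beta_int", "se_int", "f_int",
                                      "p_int", "n_sv"])
    if out.empty:
        return out.assign(q_int=pd.Series(dtype=float))
    out["q_int"] = bh_fdr(out["p_int"].to_numpy())
    if "alt" in genos.info.columns:
        out["effect_allele"] = genos.info.loc[out["snp_id"], "alt"].to_numpy()
    return out if keep_all else out[out["q_int"] < fdr_q].reset_index(drop=True)
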