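"""Synthetic data generation with planted ground truth.

Every input the pipeline consumes can be generated here: negative-binomial
count matrices with disease / population / interaction effects, log-scale PBMC
expression driven by a latent erythroid-progenitor fraction, Hardy–Weinberg
genotype dosages with planted erythroid eQTL, case/control cohorts with a
planted pain-episode odds ratio, and erythroblast stage-transition tables with
configurable concordance rates.

All randomness flows from a single seed through named substreams, so a fixed
``SimulationConfig`` yields byte-identical outputs regardless of which stages
are generated or in what order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    TRANSITIONS,
    CohortTable,
    CountMatrix,
    ExpressionMatrix,
    GeneCoords,
    GenotypeMatrix,
    Phenotypes,
    StageTransitionTable,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "two_group_design",
    "factorial_design",
    "simulate_counts",
    "simulate_pbmc",
    "simulate_genotypes",
    "simulate_eqtl_expression",
    "simulate_cohorts",
    "make_stage_table_fixture",
]


@dataclass
class SimulationConfig:
    """Parameters shared by all generators.

    Defaults mirror the study conditions: 5+5 reticulocyte RNA-Seq samples per
    group, ~10% of genes differentially expressed, a 16-gene erythroid marker
    panel, risk-allele frequency 0.29, and a planted pain-episode odds ratio
    of 1.7.  ``dispersion`` is the NB dispersion phi in Var = mu + phi mu^2;
    ``effect_log2fc`` is the planted effect size on the log2 scale (fold
    change for counts, linear-model coefficient for PBMC expression).
    """

    seed: int = 0
    n_genes: int = 2000
    n_samples_per_group: int = 5
    dispersion: float = 0.1
    effect_log2fc: float = 1.0
    frac_de: float = 0.10
    frac_interaction: float = 0.06
    n_markers: int = 16
    maf: float = 0.29
    planted_or: float = 1.7
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_group < 1:
            raise ValueError("n_genes and n_samples_per_group must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        for name in ("frac_de", "frac_interaction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_markers < 2:
            raise ValueError("n_markers must be >= 2")
        if not (0.0 < self.maf < 1.0):
            raise ValueError("maf must lie in (0, 1)")
        if self.planted_or <= 0:
            raise ValueError("planted_or must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed (stable across runs)."""
        key = zlib.crc32(stream.encode("utf8"))
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(key,)))


@dataclass
class GroundTruth:
    """Planted truth recorded by the generators."""

    de_gene_ids: dict = field(default_factory=dict)
    true_interaction_beta: pd.Series | None = None
    true_eqtl: list = field(default_factory=list)
    true_erythroid_fraction: pd.Series | None = None
    extras: dict = field(default_factory=dict)


def two_group_design(n_per_group: int, prefix: str = "S") -> pd.DataFrame:
    """Disease-only design: n controls (disease=0) then n patients (disease=1)."""
    n = 2 * n_per_group
    idx = [f"{prefix}{i + 1:03d}" for i in range(n)]
    return pd.DataFrame({"disease": [0] * n_per_group + [1] * n_per_group}, index=idx)


def factorial_design(n_per_cell: int) -> pd.DataFrame:
    """Crossed disease x population design with ``n_per_cell`` samples per cell.

    population 1 is the SCA-side population (African American), population 0
    the comparator (Chuvash); disease 1 marks patients.
    """
    rows = []
    for pop in (0, 1):
        for dis in (0, 1):
            rows += [(dis, pop)] * n_per_cell
    idx = [f"S{i + 1:03d}" for i in range(len(rows))]
    return pd.DataFrame(rows, columns=["disease", "population"], index=idx)


def _check_design(design: pd.DataFrame) -> None:
    if "disease" not in design.columns:
        raise ValueError("design must contain a 'disease' column")
    factors = [c for c in ("disease", "population") if c in design.columns]
    cells = design.groupby(factors, observed=True).size()
    expected = 2 ** len(factors)
    if len(cells) < expected or (cells < 2).any():
        raise ValueError("every cell of the disease x population design needs >= 2 samples")


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i + 1:05d}" for i in range(n)]


def simulate_counts(config: SimulationConfig, design: pd.DataFrame | None = None
                    ) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial counts with planted disease / population / interaction effects.

    Counts for gene g in sample j are NB with mean ``mu_g * sf_j * 2^(X_j beta_g)``
    and per-gene dispersion drawn log-normal around ``config.dispersion``
    (Var = mu + phi mu^2).  Planted gene classes: with a disease-only design,
    ``frac_de`` of genes are "up"/"down"; with a crossed design, ``frac_de``
    are "shared" (disease effect in both populations) and ``frac_interaction``
    are "sca_specific" (effect only in disease x population==1, i.e. a pure
    interaction).  Class membership is recorded in the returned GroundTruth.
    """
    if design is None:
        design = two_group_design(config.n_samples_per_group)
    _check_design(design)
    genes = _gene_ids(config.n_genes)
    rng = config.rng("counts")

    base_mu = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=config.n_genes)
    if config.dispersion > 0:
        phi = config.dispersion * rng.lognormal(mean=0.0, sigma=0.25, size=config.n_genes)
    else:
        phi = np.zeros(config.n_genes)
    size_factors = rng.lognormal(mean=0.0, sigma=0.2, size=len(design))

    has_pop = "population" in design.columns
    beta_d = np.zeros(config.n_genes)
    beta_p = np.zeros(config.n_genes)
    beta_i = np.zeros(config.n_genes)
    n_de = int(round(config.frac_de * config.n_genes))
    truth = GroundTruth()
    perm = rng.permutation(config.n_genes)
    cursor = 0

    de_idx = perm[cursor:cursor + n_de]
    cursor += n_de
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    beta_d[de_idx] = signs * config.effect_log2fc
    up = [genes[i] for i, s in zip(de_idx, signs) if s > 0]
    down = [genes[i] for i, s in zip(de_idx, signs) if s < 0]
    truth.de_gene_ids["up"] = set(up)
    truth.de_gene_ids["down"] = set(down)

    if has_pop:
        truth.de_gene_ids["shared"] = set(up) | set(down)
        n_int = int(round(config.frac_interaction * config.n_genes))
        int_idx = perm[cursor:cursor + n_int]
        cursor += n_int
        int_signs = np.where(np.arange(n_int) % 2 == 0, 1.0, -1.0)
        beta_i[int_idx] = int_signs * config.effect_log2fc
        truth.de_gene_ids["sca_specific"] = {genes[i] for i in int_idx}
        # independent population main effects on a further slice of genes
        n_pop = int(round(config.frac_de * config.n_genes))
        pop_idx = perm[cursor:cursor + n_pop]
        beta_p[pop_idx] = rng.choice([-1.0, 1.0], size=pop_idx.size) * config.effect_log2fc

    dis = design["disease"].to_numpy(float)
    pop = design["population"].to_numpy(float) if has_pop else np.zeros(len(design))
    log2_shift = (np.outer(beta_d, dis) + np.outer(beta_p, pop)
                  + np.outer(beta_i, dis * pop))
    mu = base_mu[:, None] * size_factors[None, :] * np.exp2(log2_shift)

    counts = np.empty(mu.shape, dtype=np.int64)
    poisson = phi <= 1e-12
    if poisson.any():
        counts[poisson] = rng.poisson(mu[poisson])
    if (~poisson).any():
        ph = phi[~poisson][:, None]
        m = mu[~poisson]
        counts[~poisson] = rng.negative_binomial(1.0 / ph, 1.0 / (1.0 + ph * m))

    truth.true_interaction_beta = pd.Series(beta_i, index=genes)
    truth.extras.update({
        "true_disease_beta": pd.Series(beta_d, index=genes),
        "true_dispersion": pd.Series(phi, index=genes),
        "true_size_factors": pd.Series(size_factors, index=design.index),
    })
    cm = CountMatrix(counts=pd.DataFrame(counts, index=genes, columns=design.index),
                     samples=design.copy())
    return cm, truth


def marker_gene_ids(n_markers: int = 16) -> list[str]:
    return [f"ERYMARK{i + 1:02d}" for i in range(n_markers)]


def simulate_pbmc(config: SimulationConfig, n_samples: int = 151
                  ) -> tuple[ExpressionMatrix, Phenotypes, GroundTruth]:
    """Log2 PBMC expression with a latent erythroid fraction and interaction signal.

    The latent erythroid-progenitor fraction per sample is Beta(2, 5) scaled to
    (0, 0.2) — a minority PBMC component.  Its standardized score z drives the
    ``n_markers`` marker genes through positive loadings of unit joint norm
    scaled by a per-marker signal near 1 log2 unit per SD (erythroid lineage
    markers are high signal-to-noise).  Non-marker genes follow
    ``y = u + z b_ery + q_hgb b_hgb + sqrt(retic) b_hemo + (z q_hgb) b_int
    + (z sqrt(retic)) b_int_hemo + eps``; ``frac_de`` of them carry a positive
    erythroid loading (deconvolvable genes) and ``frac_interaction`` of those
    additionally carry the planted hemoglobin interaction
    ``b_int = effect_log2fc``.  Hemoglobin is N(86, 14) g/L as in the PBMC
    cohort; hematocrit tracks hemoglobin; quartile coding uses the same
    per-stratum rule the deconvolution stage applies.
    """
    if config.n_markers > config.n_genes:
        raise ValueError("n_markers cannot exceed n_genes")
    rng = config.rng("pbmc")
    samples = [f"P{i + 1:03d}" for i in range(n_samples)]
    markers = marker_gene_ids(config.n_markers)
    n_rest = config.n_genes - config.n_markers
    rest = _gene_ids(n_rest)
    genes = markers + rest

    frac = rng.beta(2.0, 5.0, size=n_samples) * 0.2
    z = (frac - frac.mean()) / frac.std()

    hgb = rng.normal(86.0, 14.0, size=n_samples)
    hct = hgb * 0.003 + rng.normal(0.0, 0.01, size=n_samples)
    retic = rng.gamma(shape=9.0, scale=1.2, size=n_samples)
    hydroxyurea = (rng.random(n_samples) < 0.5).astype(int)
    transfused = (rng.random(n_samples) < 0.13).astype(int)
    age = np.clip(rng.normal(37.0, 12.0, size=n_samples), 19, 72)
    sex = (rng.random(n_samples) < 0.53).astype(int)
    pheno = pd.DataFrame({
        "hgb": hgb, "hct": hct, "retic_pct": retic, "hydroxyurea": hydroxyurea,
        "transfused": transfused, "age": age, "sex": sex,
    }, index=samples)

    # quartile coding as applied downstream: per hydroxyurea stratum, cuts from
    # non-transfused samples, ties to the lower bin
    from .deconvolution import quartile_code

    q_hgb = np.empty(n_samples)
    for s in (0, 1):
        in_s = hydroxyurea == s
        ref = hgb[in_s & (transfused == 0)]
        q_hgb[in_s] = quartile_code(hgb[in_s], reference=ref)

    loadings = rng.uniform(0.8, 1.2, size=config.n_markers)
    loadings /= np.linalg.norm(loadings)
    signal = 4.0  # joint marker signal: ~1 log2 unit per marker per SD of z
    u_mark = rng.normal(7.0, 1.0, size=config.n_markers)
    X_mark = (u_mark[:, None] + signal * np.outer(loadings, z)
              + rng.normal(0.0, config.noise_sd, size=(config.n_markers, n_samples)))

    u = rng.normal(7.0, 1.0, size=n_rest)
    b_ery = np.zeros(n_rest)
    b_int = np.zeros(n_rest)
    n_deconv = int(round(config.frac_de * n_rest))
    perm = rng.permutation(n_rest)
    deconv_idx = perm[:n_deconv]
    b_ery[deconv_idx] = rng.uniform(0.2, 0.6, size=n_deconv)
    n_int = int(round(config.frac_interaction * n_rest))
    int_idx = deconv_idx[:n_int] if n_int <= n_deconv else perm[:n_int]
    b_int[int_idx] = config.effect_log2fc
    b_hgb = rng.normal(0.0, 0.02, size=n_rest)
    b_hemo = rng.normal(0.0, 0.02, size=n_rest)

    sqrt_retic = np.sqrt(retic)
    X_rest = (u[:, None]
              + np.outer(b_ery, z)
              + np.outer(b_hgb, q_hgb)
              + np.outer(b_hemo, sqrt_retic)
              + np.outer(b_int, z * q_hgb)
              + rng.normal(0.0, config.noise_sd, size=(n_rest, n_samples)))

    values = pd.DataFrame(np.vstack([X_mark, X_rest]), index=genes, columns=samples)
    truth = GroundTruth(
        true_interaction_beta=pd.Series(np.concatenate([np.zeros(config.n_markers), b_int]),
                                        index=genes),
        true_erythroid_fraction=pd.Series(frac, index=samples),
    )
    truth.de_gene_ids["deconvolvable"] = {rest[i] for i in deconv_idx}
    truth.de_gene_ids["interaction"] = {rest[i] for i in int_idx}
    truth.extras.update({
        "marker_ids": markers,
        "true_signature": pd.Series(z, index=samples),
        "true_ery_beta": pd.Series(np.concatenate([np.zeros(config.n_markers), b_ery]),
                                   index=genes),
    })
    return ExpressionMatrix(values), Phenotypes(pheno), truth


def simulate_genotypes(config: SimulationConfig, gene_coords: GeneCoords,
                       n_samples: int = 151, snps_per_gene: int = 5,
                       n_decoys: int = 10, window_bp: int = 100_000,
                       n_eqtl_genes: int | None = None
                       ) -> tuple[GenotypeMatrix, GroundTruth]:
    """Hardy–Weinberg dosages with SNPs placed around gene windows and planted eQTL.

    For each gene, ``snps_per_gene`` SNPs are placed inside the gene body or
    within the 100 kb flanks, plus ``n_decoys`` SNPs beyond the window on the
    same chromosomes.  One local SNP per eQTL gene is recorded in the ground
    truth with effect size ``effect_log2fc`` acting through the
    erythroid x dosage interaction (the expression matrix carrying that effect
    is produced by :func:`simulate_eqtl_expression`).
    """
    if not (0.0 < config.maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5] for genotype simulation")
    rng = config.rng("genotypes")
    samples = [f"P{i + 1:03d}" for i in range(n_samples)]
    rows, ids = [], []
    truth = GroundTruth()
    gtab = gene_coords.table
    if n_eqtl_genes is None:
        n_eqtl_genes = max(1, int(round(config.frac_interaction * len(gtab))))
    eqtl_genes = list(gtab.index[:n_eqtl_genes])

    for gene, rec in gtab.iterrows():
        start1 = int(rec["start"]) + 1  # 1-based first base of the body
        end = int(rec["end"])
        lo = max(1, start1 - window_bp + 1)
        hi = end + window_bp - 1
        pos = np.sort(rng.integers(lo, hi + 1, size=snps_per_gene))
        for k, p in enumerate(pos):
            sid = f"rs_{gene}_{k + 1}"
            ids.append(sid)
            rows.append((rec["chrom"], int(p)))
            if gene in eqtl_genes and k == 0:
                truth.true_eqtl.append((gene, sid, config.effect_log2fc))
    chroms = gtab["chrom"].unique()
    span_hi = int(gtab["end"].max()) + 10 * window_bp
    for k in range(n_decoys):
        chrom = chroms[k % len(chroms)]
        far = int(gtab.loc[gtab["chrom"] == chrom, "end"].max()) + 2 * window_bp
        ids.append(f"rs_decoy_{k + 1}")
        rows.append((chrom, far + int(rng.integers(0, span_hi - far + 1))))

    dosages = rng.binomial(2, config.maf, size=(len(ids), n_samples)).astype(float)
    info = pd.DataFrame(rows, columns=["chrom", "pos"], index=ids)
    info["ref"] = "A"
    info["alt"] = "G"
    info["imputation_r2"] = rng.uniform(0.91, 1.0, size=len(ids))
    gm = GenotypeMatrix(dosages=pd.DataFrame(dosages, index=ids, columns=samples),
                        info=info)
    return gm, truth


def simulate_eqtl_expression(config: SimulationConfig, genos: GenotypeMatrix,
                             truth: GroundTruth, gene_ids,
                             signature: pd.Series | None = None
                             ) -> tuple[ExpressionMatrix, pd.Series]:
    """Expression for the eQTL stage, planted through erythroid x dosage interaction.

    ``y_g = u_g + 0.4 z + 0.05 dose + beta (z * dose) + eps`` for eQTL genes
    (beta from the ground-truth triple), interaction-free otherwise.  Returns
    the matrix and the standardized erythroid score z used (generated here
    unless supplied).
    """
    rng = config.rng("eqtl-expression")
    samples = list(genos.sample_ids)
    if signature is None:
        frac = rng.beta(2.0, 5.0, size=len(samples)) * 0.2
        z = (frac - frac.mean()) / frac.std()
        signature = pd.Series(z, index=samples)
    z = signature.to_numpy(float)
    planted = {g: (s, b) for g, s, b in truth.true_eqtl}
    vals = np.empty((len(gene_ids), len(samples)))
    for i, gene in enumerate(gene_ids):
        row = rng.normal(7.0, 0.0) + 0.4 * z
        if gene in planted:
            snp, beta = planted[gene]
            dose = genos.dosages.loc[snp].to_numpy(float)
            row = row + 0.05 * dose + beta * z * dose
        vals[i] = row + rng.normal(0.0, config.noise_sd, size=len(samples))
    expr = ExpressionMatrix(pd.DataFrame(vals, index=list(gene_ids), columns=samples))
    return expr, signature


def simulate_cohorts(config: SimulationConfig,
                     n_per_cohort: tuple = (399, 207, 168),
                     names: tuple = ("Walk-PHaSST", "PUSH", "UIC")
                     ) -> list[tuple[CohortTable, GroundTruth]]:
    """Cohorts with a binary pain-episode outcome drawn from a logistic model.

    ``logit P(outcome=1) = b0 + ln(planted_or) dose + 0.01 (age - 35)
    + 0.2 sex + 0.1 copies``; the intercept targets ~30% prevalence at the
    mean dosage.  Cohort sizes default to the three study cohorts (399, 207,
    168; 774 in total).
    """
    out = []
    log_or = np.log(config.planted_or)
    for name, n in zip(names, n_per_cohort):
        rng = config.rng(f"cohort-{name}")
        dose = rng.binomial(2, config.maf, size=n).astype(float)
        age = np.clip(rng.normal(35.0, 15.0, size=n), 3, 75)
        sex = (rng.random(n) < 0.5).astype(int)
        thal = rng.binomial(2, 0.15, size=n)
        b0 = np.log(0.3 / 0.7) - log_or * 2 * config.maf
        eta = b0 + log_or * dose + 0.01 * (age - 35.0) + 0.2 * sex + 0.1 * thal
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        table = pd.DataFrame({
            "outcome": y, "dosage": dose, "age": age, "sex": sex,
            "alpha_thal_copies": thal,
        }, index=[f"{name}_{i + 1:04d}" for i in range(n)])
        truth = GroundTruth(extras={"log_or": log_or})
        out.append((CohortTable(name=name, table=table), truth))
    return out


def make_stage_table_fixture(config: SimulationConfig,
                             rates: tuple = (0.82, 0.83, 0.70, 0.52),
                             n_genes: int | None = None,
                             frac_significant: float = 0.9
                             ) -> tuple[StageTransitionTable, pd.Series]:
    """Stage-transition fixture with planted per-transition concordance rates.

    Each gene gets a disease-DE direction (up with probability 0.6, the
    approximate up/down balance of the reticulocyte DE genes); per transition
    the gene is significant with probability ``frac_significant`` and, when
    significant, concordant with its DE direction at the planted rate.
    Returns the table and the per-gene DE directions it was planted against.
    """
    if len(rates) != len(TRANSITIONS):
        raise ValueError(f"need one rate per transition ({len(TRANSITIONS)})")
    n = n_genes if n_genes is not None else config.n_genes
    rng = config.rng("stage-table")
    genes = _gene_ids(n)
    de_dir = np.where(rng.random(n) < 0.6, 1, -1)
    cols = {}
    for t, rate in zip(TRANSITIONS, rates):
        sig = rng.random(n) < frac_significant
        concord = rng.random(n) < rate
        direction = np.where(sig, np.where(concord, de_dir, -de_dir), 0)
        effect = np.where(sig,
                          direction * np.abs(rng.normal(0.5, 0.2, size=n)),
                          rng.normal(0.0, 0.05, size=n))
        cols[f"direction_{t}"] = direction
        cols[f"significant_{t}"] = sig
        cols[f"effect_{t}"] = effect
    table = StageTransitionTable(pd.DataFrame(cols, index=genes))
    return table, pd.Series(de_dir, index=genes, name="direction")
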