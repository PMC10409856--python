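"""In-memory containers for the pipeline's data objects.

Thin, validated wrappers around pandas DataFrames: integer count matrices with
sample factors, continuous log-scale expression matrices, phenotype tables,
genotype dosage matrices with per-SNP QC statistics, gene coordinate tables
(0-based half-open, BED convention), and erythroblast stage-transition tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: ordered erythroblast maturation stage transitions
TRANSITIONS = ("ProE-EB", "EB-LB", "LB-Poly", "Poly-Ortho")


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus per-sample factors (disease, population, batch)."""

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.samples.index):
            raise ValueError("count columns must match sample table index")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        vals = self.counts.values
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class ExpressionMatrix:
    """Continuous log2-scale gene x sample expression values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if not np.issubdtype(self.values.values.dtype, np.floating):
            self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class Phenotypes:
    """Per-sample clinical covariates for the PBMC deconvolution stage.

    Expected columns: hgb (g/L), hct (fraction), retic_pct (percent
    reticulocytes), hydroxyurea (0/1), transfused (0/1), age, sex (0/1).
    """

    table: pd.DataFrame

    REQUIRED = ("hgb", "hct", "retic_pct", "hydroxyurea", "transfused", "age", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        retic = self.table["retic_pct"].dropna()
        if (retic < 0).any():
            raise ValueError("retic_pct must be non-negative")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class GenotypeMatrix:
    """SNP x sample allele dosages in [0, 2] with positions and QC statistics.

    ``info`` is indexed by SNP id with columns chrom, pos (1-based), ref, alt
    and optionally call_rate, maf, hwe_p, imputation_r2.
    """

    dosages: pd.DataFrame
    info: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.info.index):
            raise ValueError("dosage rows must match SNP info index")
        vals = self.dosages.values
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        for col in ("chrom", "pos"):
            if col not in self.info.columns:
                raise ValueError(f"SNP info missing column {col!r}")

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.columns

    def genotype_counts(self, snp_id) -> tuple[int, int, int]:
        """Hard-call genotype counts (hom-ref, het, hom-alt) from rounded dosages."""
        d = self.dosages.loc[snp_id].dropna().round().astype(int)
        return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


@dataclass
class GeneCoords:
    """Gene coordinates, 0-based half-open (BED convention), indexed by gene id."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("chrom", "start", "end"):
            if col not in self.table.columns:
                raise ValueError(f"gene coordinate table missing column {col!r}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate gene ids in coordinate table")
        if (self.table["start"] < 0).any():
            raise ValueError("start must be non-negative")
        if (self.table["start"] >= self.table["end"]).any():
            raise ValueError("start must be < end")
        if "strand" not in self.table.columns:
            self.table = self.table.assign(strand=".")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class StageTransitionTable:
    """Per-gene signed significance of expression change at each stage transition.

    For each transition t the table carries ``direction_<t>`` in {-1, 0, +1},
    ``significant_<t>`` (bool) and ``effect_<t>`` (log2 fold change used for
    profile clustering).  direction 0 iff not significant.
    """

    table: pd.DataFrame
    transitions: tuple = field(default=TRANSITIONS)

    def __post_init__(self) -> None:
        for t in self.transitions:
            for prefix in ("direction", "significant"):
                if f"{prefix}_{t}" not in self.table.columns:
                    raise ValueError(f"stage table missing column {prefix}_{t}")
            d = self.table[f"direction_{t}"]
            if not d.isin([-1, 0, 1]).all():
                raise ValueError("directions must be in {-1, 0, 1}")
            sig = self.table[f"significant_{t}"].astype(bool)
            if ((d != 0) != sig).any():
                raise ValueError("direction must be 0 exactly when not significant")

    def direction(self, t: str) -> pd.Series:
        return self.table[f"direction_{t}"]

    def significant(self, t: str) -> pd.Series:
        return self.table[f"significant_{t}"].astype(bool)

    def effects(self) -> pd.DataFrame:
        cols = [f"effect_{t}" for t in self.transitions if f"effect_{t}" in self.table.columns]
        return self.table[cols]

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class CohortTable:
    """Per-subject data for one cohort of the pain-episode association stage.

    Columns: outcome (0/1, three or more severe pain episodes in 12 months),
    dosage in [0, 2], age, sex (0/1), alpha_thal_copies (0/1/2), plus any
    stratification covariates (pc1, pc2, ...).
    """

    name: str
    table: pd.DataFrame

    REQUIRED = ("outcome", "dosage", "age", "sex", "alpha_thal_copies")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if not self.table["outcome"].isin([0, 1]).all():
            raise ValueError("outcome must be binary 0/1")
        d = self.table["dosage"]
        if (d < 0).any() or (d > 2).any():
            raise ValueError("dosage must lie in [0, 2]")

    @property
    def n(self) -> int:
        return len(self.table)


@dataclass
class GeneSets:
    """Named gene-id sets (GMT-derived)."""

    sets: dict

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = set(members)

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)
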