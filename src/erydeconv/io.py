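"""Readers and writers for the pipeline's file formats.

TSV count/expression/phenotype matrices, VCF 4.2 dosages (cyvcf2; the DS
FORMAT field when present, otherwise GT converted to dosage), BED gene
coordinates (0-based half-open), GMT gene sets, and the flat YAML pipeline
configuration.  Writers emit a ``#``-prefixed header comment recording the
package version; readers skip comment lines.  Every writer/reader pair
round-trips losslessly.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import (
    CohortTable,
    CountMatrix,
    ExpressionMatrix,
    GeneCoords,
    GeneSets,
    GenotypeMatrix,
    Phenotypes,
    StageTransitionTable,
)

__all__ = [
    "PipelineConfig",
    "read_counts", "write_counts",
    "read_expression", "write_expression",
    "read_phenotypes", "write_phenotypes",
    "read_vcf_dosages", "write_vcf",
    "read_bed", "write_bed",
    "read_gmt", "write_gmt",
    "read_stage_table", "write_stage_table",
    "read_cohort", "write_cohort",
]


@dataclass
class PipelineConfig:
    """Pipeline thresholds with the study defaults."""

    fdr_q: float = 0.05
    nominal_p: float = 0.05
    hwe_p: float = 1e-4
    maf_min: float = 0.01
    eqtl_maf_min: float = 0.1
    eqtl_r2_min: float = 0.9
    call_rate_min: float = 0.95
    window_bp: int = 100_000
    min_total_count: int = 10
    seed: int = 0
    stratify_hydroxyurea: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header_comment(config: PipelineConfig | None = None) -> str:
    tag = f"# erydeconv {__version__}"
    if config is not None:
        tag += f" config={config.digest()}"
    return tag + "\n"


def _read_tsv(path, index_col: str):
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={index_col: str})
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse TSV ({exc})")
    if index_col not in df.columns:
        raise ValueError(f"{path}: missing {index_col!r} column")
    if df[index_col].duplicated().any():
        dup = df[index_col][df[index_col].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate id {dup!r}")
    return df.set_index(index_col)


def read_counts(path, sample_path=None) -> CountMatrix:
    """Counts TSV (gene_id column + integer sample columns) plus sample factors."""
    df = _read_tsv(path, "gene_id")
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.integer))]
    if len(bad):
        raise ValueError(f"{path}: non-integer count column(s): {list(bad)}")
    if sample_path is not None:
        samples = _read_tsv(sample_path, "sample_id")
    else:
        samples = pd.DataFrame(index=df.columns)
        samples["disease"] = 0
    samples = samples.reindex(df.columns)
    if samples.isna().all(axis=1).any() and sample_path is not None:
        missing = samples.index[samples.isna().all(axis=1)]
        raise ValueError(f"sample metadata missing for: {list(missing[:5])}")
    return CountMatrix(counts=df, samples=samples)


def write_counts(cm: CountMatrix, path, sample_path=None,
                 config: PipelineConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        cm.counts.rename_axis("gene_id").to_csv(fh, sep="\t")
    if sample_path is not None:
        with open(sample_path, "w") as fh:
            fh.write(_header_comment(config))
            cm.samples.rename_axis("sample_id").to_csv(fh, sep="\t")


def read_expression(path) -> ExpressionMatrix:
    df = _read_tsv(path, "gene_id").astype(float)
    return ExpressionMatrix(values=df)


def write_expression(em: ExpressionMatrix, path,
                     config: PipelineConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        em.values.rename_axis("gene_id").to_csv(fh, sep="\t", float_format="%.10g")


def read_phenotypes(path) -> Phenotypes:
    return Phenotypes(table=_read_tsv(path, "sample_id"))


def write_phenotypes(ph: Phenotypes, path, config: PipelineConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        ph.table.rename_axis("sample_id").to_csv(fh, sep="\t", float_format="%.10g")


def read_vcf_dosages(path) -> GenotypeMatrix:
    """VCF 4.2 reader returning alternate-allele dosages.

    Uses the per-sample DS FORMAT field when present, otherwise converts GT
    (0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> missing).  Multi-allelic records are
    rejected with a message naming the site.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids, rows, dos = [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic site at {v.CHROM}:{v.POS} "
                             f"(ALT={v.ALT}); split or filter first")
        sid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        ds = None
        try:
            arr = v.format("DS")
        except KeyError:
            arr = None
        if arr is not None:
            ds = np.asarray(arr, dtype=float).ravel()
        else:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(v.gt_types, dtype=float)
            ds = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
        r2 = v.INFO.get("R2")
        ids.append(sid)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0],
                     float(r2) if r2 is not None else np.nan))
        dos.append(ds)
    if not ids:
        raise ValueError(f"{path}: no usable records")
    info = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "imputation_r2"],
                        index=ids)
    dosages = pd.DataFrame(np.vstack(dos), index=ids, columns=list(vcf.samples))
    return GenotypeMatrix(dosages=dosages, info=info)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF 4.2 with GT and DS FORMAT fields."""
    info = gm.info.sort_values(["chrom", "pos"])
    samples = list(gm.sample_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(info["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation r-squared">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for sid, rec in info.iterrows():
            ref = rec.get("ref", "A")
            alt = rec.get("alt", "G")
            r2 = rec.get("imputation_r2", np.nan)
            info_str = f"R2={r2:.4f}" if np.isfinite(r2) else "."
            cells = []
            for s in samples:
                d = gm.dosages.loc[sid, s]
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    hard = int(round(d))
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[hard]
                    cells.append(f"{gt}:{d:.3f}")
            fh.write(f"{rec['chrom']}\t{int(rec['pos'])}\t{sid}\t{ref}\t{alt}\t.\t.\t"
                     f"{info_str}\tGT:DS\t" + "\t".join(cells) + "\n")


def read_bed(path) -> GeneCoords:
    """BED (0-based half-open): chrom, start, end, gene_id[, score, strand]."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 4 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates")
            strand = parts[5] if len(parts) >= 6 else "."
            rows.append((parts[3], parts[0], start, end, strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    return GeneCoords(table=df.set_index("gene_id"))


def write_bed(gc: GeneCoords, path) -> None:
    with open(path, "w") as fh:
        for gene, rec in gc.table.iterrows():
            fh.write(f"{rec['chrom']}\t{int(rec['start'])}\t{int(rec['end'])}\t"
                     f"{gene}\t0\t{rec.get('strand', '.')}\n")


def read_gmt(path) -> GeneSets:
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, "
                                 "description, and at least one gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [g for g in parts[2:] if g]
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = set(members)
    return GeneSets(sets=sets)


def write_gmt(gs: GeneSets, path) -> None:
    with open(path, "w") as fh:
        for name, members in gs:
            fh.write(name + "\tna\t" + "\t".join(sorted(members)) + "\n")


def read_stage_table(path) -> StageTransitionTable:
    df = _read_tsv(path, "gene_id")
    for c in df.columns:
        if c.startswith("significant_"):
            df[c] = df[c].astype(bool)
    return StageTransitionTable(table=df)


def write_stage_table(st: StageTransitionTable, path,
                      config: PipelineConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        st.table.rename_axis("gene_id").to_csv(fh, sep="\t", float_format="%.10g")


def read_cohort(path, name: str | None = None) -> CohortTable:
    df = _read_tsv(path, "subject_id")
    return CohortTable(name=name or Path(path).stem, table=df)


def write_cohort(ct: CohortTable, path, config: PipelineConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        ct.table.rename_axis("subject_id").to_csv(fh, sep="\t", float_format="%.10g")
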