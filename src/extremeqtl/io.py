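"""Readers and writers for the per-SNP pipeline's tabular formats.

Phenotypes travel as a two-column TSV (sample_id, phenotype).  Genotypes
travel either as a TSV dosage matrix (rows = samples, first column
sample_id, one column of 0/1/2/NA minor-allele dosages per SNP) or as a
biallelic-SNP VCF with GT fields.  The fixture writer produces matched
synthetic inputs with a truth sidecar, standing in for real cohorts.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .models import PopulationSpec, simulate_cohort, simulate_genotypes

logger = logging.getLogger("extremeqtl")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class GenotypeMatrix:
    """n samples x m SNPs of minor-allele dosages; np.nan marks missing."""

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # float (n, m), values in {0, 1, 2, nan}
    flipped: np.ndarray | None = None  # SNPs re-oriented to the minor allele

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape does not match id lists")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.flipped is None:
            self.flipped = np.zeros(len(self.snp_ids), dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a (sample_id, phenotype) TSV; errors carry the offending line."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty phenotype file") from None
    missing = {"sample_id", "phenotype"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no phenotype records")
    numeric = pd.to_numeric(df["phenotype"], errors="coerce")
    bad = df.index[numeric.isna()]
    if len(bad):
        raise ValueError(
            f"{path}: non-numeric phenotype at line {bad[0] + 2}"  # +1 header, +1 1-based
        )
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated sample_id {dup.iloc[0]!r}")
    df["phenotype"] = numeric
    logger.info("read %d phenotype records from %s", len(df), path)
    return df.reset_index(drop=True)


def _orient_minor(dosages: np.ndarray) -> np.ndarray:
    """Flip dosages (2 - d) for SNPs whose coded-allele frequency exceeds 0.5."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    flip = freq > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    return flip


def read_genotypes(path, fmt: str = "tsv", orient_minor: bool = True) -> GenotypeMatrix:
    """Read a genotype matrix from a dosage TSV or a biallelic VCF.

    VCF GT fields 0/0, 0/1, 1/1 map to alt-allele dosage 0, 1, 2 and ./.
    to missing; multiallelic records are skipped with a logged count.
    When orient_minor is set (default) dosages are re-oriented per SNP so
    the coded allele is the minor allele.
    """
    if fmt == "tsv":
        gm = _read_genotypes_tsv(path)
    elif fmt == "vcf":
        gm = _read_genotypes_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    if orient_minor:
        gm.flipped = _orient_minor(gm.dosages)
        if gm.flipped.any():
            logger.info(
                "re-oriented %d SNP(s) to minor-allele coding", int(gm.flipped.sum())
            )
    all_missing = np.isnan(gm.dosages).all(axis=0)
    if all_missing.any():
        logger.warning("%d SNP(s) have no called genotypes", int(all_missing.sum()))
    logger.info("read %d samples x %d SNPs", gm.n_samples, gm.n_snps)
    return gm


def _read_genotypes_tsv(path) -> GenotypeMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", "NaN", ""])
    if df.shape[1] < 2:
        raise ValueError(f"{path}: genotype TSV needs a sample_id column and >=1 SNP")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    snp_ids = [str(c) for c in df.columns[1:]]
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    bad = ~(np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid dosage {dosages[i, j]!r} at line {i + 2}, SNP {snp_ids[j]}"
        )
    return GenotypeMatrix(sample_ids=sample_ids, snp_ids=snp_ids, dosages=dosages)


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover
        raise ImportError("reading VCF requires the cyvcf2 package") from None
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = variant.gt_types.astype(float)
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        columns.append(dosage)
    vcf.close()
    if n_multi:
        logger.info("skipped %d multiallelic record(s)", n_multi)
    if not columns:
        raise ValueError(f"{path}: no biallelic SNP records")
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        dosages=np.column_stack(columns),
    )


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.dosages, columns=gm.snp_ids)
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.insert(0, "sample_id", gm.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def write_genotypes_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal biallelic VCF (GT only, REF=A, ALT=C)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, snp in enumerate(gm.snp_ids):
            calls = [gt_map.get(v, "./.") for v in gm.dosages[:, j]]
            fh.write(
                f"1\t{j + 1}\t{snp}\tA\tC\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def make_fixture(
    spec: PopulationSpec,
    m_null_snps: int,
    out_prefix,
    rng: np.random.Generator,
    write_vcf: bool = False,
) -> dict:
    """Write a synthetic phenotype/genotype fixture with one causal SNP.

    The causal SNP is simulated under spec and drives the phenotype; the
    remaining m_null_snps SNPs are independent HWE markers with MAFs drawn
    Uniform(0.05, 0.5) and no phenotypic effect.  Under the null spec
    (delta = 1) no SNP has an effect and the truth sidecar records that.
    Returns the sidecar dict (also written to ``<prefix>.truth.json``).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(spec, rng)
    n = spec.n
    m_total = m_null_snps + 1
    causal_col = int(rng.integers(m_total))
    dosages = np.empty((n, m_total))
    null_mafs = rng.uniform(0.05, 0.5, size=m_null_snps)
    null_iter = iter(null_mafs)
    for j in range(m_total):
        if j == causal_col:
            dosages[:, j] = cohort.genotypes
        else:
            dosages[:, j] = simulate_genotypes(n, float(next(null_iter)), rng)
    width = len(str(m_total))
    snp_ids = [f"snp{j + 1:0{width}d}" for j in range(m_total)]
    sample_ids = [f"s{i + 1:0{len(str(n))}d}" for i in range(n)]
    gm = GenotypeMatrix(sample_ids=sample_ids, snp_ids=snp_ids, dosages=dosages)

    pheno_path = out_prefix.with_suffix(".pheno.tsv")
    geno_path = out_prefix.with_suffix(".geno.tsv")
    pd.DataFrame({"sample_id": sample_ids, "phenotype": cohort.phenotypes}).to_csv(
        pheno_path, sep="\t", index=False
    )
    write_genotypes_tsv(gm, geno_path)
    truth = {
        "causal_snp": None if spec.effect.is_null else snp_ids[causal_col],
        "causal_column": causal_col,
        "model": spec.model.value,
        "delta": spec.effect.delta,
        "sd": spec.effect.sd,
        "maf": spec.maf,
        "n": n,
        "m_null_snps": m_null_snps,
        "null_hypothesis": spec.effect.is_null,
    }
    truth_path = out_prefix.with_suffix(".truth.json")
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    files = {"pheno": pheno_path, "geno": geno_path, "truth": truth_path}
    if write_vcf:
        vcf_path = out_prefix.with_suffix(".vcf")
        write_genotypes_vcf(gm, vcf_path)
        files["vcf"] = vcf_path
    logger.info(
        "fixture: %d samples, %d SNPs (causal: %s) -> %s.*",
        n, m_total, truth["causal_snp"], out_prefix,
    )
    return truth
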