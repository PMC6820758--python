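"""End-to-end per-SNP scan on a synthetic fixture.

Writes a fixture with one causal SNP (dominant, delta = 2) among 99 null
SNPs, labels the trait tails by percentile thresholds, tests every SNP
with Fisher's exact test, applies Bonferroni, and scans a grid of
threshold pairs.
"""

import tempfile
from pathlib import Path

import numpy as np

import extremeqtl as xq

tmp = Path(tempfile.mkdtemp())
spec = xq.PopulationSpec(n=500, maf=0.3, model="dominant",
                         effect=xq.EffectSpec(delta=2.0))
truth = xq.make_fixture(spec, m_null_snps=99, out_prefix=tmp / "demo",
                        rng=np.random.default_rng(3))
print("causal SNP (hidden from the scan):", truth["causal_snp"])

geno = xq.read_genotypes(tmp / "demo.geno.tsv")
pheno = xq.read_phenotypes(tmp / "demo.pheno.tsv")
y = pheno["phenotype"].to_numpy()

sample = xq.dichotomize_by_percentile(y, xq.ThresholdPair(20, 80))
records = xq.run_association(geno, sample, test="fisher_dominant", alpha=0.05)
frame = xq.records_to_frame(records).sort_values("p_value")
print("\ntop 3 SNPs at T1=20th / T2=80th percentile:")
print(frame.head(3)[["snp_id", "maf", "p_value", "p_bonferroni",
                     "significant", "hwe_p"]].to_string(index=False))

summaries = xq.threshold_scan(geno, y, t1_grid=[10, 30, 50],
                              t2_grid=[90, 70, 50], test="fisher_dominant")
print("\nsignificant-SNP count by threshold pair (rows T1, columns T2):")
print(xq.pivot_scan(summaries).to_string())
print("\nThe causal SNP should top every cell; null SNPs clear Bonferroni",
      "only by chance.")
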