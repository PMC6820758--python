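"""Simulate one cohort, select phenotype extremes and test for association.

A single QTL with minor-allele frequency 0.3 acts dominantly with effect
delta = 1.5 (carrier trait mean 1.5 vs 1.0, within-genotype sd 1).  We
genotype only the top and bottom 10% of the trait distribution and test
the resulting 2x3 tail-genotype table, comparing with the full-data ANOVA.
"""

import numpy as np

import extremeqtl as xq

rng = np.random.default_rng(7)
spec = xq.PopulationSpec(n=300, maf=0.3, model="dominant",
                         effect=xq.EffectSpec(delta=1.5))
cohort = xq.simulate_cohort(spec, rng)

sample = xq.select_extremes(cohort, xq.ExtremeDesign(f_upper=0.1, f_lower=0.1))
table = xq.build_contingency(sample, cohort.genotypes)
print("tail genotype counts (AA, AB, BB):")
print("  upper 10% (cases):   ", table.as_array()[0].tolist())
print("  lower 10% (controls):", table.as_array()[1].tolist())

exact = xq.fisher_exact_2x3(table)
dom = xq.fisher_exact(xq.collapse_table(table, "dominant"))
anova = xq.anova_f(cohort.phenotypes, cohort.genotypes)
print(f"2x3 exact test p = {exact.p_value:.4g}   (60 genotyped individuals)")
print(f"dominant-collapsed 2x2 Fisher p = {dom.p_value:.4g}")
print(f"full-data ANOVA p = {anova.p_value:.4g}   (300 genotyped individuals)")
print("A small tail p-value despite genotyping 5x fewer individuals is the",
      "cost saving extreme sampling buys.")
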