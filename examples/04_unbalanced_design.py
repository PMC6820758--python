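"""Unbalanced case:control selection for a rare recessive locus.

With maf = 0.2 the BB risk genotype is rare (4% of the population), so at
a fixed 10% case fraction it pays to widen the control tail: the scan
reports the power-optimal control fraction.  Demo-scale replicates.
"""

import extremeqtl as xq

spec = xq.PopulationSpec(n=500, maf=0.2, model="recessive",
                         effect=xq.EffectSpec(delta=1.4))
df = xq.ratio_scan(spec, f_case=0.1, f_control_grid=[0.1, 0.2, 0.3, 0.4, 0.5],
                   n_reps=2000, calibration_reps=20_000, seed=11)
cols = ["f_upper", "f_lower", "n_sampled", "power", "power_per_individual"]
print(df[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
opt = df.attrs["optimal_power_f_control"]
print(f"\npower-optimal control fraction: {opt} "
      f"(control:case ratio {opt / 0.1:.0f}:1)")
print("More controls than cases buys power because controls deplete the",
      "rare risk genotype while cases enrich it.")
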