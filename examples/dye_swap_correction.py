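"""Quantifying dye bias from a dye-swap experiment.

Swapping the Cy5/Cy3 labels flips the sign of the true allelic signal in
the log-ratio but leaves any dye bias untouched, so the intercept of a
SNP-wise dye-swap linear model isolates the bias. The generator injects a
bias that grows with average intensity (dim probes lean toward Cy3, bright
ones toward Cy5); within-array quantile normalization should largely
remove it.
"""

import numpy as np

import asearray as aa

cfg = aa.SimConfig(n_snps=1000, n_replicates=2, seed=2,
                   dye_bias_slope=0.2, dye_bias_intercept=-1.5)
result = aa.run_dye_swap_analysis(cfg, materials=("gDNA", "cDNA"))

effects = result["effects"]
print("per-SNP dye effect (log2 units) before and after quantile normalization:")
for (material, normalized), trend in result["trends"].items():
    label = "normalized" if normalized else "raw       "
    print(f"  {material} {label}: mean |dye effect| = {trend['mean_abs_effect']:.3f}, "
          f"trend vs A: slope {trend['trend_slope']:+.3f} (r = {trend['trend_r']:+.2f})")

man = result["manifests"]["gDNA"].set_index("snp_id")
pre = effects[(effects["material"] == "gDNA") & ~effects["normalized"]].set_index("snp_id")
r = np.corrcoef(pre["dye_effect"], man.loc[pre.index, "injected_bias"])[0, 1]
print(f"\ncorrelation of raw gDNA intercepts with the injected bias: {r:.3f}")
print("normalization shrinks the effects toward zero and flattens the "
      "intensity trend, which is why the pipeline normalizes by default.")
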