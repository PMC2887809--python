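"""ROC benchmarking of preprocessing on a mixture-titration experiment.

Two individuals' gDNA is pooled at several proportions; SNPs where their
genotypes differ carry a real allelic imbalance (true positives) while
concordant SNPs stay balanced (true negatives). SNP-wise linear models
contrast each mixture against the 50:50 pool, empirical-Bayes log-odds rank
the SNPs, and the ROC AUC measures how well each preprocessing condition
(local background correction x within-array quantile normalization)
recovers the known imbalances.
"""

import asearray as aa

cfg = aa.SimConfig(n_snps=800, mixture_proportions=(0.5, 0.56, 0.6, 0.67, 1.0),
                   n_replicates=3, seed=1)
result = aa.run_mixture_benchmark(cfg)

truth_counts = result["truth"]["label"].value_counts()
print(f"truth set: {truth_counts.get('true_positive', 0)} true positives, "
      f"{truth_counts.get('true_negative', 0)} true negatives, "
      f"{truth_counts.get('excluded', 0)} excluded (missing genotypes)")

auc = result["auc"].pivot(index="contrast", columns="condition", values="auc")
print("\nAUC by mixture (rows) and preprocessing condition (columns):")
print(auc.round(3).to_string())
print("\nAUC falls as the pools approach 50:50 — a 56:44 pool is only a "
      "~1.3-fold imbalance — and background-corrected columns ('bg')"
      " dominate their uncorrected counterparts.")
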