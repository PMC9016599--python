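"""Calibrate critical values from a small gradient experiment.

Runs a reduced randomized gradient (200 replicates, 8 or 32 taxa), picks
the per-condition ROC-optimal thresholds of the informative-sites
statistic, and fits the regression of those thresholds on sqrt(taxon
count) and sqrt(sequence length). A production calibration uses more
replicates (the bundled model was fitted to 1200).
"""

from entsat import calibration as cal

records = cal.run_gradient_experiment(n_sims=200, seed=7, taxa_choices=(8, 32))
model = cal.calibrate(records, n_length_bins=2, length_range=(250, 1250))

print("per-condition ROC-optimal critical values:")
print(model.per_bin.to_string(index=False))
print(f"\nt_crit = {model.intercept:.2f} "
      f"+ {model.coef_sqrt_taxa:.2f} * sqrt(n_taxa) "
      f"+ {model.coef_sqrt_len:.4f} * sqrt(seq_len)")
print(f"adjusted R^2 = {model.adjusted_r2:.2f}")

t_crit, tpr, fpr, extrapolated = model.predict(16, 600)
print(f"\npredicted t_crit for 16 taxa, 600 sites: {t_crit:.2f} "
      f"(expected TPR {tpr:.2f}, FPR {fpr:.2f}, extrapolated: {extrapolated})")
print("\nEach row's t_crit maximises true minus false positives for"
      "\ntopological inference errors within one (taxa, length-bin) cell;"
      "\nthe regression lets the test predict t_crit for unseen data sizes.")
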