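"""Run the entropy saturation test on two simulated loci.

Simulates one slowly evolving locus (strong historical signal) and one
rapidly evolving locus (heavily saturated), then applies the
informative-sites saturation test with the bundled critical-value model.
"""

from entsat import SimConfig, SubstModel, default_crit_model, run_saturation_test, simulate_dataset

crit = default_crit_model()

for label, mean_bl in (("slow locus", 0.05), ("fast locus", 0.65)):
    config = SimConfig(
        n_taxa=32, seq_len=500, mean_branch_length=mean_bl,
        stemminess_target=0.5, balanced=True, model=SubstModel.jc(), seed=11,
    )
    _, alignment = simulate_dataset(config)
    result = run_saturation_test(alignment, crit=crit)
    print(
        f"{label} (mean branch length {mean_bl}): "
        f"t_obs = {result.t_obs:.2f}, t_crit = {result.t_crit:.2f}, "
        f"decision = {result.decision} "
        f"(S = {result.S} informative sites, H_full = {result.H_full:.2f} bits)"
    )

print(
    "\nt_obs measures how far the per-site information content lies above the"
    "\nentropy expected at full saturation; values below the calibrated"
    "\ncritical value t_crit flag the locus as saturated."
)
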