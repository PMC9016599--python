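"""Batch-screen a directory of loci for substitution saturation.

Simulates six loci spanning slow to fast evolution, writes them as FASTA
files, and screens them with the bundled critical-value model and the
standard empirical filters (>= 30 informative sites; no nucleotide
frequency above 0.5 among informative sites).
"""

import os
import tempfile

from entsat import SimConfig, SubstModel, default_crit_model, simulate_dataset, write_alignment
from entsat.screen import report_lines, screen_loci

locus_dir = tempfile.mkdtemp(prefix="entsat_loci_")
paths = []
for i, mean_bl in enumerate((0.03, 0.1, 0.25, 0.45, 0.65, 0.9)):
    config = SimConfig(
        n_taxa=16, seq_len=400, mean_branch_length=mean_bl,
        stemminess_target=0.5, balanced=True, model=SubstModel.jc(), seed=i,
    )
    _, alignment = simulate_dataset(config)
    path = os.path.join(locus_dir, f"locus_{i}_bl{mean_bl}.fasta")
    write_alignment(alignment, path, "fasta")
    paths.append(path)

reports = screen_loci(paths, default_crit_model())
for line in report_lines(reports):
    print(line)

n_sat = sum(r.decision == "saturated" for r in reports)
print(f"\n{n_sat} of {len(reports)} loci flagged as saturated."
      "\nFaster-evolving loci (larger mean branch length) drift toward the"
      "\nfull-saturation entropy, so their t_obs drops below t_crit; the"
      "\nexpected TPR/FPR columns carry the calibration's error rates for"
      "\nthis data size.")
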