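# Methods

## The saturation model and the entropy statistic

A nucleotide alignment is treated as a matrix of states over {A, C, G, T}
with every IUPAC ambiguity code, gap (`-`, `?`, `.`), and unknown symbol
mapped to a single missing-data code; missing cells are excluded from all
counts and frequencies. Substitution saturation is modelled as the limit in
which each column is an independent multinomial draw from the alignment's
pooled base composition *p*: at that limit the alignment carries no
phylogenetic structure and attains the maximal (full-saturation) entropy.

The reference entropy is computed exactly for a multinomial sample of *n*
states: the closed form combines −log₂(n!), the categorical entropy term
−n·Σᵢ pᵢ log₂ pᵢ, and the binomial expectation of log₂(xᵢ!) per category,
summed over the finite support 0..n. Factorials are evaluated through
log-gamma; categories with pᵢ = 0 contribute nothing. The per-column
information content is I(x) = −log₂ P(X = x) under Multinomial(n_obs, p),
also via log-gamma. Both quantities are reported in bits; the test
statistic is invariant to the common log base (asserted numerically in the
suite).

The test statistic is a one-sample t of the per-site information against
the full-saturation entropy:

    t_obs = (mean(I) − H_full) / (sd(I) / √S),

with the sample standard deviation (S − 1 denominator). The sign
convention is a deliberate design choice: mean information equals H_full
at the saturation null and rises above it when historical signal
concentrates columns on patterns that are improbable under the pooled
multinomial (the mean of −log₂ q(x) over structured data is a
cross-entropy, H + KL ≥ H). Small t therefore means "close to
saturation", and a locus is flagged saturated when t_obs falls below a
calibrated critical value. A statistic of zero variance across sites is an
error unless the mean exactly equals H_full (then t = 0); fewer than two
usable sites is an error surfaced as `not_testable` by the screening layer.

### Informative-sites mode

The recommended mode restricts the test — including the composition
estimate entering both formulas — to parsimony-informative columns (≥ 2
distinct states, each in ≥ 2 sequences, missing states never counted).
This removes the influence of slowly evolving sites on the base
composition, which otherwise dominates the reference entropy for
conserved loci. The restriction has a known finite-size cost: conditioning
on informativeness excludes count patterns such as (n−1, 1, 1, 1) whose
information content is above average, so at the saturation null the
informative-sites statistic is centred slightly *below* zero for small
taxon counts (about −2 standard errors at 8 taxa; measured by the test
suite). The effect shrinks as the data matrix grows and is absorbed by the
simulation-calibrated critical values, which are derived from the same
statistic under the same restriction. The all-sites statistic is centred
at the null (also asserted in the suite) but discriminates misleading
inferences far less well, especially under model misspecification.

### Missing data

Columns are scored with their own observation count n_obs; the reference
entropy uses the modal n_obs across selected columns (ties resolved toward
the larger count), and columns with other counts have their information
shifted by H(modal n) − H(column n) so all sites are measured on one
scale. This is an identity for complete matrices, including everything the
simulator produces.

## The simulator

Trees are rooted binary dendropy trees: fully balanced (complete binary;
taxon count a power of two) or fully imbalanced (caterpillar). Branch
lengths are equal within the internal and external classes and satisfy two
targets exactly: the mean branch length over all 2n − 2 branches, and the
stemminess, defined here as the proportion of total tree length on
internal branches (a value in (0, 1); the alternative ratio reading would
place the hard, short-internal-branch regime at large values, contradicting
its use). Default factor levels for the factorial experiment are taxon
counts (8, 32, 128, 512), lengths (250, 500, 1500), branch lengths (0.05,
0.25, 0.45, 0.65), stemminess (0.1, 0.5, 0.9), constant-site proportions
(0, 0.25, 0.5, 0.75), crossed with balanced/imbalanced shape and JC/GTR+Γ
generation — the full factorial is cluster-scale and is exposed as
configuration; tests use reduced crossings.

Sequence evolution is site-independent and reversible. The rate matrix is
built from six exchangeabilities and the stationary base frequencies and
rescaled to one expected substitution per site per unit branch length.
Random GTR models draw exchangeabilities from Dirichlet(5, …, 5); base
frequencies default to uniform (a choice — the generating composition is
otherwise unconstrained) and are configurable. Among-site rate variation
uses continuous Gamma(α, α) multipliers (mean 1, default shape α = 1), and
a Bernoulli(p_invariant) mask fixes sites as constant before simulation.
Transition probabilities per branch come from the spectral decomposition
of the symmetrised rate matrix (Q = A diag(w) A⁻¹, P(t·r) = A diag(e^{w t
r}) A⁻¹), which is exact for reversible models and lets every site carry
its own rate without repeated matrix exponentials. One seeded generator
drives each simulated data set; every experiment row records its own seed,
so any replicate can be regenerated in isolation.

The simulator does **not** emulate indels and alignment error, rate
heterotachy, covarion or CAT-like composition mixtures, or lineage-specific
base-composition drift. Passing tests therefore demonstrate behaviour
under time-homogeneous, stationary, site-independent evolution; the
statistic's known blind spots under composition-mixture processes are
inherited from the saturation model itself.

## The inference engine

Calibration defines "positives" through re-estimated trees. The internal
engine is neighbor-joining (Saitou–Nei criterion with Studier–Keppler
updates, deterministic lowest-index tie-break, negative branch estimates
clamped to zero) on Jukes–Cantor-corrected distances computed over shared
non-missing sites. Observed proportion differences are capped at 0.749 so
saturated pairs receive large finite distances rather than errors — the
calibration deliberately explores saturation, where p̂ can reach the 3/4
JC limit. This distance engine replaces maximum-likelihood tree inference
deliberately: it keeps calibration self-contained and fast at desk scale.
The calibration API consumes plain record tables, so users can substitute
records scored against externally inferred (e.g. ML) trees; whether
NJ-based positives shift the calibrated thresholds relative to ML-based
ones is an open question and a known limitation. Tree comparison uses the
unrooted Robinson–Foulds distance (dendropy bipartition encoding, verified
against a brute-force bipartition oracle in the suite), normalized by
2(n − 3); branch-length accuracy is the signed proportional tree-length
error, with |error| ≥ 0.5 defining a branch-length positive.

## Calibration

The gradient experiment samples, per replicate: mean branch length
U(0.01, 0.65), stemminess U(0.1, 0.9), sequence length uniform over the
profile's range, constant-site proportion U(0, 0.8), a taxon count from
the profile's choices, and fair coin flips for balanced/imbalanced shape
and JC/GTR+Γ generation. Each replicate is simulated, analysed with both
statistics, and scored against the truth with the internal engine under JC
distances. Replicates that cannot be scored (e.g. fewer than two
informative sites) are recorded with a failure flag — never dropped — and
excluded from ROC computation.

Within each condition — a taxon count crossed with an equal-width
sequence-length bin — the ROC traverse runs over every distinct statistic
value (plus one point above the maximum), flagging "saturated" below the
threshold; positives are topology errors (normalized RF > 0) by default.
The chosen t_crit maximizes TP − FP, with ties resolved toward the
smallest threshold (the conservative choice: fewer loci flagged). The
per-condition thresholds are then regressed by OLS on √(taxon count) and
√(bin-midpoint length); the model stores the per-condition TPR/FPR table,
reports the nearest condition's rates alongside each prediction, and
raises an extrapolation flag outside the calibrated ranges (taxon counts
far beyond the largest calibrated value — e.g. in the thousands — carry
excessive uncertainty).

The bundled default calibration is desk-scale: taxa {8, 32, 128}, lengths
U(250, 1250) in four bins of width 250, 1200 replicates (seed 20210911),
roughly 100 per condition. These sizes are the package's own profile,
chosen so calibration re-runs in minutes; the published full design (10⁵
replicates, up to 512 taxa and 2000 nt) is reachable through the same API.
At the desk scale the adjusted R² of the threshold regression is
replication-limited — per-condition ROC-optimal thresholds are order
statistics of ~100 draws and carry substantial variance, and with the NJ
engine topology positives are nearly universal at 128 taxa, flattening the
length trend — so values around 0.6–0.8 are typical where heavy
replication reports ≈ 0.9. Prediction inside run_saturation_test uses the
number of sites actually entering the test (informative count in
informative mode) as the length covariate; the calibration regresses on
alignment-length bins. The two coincide for highly variable calibration
alignments and diverge for conserved empirical loci — a deliberate,
documented pairing.

For the factorial study, regressions of each outcome (topological error,
tree-length error, either statistic) use the six main effects (taxon
count, alignment length, true tree length, imbalance, stemminess,
generating model), the number of variable sites, and all fifteen pairwise
interactions of the main effects. Collinear columns are dropped with a
warning and reported as such. P-values are adjusted by Benjamini–Hochberg
(the named family of false-discovery-rate procedures; BH rather than BY,
as no dependence structure argues for the conservative variant).

## Screening

Batch screening applies two filters before testing, both evaluated on the
informative-site composition the test itself uses: at least 30
parsimony-informative sites, and no nucleotide frequency above 0.5. Either
failure — or an unreadable/malformed file — yields a `not_testable` row
with an explicit reason, so the report always accounts for every input
locus. Decisions are a pure function of (alignment, critical-value model,
filter thresholds); inputs are never modified.

## Numerical and interface choices

- Coordinates are 0-based internally; reports use 1-based human
  convention where site numbers appear.
- Entropy sums are exact finite sums (no normal or Stirling
  approximations); log-gamma throughout.
- Alignment I/O (FASTA, relaxed whitespace-delimited PHYLIP without
  10-character name truncation, NEXUS data blocks) goes through
  Bio.AlignIO; round-trips preserve labels and states, with missing
  states written as `-`.
- Critical-value models serialize to a flat key–value text file with one
  `bin =` line per calibrated condition; experiment tables serialize as
  TSV with the documented column header.
- The test suite's simulation sizes (e.g. 16-taxon, 20 kb alignments for
  engine checks; 200-replicate nulls; a 2000-replicate discrimination
  run) are the package's chosen verification scale.

## Known limitations

- The informative-sites statistic is not centred at small taxon counts
  (see above); raw t values from different data sizes are comparable only
  through the calibrated critical values.
- Under the sharp separation this statistic achieves at fixed conditions,
  the flagged fraction as a function of branch length is nearly a step:
  between-condition spacing can exceed within-condition spread by an
  order of magnitude, so intermediate flagged fractions are rare at fixed
  taxon counts and lengths.
- Critical values calibrated with the NJ engine may differ from those an
  ML engine would produce; the regression form is assumed transferable.
- Amino-acid and codon alphabets, alignment trimming, and branch-support
  computation are out of scope.
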