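# Methods

## The multiple-tube consensus model

A replicated STR study observes, for each sample × locus, a set of
independent PCR outcomes: a failure, or an unordered diploid genotype in
base pairs. The consensus genotype is the *strictly* most frequent full
genotype among positive replicates; a replicate matching only one allele is
a non-match, because the unit of observation is a whole-genotype PCR
outcome (for the same reason, half-called input rows — one allele present,
one absent — are rejected rather than guessed). The quality index is
QI = m/k over the k positive replicates, of which m match the consensus.
Amplification failures are excluded from the QI denominator and accounted
separately as the failure rate.

Ties for the most frequent genotype yield an *undetermined* call. "Most
frequent" presupposes a winner; the workflow treats a tie as a QI failure,
whose remedy is more replicates. After an extension, QI is recomputed over
**all** replicates of the current extraction, not just the new ones — the
replicates are exchangeable draws from the same extract, so discarding the
earlier ones would waste information.

The acceptance workflow is a pure state machine with thresholds
(defaults): QI ≥ 0.75 at every locus, ≥ 6 loci amplified (≥ 1 positive
PCR), ≥ 4 positive PCRs per locus, 5 initial replicates, 3 extension
replicates, and at most 2 DNA extractions. The re-extract-or-discard loop
is unbounded in the lab protocol it models; bounding it at two extractions
makes the workflow terminate deterministically. The workflow never triggers
lab work — it reports verdicts, and during simulation a driver answers them
with fresh draws.

## Error-rate estimators

With C the consensus of a cell and r a positive replicate:

* **failure** — failed replicates / all replicates at the locus;
* **ADO** — defined only against heterozygous consensus genotypes: r is a
  drop-out if exactly one allele of C is present (as a false homozygote or
  paired with a spurious allele); rate = drop-out replicates / positive
  replicates of heterozygous-consensus samples;
* **FA** — r carries ≥ 1 allele not in C; rate over all positive
  replicates;
* **overall error** — r ≠ C, each altered replicate counted once even when
  it is simultaneously ADO and FA.

Pooled rates are event-count ratios over pooled denominators, not
unweighted column means — the two differ whenever per-locus denominators
differ (e.g. the ADO denominator is restricted to heterozygous-consensus
samples, whose number varies by locus). The pooled ± is the binomial
standard error of the pooled proportion. The mean allele count across loci
is an unweighted mean ± sample (n−1) SD, since there the locus is the unit.

Two identifiability confounds are inherent to this protocol and are *not*
corrected, only documented (the synthetic generator reproduces both):

1. a slippage substitution on a heterozygote removes a consensus allele,
   so it classifies as ADO **and** FA. The ADO estimator therefore
   measures the probability that a consensus allele is lost from a
   replicate, which is ado + (1 − ado)·fa under the generator — a small
   upward shift (≈ +0.8 percentage points at the default rates) relative
   to the pure drop-out probability;
2. a slipped allele can coincide with the sample's other true allele
   (dinucleotide ladders put many heterozygotes one repeat apart), making
   the FA event invisible and slightly deflating the FA rate.

The probability that an accepted homozygote supported by k matching
positive replicates is really a heterozygote that dropped the same allele
k times is taken as ADOᵏ (independent replicates; heterozygous consensus
genotypes cannot be produced by drop-out, probability 0). This power-law
form is a deliberately simple surrogate for fuller reliability models; the
locus-level value is the maximum over samples — the weakest sample bounds
the locus.

Fragment-length effects are tested by OLS of the per-locus failure (or
ADO) rate on the midpoint of the observed allele range, with the two-sided
t-test on the slope and no multiple-testing correction. The range midpoint
stands in for the unknown true amplicon-size covariate; per-event dropped
alleles use their actual bp length in the long-vs-short drop-out test
(two-sided exact binomial against 0.5).

## Population-genetic estimators

All statistics are missing-data aware: a missing cell leaves every
denominator it would have entered.

* **uHₑ** (Nei): (2n/(2n−1))(1 − Σpᵢ²) with n typed individuals.
* **Allelic richness** by hypergeometric rarefaction to g gene copies;
  g defaults to the per-locus minimum gene count across populations, so
  every population is rarefied to the worst-sampled one locus by locus.
  At g = 2N the formula returns the observed allele count exactly.
* **uF_IS** = 1 − ΣₗH₀,ₗ / ΣₗuHₑ,ₗ (ratio of sums over polymorphic loci).
  The 95% CI bootstraps loci — the unit of replication for a multilocus
  estimate. The interval is estimate ± t₀.₉₇₅,ₘ₋₁ × SE_boot ×
  √(m/(m−1)): with m ≈ 9 loci the raw percentile interval measurably
  undercovers its nominal level, while the t-form with the standard
  bootstrap-variance correction holds it (93–97 % empirical coverage at
  F = 0.2, n = 200 across independent seed blocks). A CI excluding 0 flags
  a departure from Hardy–Weinberg proportions; no exact HWE test is
  implemented.
* **F_ST** is Weir & Cockerham's θ: per allele and locus the variance
  components a (among populations), b (among individuals) and c (within
  individuals) are accumulated and combined as Σa / Σ(a+b+c) (ratio of
  sums, not an average of per-locus ratios). The estimator is unbiased and
  legitimately negative for undifferentiated populations; duplicated
  finite samples give a small *negative* θ (≈ −1/(2n) scale), not exactly
  zero — only the biased plug-in G_ST-style estimator vanishes there.
* **Jost's D** uses Nei–Chesser unbiased H_S and H_T (harmonic-mean sample
  size), averaged across loci before forming D = 2(H_T − H_S)/(1 − H_S) —
  the across-locus-means aggregation recommended for D, rather than a
  harmonic mean of per-locus D values. Loci with < 2 typed individuals in
  either population are skipped.
* **Null alleles**: Chakraborty r = (Hₑ−H₀)/(Hₑ+H₀) and Brookfield-1
  r = (Hₑ−H₀)/(1+Hₑ) (closed forms, negative estimates clamped to 0,
  uHₑ used for Hₑ), and an EM estimator over genotype counts with a
  null-allele class: observed homozygotes split between true homozygotes
  and hetero-null carriers by their posterior odds, blanks optionally
  counted as null homozygotes (appropriate only when amplification failure
  is negligible — otherwise blanks conflate the two causes). Iteration to
  |Δ| < 1e−6, capped at 1000 rounds; the EM keeps boundary estimates
  rather than clamping.
* **Allele turnover** is the pair of set differences of observed
  (locus, allele) between the historical and modern population groups.

Distance matrices export to PHYLIP square format for network construction;
negative estimates are clamped to 0 on export only (with a warning),
because SplitsTree rejects negative input — in-memory values keep their
sign.

## The synthetic-data generator

The generator emulates a replicated historical-vs-modern study on the
standard nine-locus ISAG cattle panel (dinucleotide ladders spanning
77–260 bp with 5–16 alleles per locus; within each documented range the
allele count is met by evenly spaced rungs including both endpoints).

Truth: per locus, an ancestral frequency simplex (Dirichlet(1) unless
supplied); per population, Dirichlet drift with α = p(1−d)/d — the
correlated-allele-frequencies model in which d is approximately the
expected F_ST to the ancestral pool; genotypes drawn with
P(AᵢAᵢ) = pᵢ² + pᵢ(1−pᵢ)F and P(AᵢAⱼ) = 2pᵢpⱼ(1−F).

Replicates, per PCR: failure with probability expit(logit(f₀) + s·(mid −
mean mid)) (slope 0 recovers the homogeneous rate f₀); a surviving
heterozygote drops one allele with probability ado (the longer with
probability σ — longer fragments amplify worse in degraded DNA), with an
optional logit-linear length effect on ado; each positive amplification
then substitutes one allele by ±1 repeat unit with probability fa
(slippage). Substitution keeps the observable outcome a diploid pair;
collisions with the other true allele are allowed and produce the
ADO-indistinguishable events discussed above.

Defaults are the study conditions the package is built around: failure
0.0233, ado 0.0235, fa 0.0079 (pooled magnitudes reported for replicated
genotyping of historical cattle teeth), σ = 0.7 (a clear but not extreme
long-allele bias, consistent with longer alleles dropping more often at
most loci), divergence 0.05 (pairwise F_ST in the few-percent range typical
of related cattle breeds), five historical populations of 22/20/2/2/3
museum samples through the replicated protocol and three modern
populations of 177/61/152 typed once from high-quality DNA.

What the generator does **not** model: correlation of failures across loci
within one multiplex PCR (each locus fails independently, so "samples"
never fail wholesale the way a bad extract does), stutter-peak artefacts
and peak-height information, allele-frequency realism beyond Dirichlet
draws, and demographic history (drift is a frequency perturbation, not a
coalescent). Passing tests therefore validate the estimators and the
workflow logic under the stated error model — not the chemistry of any
particular lab's PCRs.

## Numerical and design notes

* Alleles are raw integer fragment lengths; panel-standardised binning is
  assumed to have happened upstream. Missing data is an explicit state
  end-to-end; sentinel codes (0 for GenAlEx, −9 for STRUCTURE) appear only
  in exports.
* Consensus ties and all-failed cells are undetermined, never guessed;
  undetermined cells of accepted samples become missing matrix entries.
* All simulation randomness flows from one integer seed through named
  substreams, so identical configurations are byte-identical; the
  workflow driver draws lazily per sample in a fixed order.
* Test and validation problem sizes are chosen to hold Monte-Carlo noise
  well below the tolerances being asserted while keeping the whole suite
  fast: 200 seeded studies of 49 × 9 × 5 PCRs for error-rate recovery,
  100 replicates of n = 200 for the uF_IS coverage check, n = 500 for EM
  null-allele recovery, ≥ 100 random fixtures for the brute-force oracle
  comparisons at 1e−9.

## Known limitations

* The ADO/FA identifiability confounds above mean pooled ADO slightly
  overstates, and pooled FA slightly understates, the underlying per-event
  probabilities; the estimators reproduce the protocol's published
  definitions rather than attempting deconvolution.
* The EM null-allele model attributes blanks entirely to null homozygotes;
  with non-trivial amplification failure, run it with blanks excluded and
  expect a downward-biased estimate.
* Small populations (n = 2–3 museum samples) make uHₑ/A_R noisy and their
  uF_IS CIs very wide; the pipeline reports them but draws no flags from
  them.
* The workflow's bounded two-extraction loop is a modelling choice;
  protocols that re-extract indefinitely retain more marginal samples.
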