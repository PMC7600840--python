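# Methods

This note documents the statistical models implemented in `cryptobee`,
the calibration of its synthetic-data generator, and the numerical and
design choices made where the published summary statistics left the
procedure open.

## The measurement model

Each bee contributes four raw measurements in arbitrary reticle units
(malar length and width, flagellar segments 1 and 3) from which three
dimensionless ratios are derived: MRL (length/width), MR1 and MR3
(length over the respective flagellomere). Ratios are scale-invariant,
so reticle calibration never enters the analysis; raw units are never
converted to millimetres. In all three species the malar space is
shorter than wide, so the validator warns — but does not error — when
MRL ≥ 1: the regularity is empirical, not definitional.

## Synthetic generator: what it emulates

The raw specimen table behind the study summaries is not public, so the
generator reproduces the *published distributional facts* and every
downstream method is tested against data drawn from them:

* **Cell means** per species × caste × ratio from the fitted-model mean
  table (e.g. *vagans* worker MR1 = 1.46).
* **Population SDs** recovered from the published predicted 99% ranges
  under a central-normal-interval reading: `sd = (hi − lo)/(2 z_0.995)`,
  `z_0.995 = 2.5758`. The published brackets are two-sided, which is
  what motivates the central reading over a one-sided (0%, 99%) one.
* **Sample sizes** 19/27/35 workers and 3/22/9 queens for
  *perplexus*/*sandersoni*/*vagans* — 115 bees per dataset.
* **Inter-ratio correlations** pooled across cells (MR1–MR3 0.66,
  MR1–MRL 0.75, MR3–MRL 0.77), used as the within-cell correlation of a
  multivariate normal (projected to the nearest positive semi-definite
  matrix if a user supplies an invalid one; the default is already
  positive definite). Reusing the pooled values within cells is
  conservative for the combined-measurement classifier: pooled
  correlations are inflated by between-species separation, and higher
  within-class correlation makes MR1+MR3 *less* informative jointly.
* **Hair traits** sampled uniformly over each cell's published category
  span (e.g. scutum "none–few" → {none, few} with equal probability);
  no frequencies are published. The mesipisternum entries are single
  categories ("dark-light" denotes the light-above/dark-below pattern,
  not a span). Light-form *perplexus* receive yellow T3 hairs with
  probability 0.7 — the trait is described as frequent but without a
  printed rate; the value is a one-time choice.
* **Visual labels** agree with the DNA label with probability 0.704,
  the published field-identification success rate.
* **Raw-measurement back-fill** anchors malar width at 1 reticle unit;
  only ratios are identifiable, so this loses nothing.
* **Observer replicates**: measured ratio = true ratio + a persistent
  per-observer bias (SD 0.01) + replicate noise (SD 0.03). The within
  SD comes from inverting R = σ²_bee/(σ²_bee + σ²_within) at the
  published within-observer correlation ≈ 0.95 with the pooled
  between-bee SD ≈ 0.12; the resulting replicate SDs stay inside the
  published 0–0.11 range.
* **Barcodes**: 140 bp templates with exact pairwise Hamming distances
  6 (sandersoni–vagans) and 8 (perplexus to each), chosen so percent
  identities hit the published 95.7% and 94.3% exactly (the fragment
  length is printed only as "~150 bp" and per-pair counts are not
  printed). *Perplexus* splits 11/11 into two haplotypes one base apart;
  the variant site is chosen where the species already differs from both
  others, so between-species distances are unchanged. Sequencing error,
  indels and alignment are not simulated — inputs are treated as
  aligned, ungapped and equal length.

What passing tests therefore show: the *methods* recover the published
results when the data really are normal with the published moments.
They do not show robustness to features of real specimens the generator
omits — measurement truncation at reticle resolution, non-normal tails,
within-colony correlation, regional frequency differences, or hair-trait
/ ratio dependence.

A quirk of the published tables worth knowing: the printed predicted
brackets are not exactly symmetric about the printed cell means (centres
differ by up to ~0.015, consistent with rounding). Consequently the
worker MRL population envelopes of *sandersoni* and *vagans* are only
~0.005 apart under this calibration, and the two estimated 99% envelopes
can touch on some seeds even though the observed ranges separate
cleanly; the corresponding test asserts disjoint observed ranges and
near-disjoint (≤ 0.01 overlap) predicted envelopes.

## Discriminant analysis

Classical two-class Gaussian LDA: class means, df-pooled within-class
covariance, priors equal to training class frequencies (the study cells
are unbalanced), prediction by maximum Gaussian log-posterior.
*B. perplexus* is excluded from discrimination — its hair colour is
diagnostic — so the classifier is *sandersoni* vs *vagans*, fit to
queens and workers separately.

Evaluation mirrors the study protocol: a class-stratified 60/40 split
with `ceil(0.6 n)` per class in training (rounding toward training so
small classes keep a test member), test accuracy against DNA labels,
and a 999-replicate bootstrap. The published account does not say what
the bootstrap resamples; here each replicate resamples the dataset with
replacement *within class* (preserving class counts), then re-splits,
refits and re-scores. This keeps every replicate's class balance and
yields the non-zero accuracy SDs of the published results. Replicates
whose training covariance is singular (possible only for degenerate
inputs) are redrawn and logged. Class pools are sorted by specimen id
before resampling, making estimates invariant to input record order.

## Predicted ranges and field identification

For each species × caste × ratio cell: bootstrap mean over 500
replicates, then the (0.5%, 99.5%) empirical quantiles of 10,000
N(mean, SD) draws. The simulation uses the plain sample SD, not the
standard error: the published predicted intervals are *wider* than the
observed ranges, which is impossible under an SE-width simulation — the
"SE" wording in the source protocol is taken as shorthand. Cells with a
single record report an observed range only.

The identification rule filters species by whether all three ratios fall
inside the predicted intervals for the bee's caste, then applies hair
rules in order: dark or dark-light lower mesipisternum forces
{*perplexus*} (diagnostic — the other species lack it — so it overrides
range filtering); many black scutum hairs remove *perplexus*; yellow T3
hairs rank *perplexus* first without removing alternatives. An empty
candidate set is a valid "ambiguous" outcome, and every rule firing is
recorded in the returned rationale.

## Linear model, EMMs and Tukey contrasts

The "Gaussian GLM" is ordinary least squares (identity link), treatment
coded with references *perplexus*/queen/Midwest, initially with
species:caste and species:region interactions. Term significance uses
marginal (Type II) F tests — the design is unbalanced, and Type II
coincides with Type I on balanced data; interactions with p > 0.05 are
dropped and the model refit (main effects are never pruned). On the
115-bee design the pruned model has 110 residual df.

Estimated marginal means average model predictions over region with
equal weight (matching the published "averaged over region" means), with
delta-method SEs from the coefficient covariance and t-based 95% CIs.
Pairwise species contrasts of EMMs use Tukey's HSD:
`p = P(q_{k,df} ≥ |t|√2)` under the studentized-range distribution
(scipy's implementation of the standard double-integral representation,
cross-checked in the tests against a 10⁶-draw Monte Carlo oracle to
within 0.002; for k = 2 it reduces exactly to the two-sided t-test).

## Repeatability

Pearson r with `t = r√(n−2)/√(1−r²)`. Within-observer rows correlate an
observer's first and second replicate per specimen; between-observer
rows correlate per-specimen replicate *means* of the two observers (the
source protocol does not state whether replicates were averaged first —
averaging is the choice here); SD-vs-mean rows pool both observers'
replicates per specimen. Measurements an observer did not record
produce NA rows rather than errors. Note the published t for r = 0.95
at 113 df reprints as 32.34 from the rounded r; the implementation
reports the exact value for its input.

## Barcodes

Percent identity excludes sites with a non-ACGT symbol in either
sequence from both numerator and denominator (deterministic, rather than
partially matching IUPAC codes). Haplotypes collapse identical
sequences, named H001… in order of first appearance. The network is a
minimum-spanning forest under base-pair distance (Kruskal, ties broken
by (distance, name) so results are order-independent), with candidate
edges above the connection limit discarded — a simplification of
statistical-parsimony network building in which the limit (default 10
steps, literature-typical for ~150 bp at 95%) is a parameter rather
than a computed parsimony bound. The full TCS probability calculation
is deliberately not re-derived.

## Problem sizes and determinism

Default analysis sizes match the study protocol: B = 999 bootstrap
replicates for accuracy, 500 for cell means, 10,000 simulated bees per
predicted range. The acceptance script averages bootstrap medians over
10 simulated datasets and linear-model quantities over 200 datasets —
enough that the reported stochastic values are stable to well within
their comparison tolerances. All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give identical
outputs, and per-cell streams in the range table are derived by CRC of
the cell key so results are reproducible cell-by-cell.

## Known limitations

* Calibration inherits the rounding of the published summary tables
  (means to 2 decimals, intervals to 2 decimals); small cells (3
  *perplexus* queens) make some published quantities intrinsically
  noisy.
* The generator cannot reproduce observed min/max values of the original
  specimens, only their distributional envelope.
* The barcode module assumes aligned, equal-length, gap-free fragments;
  it is a desk-scale confirmation tool, not an alignment or phylogenetics
  package.
* Hair-trait frequencies and the T3 rule rate are modelling choices, so
  hair-rule accuracy on synthetic data should not be read as a field
  error rate.
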