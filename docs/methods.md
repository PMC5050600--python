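# Methods

This package implements, end to end, the statistical pipeline of a
high-throughput phenotyping study of a *Brassica napus* diversity panel:
seedling root morphology measured in a pouch-and-wick hydroponic screen,
and leaf and seed mineral composition (the ionome) measured by ICP-MS on
plants from a polytunnel randomised block experiment.  No plant data are
distributed; a synthetic-data module generates both experiments with the
designs and variance structure the analysis assumes, so that every
downstream stage is exercised and its estimators validated by parameter
recovery.

## Experimental designs emulated

**Root screen.**  Each run holds 4 frames; a frame holds 9 drip trays in a
3 x 3 arrangement (3 tray columns), trays hold 10 or 11 pouches summing to
96 per frame, and each pouch carries one plant per paper side — 192 plants
per frame, 768 per run.  32 genotypes x 24 individuals are assigned per
run, with seeds sieved into four diameter classes (1.4, 1.7, 2.0, 2.36 mm)
and allocated 25% per class; a shortfall in one class is taken from the
next smallest.  A configurable attrition fraction (default 0.29) is flagged
as non-germinated / non-emerged / deformed / stunted in fixed proportions
(0.50 / 0.20 / 0.15 / 0.15 of the attrition), so the QC stage has real work
to do.  Five observed diameters (adding 1.18 mm) are also exposed in
configuration, since the sieve categories and observed diameters differ;
the generator uses the four sieve classes.

**Polytunnel ionomics.**  432 units (387 core genotypes + 16 reference +
29 filler lines) x 5 replicate blocks = 2,160 pots; replicates 1–3 sit in
polytunnel A, 4–5 in B; each replicate is split into 12 sub-blocks of 36
randomly allocated genotypes.  Leaf analysis defaults to 2,096 solutions
in 14 ICP-MS runs; seed analysis to 1,986 solutions in 4 runs.  Reference
genotypes are winter oilseed rape (they are normalisation lines); filler
lines are recorded as exotic/unspecified.

**ICP-MS run structure.**  Within a run, a reference-material row is
inserted after every ninth sample (interleaved positions 10, 20, 30, ...),
and two operational blanks are appended at the end of the run, so the
sample/reference sequence starts at position 1.  Raw readings are true
tissue concentrations back-converted to the solution scale
(ug/L = mg/kg x dry mass / (digest volume x dilution)), multiplied by a
within-run drift factor linear in position (amplitude default 0.05), plus
Gaussian blank background.  Reference rows carry no measurement noise by
default, which makes the drift corrector's exactness testable; a
`reference_noise_sd` knob restores realism when wanted.

## Generative trait model

Every quantitative trait is generated as grand mean + one zero-mean effect
per factor level + residual, with per-term variances given as fractions of
a total variance.  Two deliberate calibration choices:

- Per-level effects are drawn normal and then centred and rescaled so that
  their ddof=1 variance across levels equals the configured component
  *exactly*.  For factors with many levels this is indistinguishable from
  raw draws; for the few-level factors (habit: 6, seed diameter: 4) it
  removes the chi-square draw noise (3–5 df) that would otherwise dominate
  any recovery comparison.  The configured fractions are therefore the
  realized, not merely expected, decomposition, and REML recovery error
  measures the estimator, not the draw.
- The seed-diameter effect is a deterministic gradient, linear in class
  midpoint and scaled the same way, making the effect monotone increasing
  in seed size as observed in germination-paper screens.

The 'experimental' fraction is split equally across the nested design
terms (run, run.frame, ..., paper side for the screen; polytunnel,
replicate, sub-block for the polytunnel).  Lateral root number is rounded
to a non-negative integer; lengths are truncated at zero; seedlings with
no laterals get zero total lateral length.

The default fractions are the published per-trait decompositions
(genotype / habit / experimental / seed diameter, residual as the
complement so each row sums to exactly 100%).  Element concentrations are
log-normal within element — tissue ionomes span six orders of magnitude
across elements — with the variance decomposition applied on the log10
scale and geometric means chosen to reproduce the reported concentration
ranges (leaf As 0.01 to K > 50,000 mg/kg; seed Cd 0.01 to K > 13,000
mg/kg) and leaf pair ratios of the right magnitude (Ca:Sr ~ 500:1,
K:Rb ~ 3,000:1, S:Mo and Zn:Cd within the reported ranges).

Two consequences worth knowing.  First, components are generated
per-trait, so a *derived* trait (TRL = PRL + LRL) inherits the
deterministic seed-diameter gradients of both components coherently while
their random effects add independently; its realized seed-diameter share
is therefore somewhat larger than either component's.  Recovery targets
use the per-trait generator directly (a TRL column generated under the TRL
decomposition), where the configured share is the truth.  Second, elements
are generated independently, so the strong cross-element correlations of
real ionomes (e.g. leaf Ca with Sr) are *not* emulated by default; the
correlation stage is validated against constructed shared-latent-factor
data instead.  Passing tests demonstrate correct estimators under the
stated variance structure, not biological covariance structure.

## ICP-MS quality control

Fixed stage order, every filtering step logged with counts:

1. **Blank subtraction** — per run and element, subtract the mean
   operational blank reading; negatives are retained so the censoring rule
   sees them.
2. **Drift normalisation** — per run and element, a piecewise-linear factor
   interpolated between bracketing reference readings, normalised to the
   run-mean reference reading; samples divide by the local factor, samples
   outside the bracket use the nearest factor, runs with fewer than two
   references are left uncorrected with a warning.  The cited
   reference-material method publishes no equations; piecewise-linear
   normalisation is this package's documented choice, and it exactly
   removes the simulator's linear drift (reference CV drops to zero), which
   pins the oracle.  Correction is applied wherever reference rows exist,
   for both tissues.
3. **Unit conversion** — mg/kg = ug/L x dilution x digest volume (L) /
   dry mass (g).
4. **LOD** — 3 x SD of the blank solution readings, converted with a
   notional dry mass (leaf 0.200 g, seed 0.015 g).
5. **Element retention** — the printed exclusion lists are the defaults
   (leaf drops Ag, Co, Cr, Ni, Pb, U, V of 28 monitored, retaining 21;
   seed drops the monitored subset of As, Co, Cr, Fe, Ni, Pb, Se of 20,
   retaining 15 — Cr and Pb on the seed list were never monitored in
   seed).  An automatic rule (mean < k x LOD, default k = 2) is available
   because the study's own numeric threshold is unstated.
6. **Half-LOD substitution** — cells strictly below the element LOD become
   LOD/2 (standard left-censoring convention); applied before the outlier
   screen, following the processing narrative's order.
7. **Outlier screen** — one-sided and non-iterative: cells strictly above
   the global arithmetic mean + 5 SD for that element are set missing as
   suspected contamination.

Per-cell flags (raw / blank_corrected / drift_corrected /
half_lod_substituted / outlier_removed) are mutually exclusive, and cell
counts are conserved: raw = final + outliers removed + excluded-element
cells.

## REML variance components

Models: roots `(run/frame/column/tray/paper-side) + habit + seed size +
genotype`; composition `habit + genotype + polytunnel +
polytunnel/replicate + polytunnel/replicate/sub-block`; all terms random
(habit and seed size included, despite their few levels — their shares
carry wide sampling error, which the synthetic recovery runs make visible),
intercept the only fixed effect, nesting `a/b` expanded to `a + a.b`.

Estimation is residual maximum likelihood on Henderson's mixed-model
equations: 5 expectation-maximisation warm-up iterations, then
average-information updates with element-wise EM fallback wherever an AI
step would leave the parameter space.  Because EM converges only linearly,
each component's geometric tail is periodically extrapolated (Aitken);
components are truncated at zero — pinned, with the remaining terms
refitted — when negligible (< 1e-6 of trait variance) or monotonically
shrinking below 0.3% of trait variance, which is far below the
integer-percent reporting precision.  Convergence requires a relative
parameter change below 1e-8 for every component above 0.01% of trait
variance; non-convergence raises an error carrying the last iterate.
Correctness is pinned by three oracles in the test suite: the closed-form
balanced one-way ANOVA estimator (agreement to 1e-6), statsmodels MixedLM
on unbalanced one-way data, and MixedLM variance components on crossed
two-factor data.

Percent of variance = 100 x component / (sum of components + residual);
the vector sums to 100 by construction and is rounded only at report time.

**Genotype means.**  Root and leaf traits: genotype enters as a fixed
factor (cell-means coding) with the remaining terms random at their REML
variances — generalised least squares means, which equal arithmetic means
on balanced data and beat them under unbalanced block effects.  Seed
traits and the seed-weight traits: arithmetic per-genotype means.  The
composition model is used for the leaf mean structure; the study also
mentions a replicate-based leaf mean model omitting polytunnel, and either
can be expressed through `VarianceModelSpec`.

## Ratios, correlations, discriminant analysis

**Translocation ratios.**  For pairs S:Mo, Ca:Sr, K:Rb, Zn:Cd:
leaf ratio = [A]leaf/[B]leaf, seed ratio likewise, translocation index =
seed ratio / leaf ratio.  Genotypes with any missing or non-positive input
yield a missing result with a recorded reason.  Habit summaries use
median, quartiles and 95% whiskers, matching the box-plot convention.

**Correlations.**  Pearson r on pairwise-complete genotype means for every
pair of the 44 traits (2 seed-weight + 6 root + 21 leaf + 15 seed).
44 x 43 / 2 = 946 pairs — the study's text says 945; the arithmetic says
946 and the package emits 946.  Two-sided p-values via the t transform, no
multiple-testing adjustment (raw p-values are the reporting convention
followed).

**Discriminant analysis.**  Wilks' Lambda = det(W)/det(T) with W the
pooled within-group and T the total cross-product matrix.  Forward
selection adds, at each step, the candidate minimising Lambda of the
augmented set, ties broken by input order; singular candidates are
skipped.  Allocation is by maximal linear discriminant score with pooled
within-group covariance and equal priors (the groups are highly
unbalanced, 163 winter OSR vs 7 semiwinter; proportional priors are a
config option); specificity is the resubstitution fraction of each habit
allocated back to itself.  Genotypes missing any active trait are dropped
listwise per step, with counts logged.  Canonical variates come from the
generalised eigen-decomposition of between- against pooled within-group
scatter, scaled to unit within-group variance; the 95% confidence circle
radius for a group mean is sqrt(chi2(2 df, 0.95) / n_group) and group
polygons are convex hulls of the scores.  These allocation conventions
(priors, tie-breaks, incomplete-row handling, circle formula) are explicit
package choices; the original analysis software's defaults are not
published.

## Problem sizes and numerical defaults

The analysis scripts default to a 7-run root screen (5,376 positions,
~5,000 analysed seedlings after truncation; 224 genotypes) and the full
polytunnel (2,160 pots, 2,096 leaf + 1,986 seed solutions).  The
variance-recovery checks simulate 5,000 seedlings and require the
seed-diameter share within +/-5 percentage points of the generating values
(44% for TRL, 35% for PRL) in at least 8 of 10 seeds.  REML tolerance
1e-8, maximum 500 iterations; Wilks' Lambda selection tolerance 1e-15 on
ties; correlation pairs need >= 3 complete observations.

## Known limitations

- Between-element covariance, seasonal/weather effects, pot-level nutrient
  dynamics and image-analysis error are not modelled; simulated attrition
  is independent of genotype and position, whereas real attrition is not.
- The drift model is linear within run; the corrector is exact for it but
  only approximate for curvier real drift (the piecewise-linear form
  handles smooth nonlinearity between references).
- Variance shares for 4–6-level factors (habit, seed diameter) are
  estimable but carry large sampling error in any single experiment; the
  recovery tests quantify this under the stated conditions only.
- CRM recovery is computed but not validated against certified ranges (no
  certified materials ship with the package).
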