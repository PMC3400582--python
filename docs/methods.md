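# Methods

This note records the models, parameter choices and numerical conventions
behind `wormscreen`, and what the synthetic-data validation does and does
not establish about real plates.

## Image quantification

**Pipeline.** Each well is processed as a stitched image (four row-major
2×2 tiles). Well detection blurs the bright field (Gaussian, σ = 5 px
default) and thresholds at `L*F`, `L` from Otsu's method, `F = 0.9`; the
largest connected component is kept and hole-filled, so the mask is a
single region covering the illuminated well. Worm segmentation bottom-hat
filters the bright field (morphological closing minus image, disk
footprint, radius 8 px default) — worms absorb light and sit darker than
the well interior, so the filter converts them into bright peaks on a flat
background while cancelling smooth illumination gradients. Otsu's method
thresholds the filtered pixels inside the well; connected components with
area outside `[size_min, size_max]` (defaults 150–4000 px²) are discarded
as debris or clumps.

**Otsu level and effectiveness.** The level maximizes between-class
variance. Candidate thresholds are the midpoints between consecutive
distinct sample values when there are ≤256 of them, otherwise 256 evenly
spaced levels over the observed range; ties break toward the lower
threshold. Effectiveness is Otsu's separability measure
η = σ²_between(L)/σ²_total, computed from the exact pixel partition at the
chosen level (not from binned moments), so it agrees bit-for-bit with an
exhaustive search on small samples. A constant sample is degenerate: η = 0
and no exception.

**Fallback rule.** When η < 0.7 (strict; at equality Otsu is retained) the
threshold is replaced by a robust outlier rule: foreground = pixels above
`median + k·MAD` with SD-consistent MAD (×1.4826) and k = 3. The rule is
shift-equivariant and parameter-light; when MAD = 0 the rule reduces to
"above the median", and an empty foreground is flagged rather than raised.

**Measurement.** Background is the median GFP over well pixels outside
worm objects; the well value is the median over all worm pixels of
(GFP − background), clipped at 0. A config switch (`object_statistic =
"object_median"`) instead takes the median of per-object means; the
pixel-median form is the default. Condition values are the arithmetic mean
of per-well medians over replicates, with per-well values retained for the
t-test. Quantification is performed within bright-field-derived objects
(not GFP-thresholded ones), and the worm-analysis region is eroded by the
bottom-hat radius + 1 px because the well rim is itself a dark-to-bright
transition that the filter would otherwise highlight.

## Hit calling

Fold decrease = mean(control)/mean(RNAi); significance from a one-tailed
two-sample t-test of control > RNAi. Pooled-variance Student's t is the
default (small equal-size replicate groups; the classic spreadsheet/SPSS
convention), with Welch available by flag. Zero-variance groups with equal
means return p = 0.5. A hit requires fold strictly > 1.5 and p ≤ 0.05
inclusive; no multiple-testing correction is applied anywhere, by design.
A non-positive RNAi mean renders the fold unquantifiable; such cells carry
the `>>>` sentinel and the hit call rests on the p criterion.

## Clustering

Uncentered correlation similarity s = Σxᵢyᵢ/√(Σxᵢ²·Σyᵢ²), distance 1 − s
∈ [0, 2], undefined (error) for zero profiles. Agglomeration is unweighted
average linkage (UPGMA) maintained by the Lance-Williams size-weighted
update; tied minimum distances break toward the pair holding the lowest
original indices, and within a merge the child containing the lower
original index comes first. Leaf order follows merge order with the
lower-index subtree first — the Cluster 3.0 display convention — with no
optimal-leaf-ordering. GTR node records carry correlation = 1 − merge
height; CDT rows are reordered to leaf order with GID identifiers.

## Lifespan analysis

Mean lifespan is the Kaplan-Meier restricted mean: the area under the
product-limit curve up to the largest observed time, computed via
`lifelines`; deaths tied at a scoring day are processed before censorings
at that day. On uncensored cohorts this equals the arithmetic mean of
death times exactly (property-tested). Derived quantities, per RNAi clone:

* Δ lifespan = 100·(mean_RNAi − mean_vector)/mean_vector, on wild type;
* percent extension = 100·(mean_mutant − mean_N2)/mean_N2 within the same
  RNAi treatment;
* Δ extension = 100·(ext_RNAi − ext_vector)/ext_vector.

Δ extension is deliberately the *relative change in percent extension*,
not the relative change in day-gain: the two candidate formulas disagree,
and only this form reproduces the packaged table's printed cells (e.g.
pas-3/isp-1 −70%, phi-50/eat-2 −72%, elt-2/daf-2 −33%). Classification
uses unrounded values against thresholds of −15%, −50% and −200/3 %
(classes nested by construction); displayed columns round half away from
zero. This reproduces all five packaged summary counts (12/16/25/5/20)
including the borderline nekl-2/eat-2 cell at −67.4% against the 2/3
cutoff. "Reduces wild-type lifespan by less than 10%" is read as
Δ lifespan > −10%, so lifespan increases qualify. Classification rests on
the 15% threshold alone (no additional per-strain p-value gate), which is
what reproduces the packaged counts. No log-rank testing: all comparisons
are on means, matching the screen's design.

A few printed Δ-extension cells differ by one percentage point from
recomputation off rounded means (e.g. ima-3/eat-2 prints −85% where the
rounded means give −84%), presumably because the original arithmetic used
unrounded underlying means; those cells are not asserted.

## Synthetic data: what it emulates

The generators define the validation conditions. Worms are random
bounded-curvature backbones (heading random walk, step 2 px) dilated to a
tube; defaults are 50 animals/well (the screen's density), 60 px
backbones, 8 px body width, 4 px minimum separation, placed with rejection
sampling inside the well disk (bounded retries, then an overcrowded-well
error). Intensities are 16-bit-style: bright well interior (30000) on a
dark surround (2000), worms 12000 counts darker, a smooth illumination
gradient (1500 across the well) for the bottom-hat to cancel, and GFP =
500 background plus 1000 × induction × suppression on worm pixels, with
additive Gaussian noise on both channels. Debris are dark disks below the
size filter, placed disjoint from worms and from each other so each
planted disk is individually sub-threshold. In the noiseless limit the
pipeline's fold estimate equals the planted fold exactly, because the
median is taken over identically-valued worm pixels.

Survival cohorts are Weibull (default scale 20 d, shape 4 — a realistic
wild-type-like mean of ~18 d with moderate spread) multiplied by strain
and RNAi factors, snapped to the alternate-day scoring grid (deaths
observed at the next even day), with uniform-before-death right-censoring
at probability 0.1. The grid produces heavy ties, exercising tie handling.
qPCR tables anchor the target at reference Ct + 4 and encode the fold as a
−log₂(fold) Ct shift with per-well Gaussian Ct noise.

**What passing does not show.** The synthetic worms are smooth tubes on
clean backgrounds: no touching/overlapping animals, no autofluorescent gut
granules, no vignetting or tile seams, no partial wells. Recovery rates
here bound what the pipeline can do under its own model assumptions, not
performance on real plates; the raw screen images were never deposited, so
printed fluorescence values are not reproducible and planted-truth
recovery is the appropriate validation.

## Problem sizes and tolerances

Validation sizes were chosen to give tight Monte-Carlo error at modest
cost: 100 simulated plates (2 conditions × 4 replicate wells, 12
worms/well, 110 px wells) for the 5%-noise fold-recovery check (every
plate within 10%; observed max error ≈ 0.6%); 50 random ≤64-pixel samples
for the exhaustive Otsu comparison; 50 random 8×7 score matrices for the
brute-force UPGMA comparison; 1000 random uncensored cohorts for the
restricted-mean identity; and n = 1000 cohorts (6 replicates, against an
n = 60000 reference) for Δ-extension recovery within 3 Monte-Carlo SE.
The acceptance script uses 30 noisy plates and reports observed values
rather than asserting them.

## Known limitations

* The well-boundary heuristic assumes one dominant bright region; plates
  with multiple bright artifacts outside the well would need masking.
* The outlier fallback's k = 3 is a convention; very sparse worms with
  heavy-tailed backgrounds may need tuning.
* Leaf ordering matches the merge-order convention, not any
  optimal-leaf-ordering refinement, so trees from other software may
  display the same topology with different leaf sequences.
* The Δ-extension formula divides by the control extension, so it is
  unstable for mutants whose control extension is near zero; inputs with
  ext_vector = 0 raise rather than return a value.
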