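# Methods

This note documents the models, parameter choices and numerical conventions
behind `lysoquant`, and what the simulators do and do not emulate.

## Imaging geometry

**Nuclear segmentation.** Intensity thresholding of the nuclear-stain
channel; the default method is Otsu because it is parameter-free and its
threshold is recorded in the mask provenance for reproducibility. Connected
components below `min_area` (default 50 px²) are discarded. A constant
channel yields zero objects with a warning rather than an error, so empty
fields flow through batch runs.

**Cell masks.** One cell per nucleus, grown by seeded watershed over the
thresholded cytoplasm channel on the distance-to-nearest-nucleus map. This
uses the cytoplasm intensity only to delimit the cell footprint and splits
shared blobs by proximity, which is the deterministic choice when the
cytoplasm stain is flat. A nucleus without surrounding cytoplasm signal
keeps its nuclear extent as the cell and is flagged. Border-touching objects
are removed (and the operation is idempotent) before any per-cell counting.

**Concentric rings.** Ring bands are defined on a signed Euclidean distance
measured from the layer of nuclear-mask pixels that have a 4-connected
background neighbour (distance 0 on that layer, negative inside, positive
outside). Ring k covers distances in `(-inset + (k-1)·width,
-inset + k·width]`; the half-open bands make rings disjoint by
construction. Defaults: inset 3 px, width 6 px (≈ 2 µm at 0.33 µm/px),
4 rings. The boundary-layer convention was chosen after measuring
discretization error on rasterized disks: across nuclear radii 10–30 px it
reproduces the analytic annulus areas within ~3–4%, whereas conventions
based on the raw inside/outside distance transforms miss individual rings
by 6–20% on small disks. In crowded fields every pixel reachable by more
than one nucleus is assigned to the nearest nucleus by plain
distance-to-mask, ties to the lower label; pixels inside a nucleus always
belong to it. Nuclei shallower than the inset are flagged `ring1_partial`;
ring systems clipped by the image border are flagged `border_clipped` but
retained, since dropping them would bias crowded fields.

**Proximity score.** Arithmetic ring means of the organelle channel; score
= ring-1 mean divided by the average of the outer ring means. Missing outer
rings are excluded from the average with a flag; a zero or undefined outer
average gives a missing score, never ±inf. The score is a ratio of means,
hence invariant to global intensity rescaling; no background subtraction is
applied by default. One figure-legend phrasing describes the denominator as
the marker intensity "in the rest of the cytoplasm"; the methods-grade
definition (outer rings 2–4) is implemented and the legend phrasing treated
as shorthand. Scores are computed per nucleus (multinucleate or contacting
cells are not merged). Inference follows the SuperPlot convention: per-cell
scores are display data; statistics consume per-experiment means.

## Puncta and ratios

**Detection.** White top-hat with a disk footprint (default radius 5 px)
removes any structure broader than the disk — flat background, slow
gradients and the rim of fluorescence that accumulates at cell edges —
before thresholding (default 15 AU, set explicitly in every pipeline run),
connected-component labelling and an area filter (defaults 3–400 px²). The
commercial analysis software that inspired this stage does not publish its
kernel or thresholds, so these are configuration with simulator-calibrated
defaults. Each detection is assigned to the cell containing its (rounded)
centroid; detections outside whole cells are dropped.

**Positivity.** A cell is positive at ≥ `min_puncta` detections (default 3,
the lysosomal-leakage convention). The percentage is over all whole cells
in the field; the per-positive-cell count list is reported alongside. Zero
cells is an error; zero positive cells is a valid 0%.

**Two-channel ratios.** Per-object mean intensity in each channel over the
object's pixel support, then the ratio. For pH ratiometry the objects are
detected on the pH-insensitive channel so detection is unbiased by the
quantity being measured; for tandem-reporter puncta the per-cell mean ratio
is also reported because cells are the replication unit there. Zero
denominator means a flagged missing ratio. No background subtraction is
applied before ratios.

**Grubbs filter.** Two-sided, iterative: remove the most extreme point
(ties broken by first index) while `G = max|x−mean|/SD` exceeds the
critical value `G(n, α) = (n−1)/√n · √(t²/(n−2+t²))` with
`t = t_{1−α/(2n), n−2}`; stop below n = 3 or at zero variance. The default
α = 1e−4 matches the published use for per-replicate lysosome-ratio
cleaning; the filter must be applied per replicate, never to pooled
replicates. Because the bound is Bonferroni-style, the per-pass removal
probability under the null is slightly below α, which the test suite checks
by simulation.

## Plate calculators

Absorbances are blank- and reference-wavelength-corrected in a dedicated
preprocessing step; negative corrected values clamp to zero (the source
protocols are silent on negatives, and clamping keeps percentages in
[0, 100]). Cytotoxicity is `100·medium/(medium+lysate)`; a non-positive
total yields a flagged missing value. PI death warns (not errors) below the
500-cells-per-slide sampling convention. The flux ratio normalizes the
degradable/non-degradable reporter ratio to its value at the first time
point, making 100% the t = 0 baseline by construction and the result
invariant to rescaling either luminescence series. Hydrolase leakage
divides both cytosolic and total Vmax by their matched LDH activities
before the percentage, correcting extraction efficiency and cell number.
Synergy excess subtracts vehicle death from the combination and from each
single drug before comparing — without vehicle correction, spontaneous
death would be counted twice in the additive expectation; this choice is
recorded in output metadata. AUC uses the trapezoid rule on the native
sampling grid (exact for piecewise-linear curves, additive over abutting
intervals), with strictly increasing times required.

## Lipidomics

**Quantification.** `mol = intensity / IS_intensity × IS_amount` per class,
response factor 1 (no correction factors are assumed). Species whose class
lacks a standard are excluded and listed in provenance. mol% normalizes
each sample column to 100 over all monitored species, internal standards
excluded.

**Filter.** A species is kept if its median mol% across the replicates of
at least one sample type (treatment group) reaches 0.0001 mol%. The
source phrasing is ambiguous between in-any-group and in-all-groups
exclusion; the retain-if-any-group-passes reading is implemented because it
never discards a species that is reliably measurable in some condition.
The filter is idempotent and monotone in the threshold.

**Differential abundance.** Per species, ordinary least squares on
`quantity ~ group + batch` (fixed effects) over the two groups being
compared; p-value from the t-test of the group contrast; q-values by
Benjamini–Hochberg over all species tested; significant at q < 0.05. The
model is fit on the linear mol% scale and the log₂ fold change is taken
from the fitted group means averaged over batches — for balanced designs
this equals the raw group-mean ratio, so a purely multiplicative batch
effect leaves the estimate untouched (exactly so in the noiseless case),
which the tests verify. A `log_scale` option fits log₂ quantities and reads
the fold change off the coefficient instead. Empirical-Bayes variance
moderation is deliberately not implemented: with nine data points per group
the ordinary contrast t-test is fully specified, its null calibration is
verified by simulation, and a moderated path would ship untested; the
design matrix is checked for rank and confounded factors are reported by
name. Rank-deficient designs, groups with fewer than two replicates and
non-positive fitted means (log fold change undefined) are all surfaced
explicitly rather than silently patched.

**Classes and saturation.** Class mol% is the sum of member species (so
classes partition the 100%); categories group classes as diacyl-GPL (PA,
PC, PE, PG, PI, PS and their ether forms), lyso-GPL (the eight LP*
classes), sphingolipid (Cer, HexCer, SM), sterol (Chol, CE) and other (BMP,
DAG). Class- or category-level differential analysis is the species model
run on the aggregated table. The double-bond profile of a category reports
the mol% share carried by each total-acyl-double-bond count and the
mol%-weighted mean double bonds per lipid. Drug uptake is
`(intensity/IS_intensity × IS_amount) / total lipid mol`.

## Statistical primitives

Welch's unpaired t-test (two-sided, fractional Welch–Satterthwaite df
retained) and the one-sample t-test, with explicit conventions for
zero-variance degeneracy: equal means give p = 1, unequal means p = 0 with
a degenerate flag, never NaN. No family-wise correction is applied to
figure-style multi-endpoint comparisons (that is how the assays are
reported); only the lipidomics arm uses BH. Per-experiment means are the
replication unit — a 3-experiment design contributes exactly 3 values per
condition regardless of how many cells were imaged. Both tests agree with
an independent R `t.test` oracle to 1e−10 on 100 frozen fixtures. One
caveat the suite documents by simulation: at n = 3 per group Welch's test
is intrinsically conservative (null rejection ≈ 3.6% at nominal 5%), so
calibration is asserted at n = 10 per group, with an anti-conservativeness
guard at n = 3.

## What the simulators emulate — and what they don't

The image generator renders disk nuclei and cytoplasms with isotropic
Gaussian puncta, a Gaussian PSF, flat background and additive Gaussian
noise. Juxtanuclear clustering is a mixture: each punctum falls in a band
abutting the nucleus with probability κ, else uniformly in the cytoplasm —
the published description of clustering is qualitative, so κ is a
generative knob, not a calibrated fit to any figure. Real fields differ in
ways the simulator deliberately omits: non-convex touching cells, uneven
illumination, camera shot noise and gain, 3D defocus, and puncta that
overlap below the resolution limit. Passing tests therefore establish that
the pipeline recovers truth under its stated geometric assumptions, not
that those assumptions hold for any particular microscope.

The lipidome generator uses the study design the statistics assume — three
groups × three independent experiments (batches) × triplicates, nine data
points per group — with a default composition spanning the 23 monitored
classes (~300 species), a total lysoGPL share near 0.55 mol%, and default
planted treatment effects that emulate the reported direction of change
(lysoGPL roughly doubled, SM up, Cer down, diacyl-GPL unsaturation shifted
down). Noise is multiplicative log-normal (mean 1, CV 0.1 by default) and
batch effects are per-species log-normal factors (σ = 0.25 on log₂),
because a batch factor common to all species would cancel exactly under
mol% normalization. Isotope overlap, in-source fragmentation, response
nonlinearity and missingness are not modelled; absolute quantification is
exact by construction at zero noise, which is what makes the round-trip
test meaningful.

The plate generator produces exact signal models (fractional LDH split,
exponential reporter decay against a constant mutant, binomial PI counts)
plus additive Gaussian noise; it does not model edge effects, evaporation
or drift.

## Problem sizes

The validation suite and the acceptance script use: 18 + 18 fields of 25
cells (450 cells per arm) for the proximity null and clustering sweep; 100
noiseless ten-cell scenes (1000 cells) for puncta recovery; 1000 null
species and 200 planted-effect species for differential calibration; 100
random vectors for the Grubbs oracle; 10⁴ draws for t-test calibration.
These sizes give binomial/SEM resolution comfortably inside every asserted
tolerance while keeping a full run on one CPU to about a minute.

## Known limitations

* Watershed cell splitting is proximity-based; intensity valleys between
  touching cells are ignored.
* Puncta detection has no sub-pixel localization or deconvolution; two
  puncta closer than the PSF merge.
* The differential model assumes homoscedastic residuals per species on
  the fitted scale; heavy-tailed intensity noise is only covered via the
  log-scale option.
* LD₅₀ / dose–response fitting is out of scope, as are raw-spectrum
  processing and peak identification (the lipidomics stage starts from
  identified species intensities).
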