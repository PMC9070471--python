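# Methods

## REIMS burn-event processing

A raw run is an ordered list of centroided scans with strictly increasing
scan times; the total ion current (TIC) of a scan is the sum of all its ion
intensities. Burn-event detection uses the median TIC of the run as the
baseline (robust as long as burns occupy a minority of scans) and reports
maximal contiguous windows with TIC above `threshold_factor × baseline`
(default 5), discarding windows shorter than 3 scans.

Each detected window is converted to the canonical processed trace: 35
scans, burn spanning 12 scans, maximum at scan 18 (1-based). The trace is a
fixed Gaussian shape — weights `w_k ∝ exp(−(k − μ)²/2σ²)` at positions
k = 1…35 with μ = 17.8 and σ = 3.0 — scaled so its sum equals the window's
total TIC (conservation is exact). The off-integer centre is deliberate: an
even, 12-scan burn span cannot bracket an integer peak symmetrically, so
the centre sits 0.2 scans below 18, putting scans 12–23 inside the burn
while the argmax stays at 18. The burn-level threshold is the midpoint
between the 12th and 13th largest trace values, so exactly 12 scans exceed
it by construction. An alternative would derive σ per event from the
detection threshold, but that is not solvable for every event and would
make the canonical shape event-dependent; a fixed shape reproduces every
stated property of the trace for every input.

The same Gaussian, evaluated at each window scan's position mapped linearly
onto the 12-scan burn span, weights the window's scans into one consensus
spectrum (rescaled to the window TIC) which is then lockmass-corrected and
binned.

Lockmass correction shifts all m/z by a single constant so the most intense
centroid within ±0.5 Da of 554.2615 ([M−H]⁻ of leu-enkephalin, the
standard negative-mode reference) lands exactly on the reference; a missing
reference peak leaves the spectrum unshifted with a warning. The correction
is idempotent. Binning sums intensities into half-open 1-Da bins over
[50, 1200) by default (configurable down to 0.1 Da); TIC normalization
divides by the vector sum. Bin width and normalization are declared
defaults — acquisition software conventions vary and desk-scale analyses
need ~1000 features, not 10⁵.

## Histology quantification

The tissue mask takes the blue channel (highest tissue/slide contrast),
finds its modal value (ties broken towards the brightest, since the mode is
the blank slide), and masks pixels strictly below it; 8-connected
components smaller than 64 px are removed and holes smaller than 256 px
filled (scale-free defaults, overridable). The collagen index
`R/50 − G/20 + B/30` is applied to raw 0–255 values: white scores 0.85,
pink/magenta/dark-red collagen hues score above 1.0 (the nominal
threshold). The published index ranges (−0.75…1.0 non-collagen, 1.0…1.75
collagen) are treated as descriptive of stained-tissue pixels, not analytic
bounds — no single linear scale reproduces them exactly. The elastin index
is inverted brightness `1 − (R+G+B)/765` (elastin stains grey-to-black),
thresholded at 0.5. Thresholds use strict `>`, so boundary pixels count as
unstained. Area fractions are pixel-count ratios against the mask — no
spatial calibration enters.

The collagen threshold can be calibrated against the adjacent PSR section:
PSR collagen is classified by red dominance (R exceeds both G and B by a
30-level margin, configurable — the rule used by the original desktop tool
is unpublished), and the VVG threshold is grid-searched over nominal ± 0.75
in 0.01 steps to match the PSR area fraction, ties resolved towards the
nominal value. Threshold-variation errors report the area gained/lost when
the threshold moves ±δ (default 0.05): because the fraction is
non-increasing in the threshold both errors are non-negative, and they are
large exactly where the index histogram is dense at the cut-off.

## PLS-DA workflow

Labels are one-hot encoded; a PLS2 regression (NIPALS, via scikit-learn's
`PLSRegression`) of the centred/scaled spectra onto the centred indicator
matrix provides continuous class scores, and the predicted class is the
argmax. Zero-variance columns receive unit scale and contribute nothing.
Evaluation repeats (default 50, per-repeat seeds at fixed offsets from the
master seed) a stratified 80/20 split; the component count (1…10) is chosen
per repeat by stratified 2-fold CV on the training part only, taking the
smallest count at the minimal misclassification error. Splits stratify by
tissue type at the sample level; with one piece per patient (the generator
default) this is also patient-level, and `pieces_per_patient` exists
precisely to let users study the leakage that patient-level duplicates
would introduce. VIP uses the standard definition with SSY_a the Y-variance
explained by component a; Σ_j VIP_j² = p is an algebraic identity and is
asserted in the tests on every fitted model. Refinement keeps features with
VIP mean and median strictly above 1 across repeats; an empty selection is
an error, not an empty model. The ROC reduces the 3-class problem to FL
vs rest (the most distinct tissue in this design; the reduction is a
declared choice) and sweeps the continuous FL score; its trapezoid AUC
equals the Mann–Whitney rank statistic.

## Cluster stability

FL samples are clustered by Ward linkage on Euclidean distances of their
TIC-normalized binned spectra. For support values, the m/z features are
resampled with replacement to `round(p·r)` columns at ten scales
r = 0.5…1.4 (1000 replicates per scale by default, 100 in fast mode), the
samples are re-clustered, and each original node's bootstrap probability
BP_r is the fraction of replicates containing its exact leaf set.
Resampling features — not samples — keeps every leaf present in every
replicate, which is what makes exact leaf-set matching well defined; it is
also the convention of the reference R implementation of this method. The
probit fit `Φ⁻¹(1−BP_r) = v√r + c/√r` is weighted by the delta-method
binomial variance of BP and uses only informative scales (0 < BP < 1): a
node saturated at BP = 1 (or 0) across all scales gives a constant probit
that the two-parameter fit would split arbitrarily between v and c,
assigning AU ≈ 0.6 to a perfectly supported node; such nodes short-circuit
to AU = 1 (or 0) with `fit_ok = False`. AU = 1 − Φ(v−c). Stable clusters
are the maximal disjoint nodes with AU strictly above 0.90, found
top-down; the root (trivially recovered in every replicate) is never a
candidate, and uncovered leaves become singletons.

## Non-parametric statistics

All tests are two-sided. Kruskal–Wallis uses the tie-corrected H with a
chi-square p on k−1 df. Dunn's post hoc z statistics divide mean-rank
differences by `sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j))`;
p-values are Holm-adjusted within each variable across the three pairwise
comparisons (a flag allows family-wide adjustment). Holm adjustment is the
step-down rule: sort ascending, multiply the i-th smallest by m−i+1,
enforce monotonicity, cap at 1. Mann–Whitney reports U = min(U_a, U_b) with
an exact two-sided p by full enumeration of group assignments (valid under
ties) when both groups have ≤ 8 observations, and the tie- and
continuity-corrected normal approximation otherwise.

## Synthetic-data generator

The generator defines the study conditions: 10 FL / 10 FP / 6 TL samples,
three latent FL sub-groups (round-robin assignment: sizes 4/3/3), one
sample per patient per tissue type.

**Feature table.** Variables are log-normal (guaranteeing positivity) with
FP/TL medians chosen at plausible magnitudes for aortic media (G′ 25 kPa,
G″ 8 kPa, collagen 90 µg/mg, elastin 130 µg/mg, GAG 18 µg/mg, age 57 y,
indexed aortic size 12.3). The FL group is shifted down on the log scale by
1.5 log-SD on G′, G″ and GAG and 0.75 log-SD on elastin (scaled by
`class_effect`), encoding the degraded false-lumen phenotype. These are
generator defaults, not estimates of any cohort.

**Spectra.** Templates live directly in binned space: Gaussian peaks
(σ = max(2 Da, bin width)) on a 30-peak backbone concentrated in the
lipid-rich 600–900 m/z region, plus 8 class-marker peaks per tissue type
and 6 marker peaks per FL sub-template in a wider 550–1050 band. Peak
centres are allocated on a jittered slot grid, which guarantees a minimum
separation without rejection sampling and records the marker bin of every
planted peak for downstream verification. Samples apply per-bin
multiplicative log-normal noise with CV `noise_cv` (default 0.2, a typical
technical-plus-biological spread for ambient MS intensities) and are TIC
normalized. With all effects and noise at zero, every sample is the
identical vector.

The FL sub-templates are planted *symmetrically with respect to Ward's
merge cost*. Ward merges the pair of tight sub-groups minimizing
`(n_i n_j/(n_i+n_j)) d_ij²`; if one pair is systematically cheapest, its
union — not only the planted sub-groups — appears in essentially every
bootstrap replicate and is itself reported as a stable cluster. Because TIC
normalization couples marker mass to the entire spectrum, equalizing
nominal marker energies is not enough; the generator instead balances the
realized pairwise merge costs of the noise-free normalized centroids by a
short fixed-point iteration on the marker amplitude scales. The default
`subcluster_effect = 2.0` makes sub-phenotype markers about twice a typical
backbone peak — pronounced, clearly-resolved sub-groups whose dendrogram
nodes stay together under feature resampling.

**Burn events.** One jagged elevated-TIC window (per-scan TIC uniform in
0.6–1.4 × ten-fold baseline) flanked by baseline scans at least as long as
the event, so the median-TIC baseline is well defined; per-scan spectra are
random centroids rescaled to the target TIC exactly.

**Stained sections.** An elliptical tissue footprint on a constant
blank-slide background (so the modal blue value is exact); within it the
requested collagen and elastin fractions are painted pixel-exactly with
palettes chosen to land on the correct side of every decision rule
(collagen hues: index > 1, darkness < 0.5; elastin greys: darkness > 0.5,
index < 1; counterstain and background: neither). The PSR companion paints
the same footprint's collagen fraction (± a configurable adjacent-section
jitter, default 0.01) in saturated reds.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: chemically meaningful lipid annotations or
isotope patterns; peak-shape drift, baseline chemical noise and
batch/instrument effects; inter-patient correlation beyond the optional
duplicate-pieces mechanism; histological texture, stain variability,
uneven illumination or colour bleed (real sections violate the clean
palette separation by design); and cohort-level clinical covariate
structure. The perfect classification metrics on default synthetic
conditions reflect the planted separability, not expected performance on
surgical tissue.

## Problem sizes and defaults

Default runs use 1-Da bins (1150 features), 50 evaluation repeats, and
1000 bootstrap replicates per scale; the `fast_mode` flag of the pipeline
drops these to 10 repeats and 100 replicates for quick iteration. The
bundled cohort sizes keep the complete analysis in the minutes range on a
single CPU. With 3–4 sections per FL cluster, the exact Mann–Whitney
two-sided p cannot fall below 2/35 before adjustment — the pipeline
reports the comparisons regardless, which is the honest behaviour at this
cohort size.

## Known limitations

- The canonical-trace geometry (35/12/18) is a re-implementation of a
  described output contract, not of any proprietary algorithm's internals.
- AU p-values inherit the asymptotics of the multiscale bootstrap; with 10
  leaves and saturated nodes the reported 1.0 means "recovered in every
  replicate at every scale", not a calibrated probability.
- The exact index-scale behind the published collagen ranges is
  unknowable from the description; the raw-0–255 convention here is a
  declared choice that preserves the printed threshold semantics.
- Exact Mann–Whitney enumeration is O(C(n_a+n_b, n_a)) and is capped at
  8 + 8 observations; beyond that the normal approximation applies.
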