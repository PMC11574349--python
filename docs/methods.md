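# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `optoquant`. The package quantifies live-imaging
optogenetics experiments on the Dorsal (DL) morphogen system of the
early *Drosophila* embryo: reversible nuclear export (LEXY-type tags)
and light-induced degradation (BLID-type tags) of a transcription
factor, read out through nuclear fluorescence, MS2/MCP transcription
reporters, FRAP, and fixed-embryo stainings.

## The synthetic embryo generator

Every analysis stage is driven and validated by a generator that
renders the experiment classes with full ground truth. The generator
is first-class, tested code — its contracts (determinism, signal
conservation, closed-form trace shapes) are asserted in the suite.

**Scene.** An elliptical embryo on a dark background; nuclei are
soft-edged disks (error-function edge, width 0.5 px) on a hexagonal
lattice with Gaussian jitter (s.d. 10% of spacing), keeping a 4-px
margin from the embryo outline as real nuclei keep a cortical membrane
margin. Defaults mirror common confocal acquisition for this
preparation: 512×512 px at 0.29 µm/px every 25 s for population
movies; 0.100 µm/px at one frame per 2 s for FRAP; nucleus radius
2.6 µm, spacing 6.5 µm (interphase-14 scale). Pixels are quantized to
16 bit on write.

**Nuclear level model.** Each nucleus follows a piecewise
single-exponential level model, continuous at segment boundaries:

* *none* — constant baseline;
* *export* — baseline before light; during light an exponential decay
  at rate `k_e` toward a floor of 10% of baseline (nuclear signal is
  never observed to vanish completely under export); after light-off a
  recovery `I(t) = I_ss − α·e^(−β t)` with `I_ss` the baseline and `α`
  fixed by continuity. The decay-phase functional form is a modeling
  choice: only the recovery phase is ever fitted, so the analysis does
  not depend on it.
* *degrade* — exponential decay at rate `k_d` during light and for a
  configurable 2 further frames after light-off (degradation ends with
  a short delay), then a hold with no recovery.

Baselines are modulated by a DV Gaussian `A·exp(−d²/2σ²)+B` in
DV-position fraction (image-axis fraction for movie views, arc-length
fraction along the periphery for cross-sections). The cytoplasm is
rendered so the embryo-total signal is conserved under export (the
protein relocalizes) and decays under degradation (the protein is
destroyed); the conservation is asserted to <2% over the light window.

**Transcription spots.** Nuclei inside a gene's domain (a band of the
embryo minor axis; `sna`-like central band by default, sized to hold
≈60 nuclei at the default geometry) are active with probability 0.95
and carry one isotropic Gaussian spot (σ 0.3 µm) at a fixed jittered
intranuclear position. Spots gate off when the simulated nuclear level
stays below 50% of that nucleus's baseline for 2 consecutive frames,
and gate back on symmetrically — the threshold and delay are
phenomenological simulation parameters, not mechanistic claims. With
the default rates this makes export-mode spot counts collapse during
light and recover afterwards, and degrade-mode counts collapse without
recovery.

**FRAP.** Nuclei inside a circular ROI ramp linearly to `I_ss − α`
over the bleach frames and recover as `I(t) = I_ss − α·e^(−β t)` with
the clock starting at the bleach-end frame; nuclei outside the ROI
hold their steady level.

**Noise.** Gaussian read noise (default s.d. 300 a.u. for reporter
movies → spot SNR 10; 100 a.u. for FRAP), optional Poisson
resampling, optional salt-and-pepper replacement (≤5% of pixels, half
0 / half max), clipped to [0, 65535]. All randomness flows through one
`numpy` generator; identical (config, seed) gives byte-identical
output.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no optical PSF beyond the isotropic
Gaussian spot, no z-dimension, no photobleaching outside the FRAP ROI,
no nuclear divisions or flows, no spatially correlated background, no
chromatic offsets. Detection thresholds that are exactly right for the
generator's intensity scale will always need per-dataset calibration
on real movies, as they did in the original workflow.

## Focus (transcription-site) detection

Per frame: 3×3 median filter (salt-and-pepper removal) → 51×51 median
as a background estimate, subtracted → Gaussian blur (σ 1 px) →
threshold → drop 1-px objects → drop objects touching the image border
→ drop objects whose centroid lies outside the embryo mask → keep only
objects with ≥1 *raw* pixel above a second, higher threshold. The low
threshold finds foci plus noise; the high raw threshold removes the
noise. The embryo mask comes from the max-projection over time:
Gaussian blur, midpoint threshold, morphological closing, discard
components <100 px, keep the largest.

The detection threshold rises logarithmically through nc14 (nuclear
background increases over the cycle):
`thr(f) = thr_low·(1 + c·ln(1 + (f − f₁₄)/n₁₄))`, `c` user-set, 0 by
default. This specific functional form is this package's definition
and is recorded in output metadata.

Implementation notes: the large-kernel median uses a sliding-histogram
rank filter on the (already 16-bit-quantized) image — an order of
magnitude faster than a sorting median at 51 px and identical up to
input rounding. Default thresholds (low 500 a.u. processed, high
2600 a.u. raw) are calibrated to the default synthetic movie's
intensity scale; on real data they are empirical per-dataset settings.
Counting is instantaneous per frame; series are normalized by the
starting count (flagged, not normalized, if the start count is zero).

## Expression-domain area

Centroids pooled over a nuclear-cycle window (duplicates kept) are
cleaned by a per-axis MAD filter: remove a point iff strictly
`|y−med_y| > k·MAD_y` or `|x−med_x| > k·MAD_x` with unscaled MAD and
k = 2; an axis with zero MAD removes nothing. The 2-D MAD rule is not
uniquely defined for point clouds; the per-axis form was chosen for
transparency and is configurable. The convex hull of the survivors
gives the area (0 for <3 non-collinear points; `scipy.spatial`
Qhull, verified exactly against the shoelace formula), and the
between-cycle difference `area(nc14) − area(nc13)` cancels
embryo-orientation differences. Cycle boundary frames are user input
(staging is visual in practice).

## Nuclei segmentation, traces and tracking

**Segmentation** is LoG-based: `gaussian_laplace` at σ 4 px
(population view) or 10 px (high zoom) responds negatively just inside
each bright edge; filling those closed contours recovers the blobs;
watershed on the distance transform splits touching nuclei; gates then
remove non-nuclei: area within [0.25, 4]× the median, inscribed radius
≥0.5× the median (strips thin embryo-edge fragments), mean intensity
≥0.5× the median object mean (strips enclosed cytoplasm patches).
Objects with strong internal contrast are shrunk to their bright core
(largest component above the 5th/95th-percentile midpoint) so
embryo-boundary tails do not shift centroids. Mean intensities are
measured on 1-px-eroded masks to avoid boundary partial-volume mixing.

**Carry-forward.** When a frame detects nothing — or detection
*collapses* below 25% of the previous frame's count, which is what
actually happens when blue light inverts nuclear/cytoplasmic contrast —
the previous frame's segmentation is reused and intensities are
re-measured on the current frame.

**Embryo ellipse and midline.** Max-projection → Gaussian blur →
normalized threshold at 0.005 → opening/closing → least-squares
ellipse fit to the largest component's boundary. The normalization
references the median of the blurred image (the off-embryo pedestal)
rather than the raw minimum: with additive detector noise a
min–max normalization would put the 0.005 level inside the noise
floor. This assumes the embryo covers less than half the field. The
midline is the major-axis line; only nuclei within ±100 px of it
(inclusive) enter the population trace, reported per frame as
mean ± s.d. across nuclei (missing, not zero, when no nuclei qualify).

**Tracking.** Matching cutoff = the radius of a single nucleus
(median √(area/π) of the first frame). Greedy one-to-one matching by
ascending centroid distance (ties broken by lower label), gap closing
by searching up to 10 frames back from the last known centroid (no
motion extrapolation). Track filters: remove tracks missing *any* of
the first 10 frames, any of the last 10 frames, or holding fewer than
half of all frames — the stricter "any" reading of the end-window
rule, configurable.

## Recovery kinetics

`I(t) = I_ss − α·e^(−β(t−t₀))` is fitted by trust-region nonlinear
least squares with the analytic Jacobian, bounds `I_ss, α, β ≥ 0`,
parameter tolerance 1e−10, and initialization `I_ss₀` = mean of the
final 10% of the window, `α₀ = max(I_ss₀ − I(t₀), 0)`,
`β₀ = 2/window duration`. `t₀` is the first post-bleach (or first
post-light-off) frame; `β` is reported per minute regardless of
acquisition interval. Traces with numerically zero variance raise a
flat-trace error (β unidentifiable). Fits are unweighted.

FRAP analysis tracks the nucleus nearest the bleach-ROI center at
frame 0; when the bleached (dark) nucleus drops out of the
segmentation, its last known pixel mask keeps being measured rather
than jumping to a neighbor. Rate-constant comparisons use the pooled
(Student) two-sample t-test — the unequal-variance form does not
reproduce conventional significance levels for the 3-vs-3 rate
comparisons this pipeline reports.

## Fixed-embryo geometry

**Ring segmentation.** Coarse LoG (σ 20 px) responds negatively inside
the bright peripheral ring of nuclei; the filled band's outline gives
the outer boundary, its hole the inner one; ellipses are least-squares
fit to both and averaged parameter-wise (orientation averaged on the
doubled angle, weighted by eccentricity, since near-circular fits have
arbitrary tilt). A solid object is rejected by checking that the
band's hole is dark, not bright.

**DV profile and gradient.** Intensity is sampled along the mid
ellipse within ±20 px of the periphery along the local normal (~2 px
radial steps), averaged into angular bins indexed by arc-length
fraction ∈ [0,1), with 0 at the ventral-most point. The gradient is
fitted as `A·exp(−(x−µ)²/2σ²) + B`; the profile is rotated so the
empirical maximum sits at 0.5 before fitting to avoid circular wrap
bias, and µ is mapped back. The additive offset `B` absorbs background
staining. The symmetric-with-offset form is this package's choice of
parameterization.

**Domain widths.** The expression channel is thresholded (Otsu if no
threshold is given), components below 25% of the largest are dropped
as noise, the mid ellipse is sampled at 4096 angles (≈0.09°), maximal
angular runs inside the mask become domains, crossing angles are the
midpoints between the last-outside and first-inside samples, and each
run's arc length (adaptive quadrature of
`∫√(a²sin²θ + b²cos²θ)dθ`, relative tolerance 1e−11) is normalized by
the perimeter. Multi-domain patterns report every width; pooling
across domains and embryos is the caller's step.

## Statistics

* Pooled two-sample t-test (`df = n_a+n_b−2`), two-sided.
* One-way ANOVA with Tukey HSD p-values from the studentized-range
  distribution; for k = 2 these reduce exactly to the pooled t-test.
* Sample size: smallest integer n per group whose *exact*
  noncentral-t power (noncentrality `|Δ|/σ·√(n/2)`) reaches the
  requested power; bracketed by the normal approximation, then walked
  to the exact minimum.
* Cross-replicate series averaging: modified Akima ("makima") cubic
  Hermite interpolation onto a common grid restricted to the overlap
  interval (grid step = median sampling interval), then pointwise
  mean ± s.e.m. Modified Akima does not overshoot step-like data,
  unlike natural cubic splines — asserted in the suite.

## Problem sizes used in the shipped checks

The acceptance script and end-to-end tests run: 100-frame 512×512
reporter movies (one per illumination condition) for detection
metrics; a 100-frame 256×256 drift movie with a scripted 5-frame
occlusion for tracking; 570-point FRAP traces (2 s over 19 min) at the
reported amplitude scales; 50-seed noise replicates for gradient
recovery; 1000 random point sets for the hull oracle. These sizes were
chosen so the full pipeline demonstrates each guarantee at realistic
data scales while remaining quick to run on a laptop.

## Known limitations

* Segmentation gates assume a majority of well-formed nuclei per
  frame (median-referenced); fields dominated by debris would need
  absolute gates.
* The embryo-ellipse normalization assumes the embryo fills less than
  half the field of view.
* Tracking handles no divisions or large jumps (> one nucleus radius
  per frame); it is built for single-interphase analysis.
* The export-phase decay form (exponential to a 10% floor) is a
  generator convention; only recovery-phase parameters are ever
  estimated from it.
* Domain-width crossing resolution is bounded by the 4096-angle
  sampling (≈2.4·10⁻⁴ of the perimeter) and by the sharpness of the
  thresholded expression boundary.
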