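# Methods

This note documents the models behind `capillux`: what each stage assumes,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Line-scan geometry and flux arithmetic

A kymograph is a 2-D array with rows = spatial pixels along the scanned
line (row 0 = superior edge) and columns = scan index at the scanner rate
(default 15 450 scans/s; the hardware is nominally a 15.4–15.45 kHz
resonant scanner and the rate is configurable).  All indices are 0-based;
windows are half-open `[start, start + W)`, so a cell on a window edge
belongs to the later window.  Per-second flux tiles the recording with
non-overlapping 1-s windows; the command-line default starts the first
window at t = 1 s, mirroring the practice of counting the second recorded
second.  Instantaneous flux divides the scan rate by the gap between
consecutive markers and sits at the fractional pair midpoint (kept
unrounded; placement only affects plotting).  Velocity uses the fixed
7.25 µm RBC length over the dwell time; with the default scanner rate a
dwell of one second gives 7.25 µm/s exactly.

Smoothing for contrast enhancement is an isotropic Gaussian with
σ = 7.5 px in both axes; the filter used before manual counting is
described only as "spatiotemporal", so a single σ is applied to both.

## Synthetic kymographs

**Arrival process.** Cell arrivals follow a cardiac-modulated rate
λ(t) = F·(1 + d·sin 2πf_c t) with defaults F = 100 cells/s (the population
mean), f_c = 4.5 Hz (4–5 cardiac cycles per second under anesthesia) and
d = 0.2.  Two physical facts shape the gap distribution: cells travel
single file, so no gap can be shorter than the dwell time τ = L/v; and
observed capillary traffic is strongly sub-Poisson (nearly nose-to-tail at
high occupancy).  Gaps are therefore drawn as τ plus a gamma variate
(shape 6) whose scale is set so the conditional mean gap equals 1/λ(t);
the long-run rate then equals λ and the realized trains respect the
single-file constraint.  A plain inhomogeneous Poisson mode
(`enforce_single_file=False`) exists for comparison.

This choice matters for a known estimator property: the pair-based mean of
instantaneous flux exceeds the windowed flux by approximately
CV²(gap) + d²/2 (Jensen's inequality plus rate-weighted pair sampling).
With exponential (Poisson) gaps at the study's occupancy the bias is tens
of percent and the two flux readouts could never agree; with the gamma
gaps and modest modulation the two agree to within a few percent on 20-s
recordings, which matches the observed convergence of cumulative
instantaneous flux toward the windowed value after several cardiac
cycles.

**Rendering.** Cells are dark ellipses on a bright background (inverse
cell contrast of phase-contrast detection): horizontal extent = dwell
scans = round(L/v·f), vertical extent = lumen/(pitch·cos angle).  The
vessel band is drawn slightly dark and displaced per scan by the
eye-motion trace (sinusoid + linear drift; defaults keep peak eye velocity
two orders of magnitude below the 1100 µm/s default RBC speed, the only
constraint available).  Gaussian sensor noise (σ = 0.02 of the unit
background) is added last.  Exact parachute cell geometry, photon noise
and the optical point-spread function are not modeled; a stalled vessel
renders a static dark cell band and yields no markers.

Defaults: 20-s captures, 0.71° line (pixel pitch 0.38 µm/px at 64 px),
lumen 4.1 µm, RBC speed 1100 µm/s (mid-range of reported capillary RBC
speeds; occupancy F·τ ≈ 0.66 at the mean flux, peak < 1 under
modulation).  Validation rejects modulation depth ≥ 1, lumen ≥ 7 µm,
sub-Nyquist scan rates and peak occupancy ≥ 1.

**Synthetic detector.** `detect_cells_synthetic` (Gaussian σ = 2 px, Otsu
threshold on the inverted image, 8-connected components, minimum area
4 px) exists only to close the loop on simulator fixtures; it is not a
model of human grading.  Components spanning > 25 % of the recording are
treated as a stationary stalled cell; merged touching cells are split by
area multiplicity against the median component area.

## Lumen diameter

Three widths from 15-ms boxes are averaged; on fixtures the boxes sit on
the three temporally earliest non-overlapping cells and the width is the
full vertical extent (max − min occupied row + 1) of the thresholded dark
trace.  Conversion to µm uses the pixel pitch — for real data the
age-resolved magnification table (µm/degree vs postnatal week) is
interpolated linearly and clamped at its ends, because the growing mouse
eye changes image magnification; the shipped single-row table
(34 µm/degree) is a placeholder and synthetic fixtures always carry their
own pitch.  The cos(angle) correction and the µm conversion commute, so
their order is immaterial.  Diameter recovery on fixtures is accurate to
about one pixel pitch for angles up to 45°.

## Eye motion

Blocks of `block_scans` columns (default 16; tests use 64 = 4 ms, which
still oversamples the < 5 Hz eye-motion band by > 50×) are averaged into
1-D spatial profiles and registered to the first block by maximizing the
cross-correlation of mean-subtracted profiles with parabolic sub-pixel
refinement.  The first block is the reference (keeps the estimator linear
and seed-independent); a flat profile registers as zero shift with a
warning flag.  Displacement is mean-zeroed (the study plots displacement
about zero), emitted per block and interpolated per scan; velocity is the
first difference times the sampling rate, the only reading of
"displacement × scan rate" consistent with units.

## OCT segmentation

B-scans are piecewise-constant axial models: vitreous 0.05, retina
0.05 + contrast (default 0.55), a 6-px RPE band at 0.95, choroid 0.12,
with fractional boundary rows rendered by partial-pixel mixing and
multiplicative Gaussian speckle (clipped at zero; Rayleigh statistics are
not modeled).  Defaults give a 110-px retina at 2 µm/px = 220 µm.

The boundary graph uses a centered first difference along the axial axis,
sign-selected by polarity and min-max normalized per B-scan (making the
segmentation invariant to affine intensity rescaling).  Edge weight
`2 − (g_a + g_b) + w_min` with `w_min = 1e-5` follows the standard
graph-segmentation formulation; the phrase "difference of local gradient
values" admits several readings and this is the established one.  Virtual
terminal columns attached at cost `w_min` to every row of the first and
last column let the path start and end anywhere.  Dijkstra runs on a
sparse matrix (scipy.sparse.csgraph); output is deterministic for a fixed
construction order, and the boundary is the mean path row per column (a
path may occupy up to two rows per column under 8-connectivity).

The ILM (strongest dark-to-bright transition) is segmented first over the
whole image; the OS–RPE search is restricted to rows ≥ 3 px below the ILM
path, which prevents both paths collapsing onto the same edge.  A constant
image raises an error rather than returning a silent boundary.  Expert
per-column overrides are applied by `review_segmentation`, which re-checks
the ILM < RPE invariant and flags corrected columns.  Thickness is
averaged over the full B-scan/cube; repeated cubes of one imaging session
are averaged into the session value.

## Cohort generator

Two groups of 9 mice carry weekly glucose and weight (postnatal weeks
3–18), biweekly capillary visits (weeks 5–17, 10 capillaries/mouse) and
4-weekly OCT sessions (weeks 4–20).  Group parameters default to the
study-scale values: glucose 461.51 ± 93.74 vs 180.79 ± 39.43 mg/dL,
flux 99.85 ± 58.53 vs 102.77 ± 65.12 cells/s, diameter 4.2 ± 0.6 vs
4.1 ± 0.5 µm (range 2.8–7.0), thickness 213.7 ± 3.79 vs 221.06 ± 5.79 µm,
week-to-week capillary CV 27 %/32 %, stall probability 1.5 % per visit,
weights 23.45 ± 3.53 / 24.80 ± 3.87 g.

Hyperglycemic glucose from week 5 onward is drawn truncated above the
250 mg/dL cutoff (so the two-consecutive-readings designation holds by
construction) and censored — pinned, not resampled — at the 600 mg/dL
meter cap; weeks 3–4 use a rising-phase distribution around the cutoff.
Capillary flux combines a per-capillary baseline with a diameter coupling
of 45 cells/s/µm (reproducing the weak flux–diameter regression,
R² ≈ 0.15) and multiplicative week-to-week variability at the printed CV;
the residual between-capillary SD is derived so the marginal SD matches
the printed population SD.  Truncated-normal draws solve for the location
that preserves the requested mean after truncation.  Quality indices are
drawn from a marginal with 96 % of scans at grade 3–5.  Thickness
measurements are independent normal draws per session; mouse-level random
effects are not modeled, so the thickness comparison behaves as if
sessions were independent — adequate for calibration checks, optimistic
for real designs.

What passing tests show: the arithmetic, the segmentation and the
statistics are correct on data matching these generative assumptions.
What they do not show: performance under real optical blur, non-Gaussian
speckle, grader idiosyncrasies, irregular heart rates, or correlated
longitudinal structure.

## Statistics

"Student's test" is the pooled-variance two-tailed unpaired t test
(Welch available via `equal_var=False`).  Skew and excess kurtosis use the
standard bias-adjusted (G1/G2) formulas.  Stall percentages are truncated
to two decimals (9/589 → 1.52 %).  Bland–Altman uses the grader mean as
reference (no established ground truth exists for manual flux counts) and
plain differences in cells/s; limits of agreement are bias ± 1.96 SD, the
bias CI is the t interval, and the LoA CIs come from exact two-sided
normal tolerance factors evaluated at the 2.5 % and 97.5 % confidence
quantiles.  The exact factor k(n, coverage, confidence) is found by
root-finding on the noncentral-χ² formulation and verified by Monte-Carlo
coverage; a Howe closed-form approximation (`method="howe"`) is used where
many factors are needed.  Degenerate zero-variance inputs collapse the
limits onto the bias with zero-width CIs and a flag.  No multiple-testing
correction is applied anywhere — a deliberate choice, since these are
descriptive single comparisons; callers doing many comparisons should add
their own.

## Problem sizes

Tests and the acceptance script use 2-s kymographs (32–64 spatial px) for
flux recovery (50 seeds × {25, 100, 400} cells/s for the exact
ground-truth route, 5 seeds each for the detector route), 20-s arrival
simulations for the instantaneous/windowed agreement, 100 × 220 px B-scans
(20 speckle seeds), 100-seed Bland–Altman Monte-Carlo at 38 capillaries ×
5 graders, and 5–40 seeded cohorts for calibration and significance
checks.  These sizes make the whole suite run in well under a minute of
simulation time while leaving every statistical tolerance comfortably
resolved.
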