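# Methods

## Equivalent-circuit model and fitting

The sensor system is modelled as three lumped elements in series/parallel:
the culture medium as a resistor R_med (ohm), and two parallel RC branches —
the attached cell monolayer (R_cell, C_cell) and the passivated electrode
stack (R_el, C_el). The model deliberately lumps the whole monolayer into
one branch; no per-cell microscopic model, constant-phase element or Warburg
element is included. Im(Z) is stored as the mathematical imaginary part
(negative for this capacitive topology); presentation layers may plot −Im.

**Complex nonlinear least squares.** A sweep is fitted by minimizing the
stacked (Re, Im) residuals over all frequencies with
`scipy.optimize.least_squares` (trust-region reflective, xtol = ftol =
gtol = 1e-10, ≤ 5000 evaluations). Two numerical choices matter:

* *Modulus weighting* (default): each Re/Im pair is divided by the measured
  |Z(f)|. |Z| spans orders of magnitude across 5–100 kHz, and unweighted
  residuals would let the low-frequency points dominate. Unit weighting is
  available via `FitOptions(weighting="unit")`.
* *Log-parameter space*: free parameters are optimized as logarithms, which
  enforces strict positivity without bound handling and equalizes scales
  between ohm-sized resistances and nanofarad-sized capacitances.

**Initialization**, when the caller supplies none: R_med from Re at the
highest frequency (both capacitors short), the series total from Re at the
lowest frequency, the branch resistance split 2:1 between cell and
electrode, and each capacitance placed so its branch corner frequency sits
at the frequency of extremal Im.

**Branch identifiability.** The two parallel RC branches are algebraically
exchangeable. They are disambiguated physically, never by magnitude-based
relabeling: the electrode does not change over a cultivation, so
`fit_series` determines (R_el, C_el) once — either supplied directly or
fitted from a cell-free calibration sweep with the cell branch pinned to a
negligible resistance, which makes the assignment unambiguous — and holds
them fixed at every timepoint. Successive timepoints are warm-started from
the previous fit. Spectra are sorted by frequency on construction, so fits
are invariant to input point order.

## Image segmentation and the concentration estimator

Stages, in order, on a float image in [0, 1]:

1. RGB→grayscale with BT.601 luma weights (0.299, 0.587, 0.114) — a fixed
   convention for bit-reproducibility.
2. 7×7 median filter (reflect padding): removes speckle and small
   impurities while preserving edges.
3. CLAHE, clip limit 0.01, 8×8 tile grid: local contrast normalization so
   dim and bright cells become comparably detectable.
4. Canny, Gaussian σ = 1.4 px, hysteresis thresholds at fractions (0.1,
   0.2) of the maximum Sobel gradient of the σ-smoothed image. Expressing
   thresholds relative to the gradient range makes them survive CLAHE's
   renormalization; both fractions are configurable.
5. Morphology: 2 dilations with a radius-1 disk, hole filling, 2 erosions
   (reflect-style borders: dilation treats outside as background, erosion
   as foreground, so cells cut by the field of view keep their area). The
   closing only needs to seal the small gaps Canny leaves in cell outlines.
   A wider closing (e.g. radius 3 × 3 iterations, ~9 px) was evaluated and
   rejected: it bridges the gaps *between* neighbouring cells and inflated
   coverage by tens of percentage points at 30–60% confluence on
   ground-truthed renders.

Surface coverage is 100 × foreground / total pixels. Replicate images per
timepoint are summarized as mean ± sample SD (ddof = 1; 0 for a single
image). Concentration is estimated as c_t = c_i·SC_t/SC_i — valid below
confluence, where covered area grows linearly with attached cell count —
and a reporting helper rounds to two significant figures (half to even) for
a×10^b presentation. SD is reported on the same percent scale as the mean.

## Phase annotation

The classifier is an explicit algorithmic stand-in for by-eye annotation
and says so in its output metadata. The primary signal (C_cell if present,
else coverage) is smoothed with a 3-sample moving average; backward
interval slopes are compared against a flatness threshold of 5% of the
signal range per 12 h, making labels invariant to affine rescaling. A
forward-only state machine (attachment → lag → exponential → stationary →
dying) walks the slope signs; transitions require the new sign to persist
for two consecutive intervals so one noisy slope cannot flip a phase, and a
steep change inside the first 2 h is labelled attachment (cells settling
onto the sensor). The centered smoothing window looks ahead and the
backward difference lags; the two roughly cancel, localizing change-points
to about one sampling interval.

Cross-modality agreement uses Spearman rank correlation, computed
separately for t ≤ cutoff and t > cutoff (default 60 h, the nominal dying
onset): the two signals live on unrelated scales (farad vs percent) and the
claim under test is about shared trends. Windows with fewer than three
shared timepoints are reported as undefined rather than fabricated.
Modality grids are merged by linear interpolation of coverage onto the
impedance timepoints, with no extrapolation.

## Synthetic data: what it emulates and what it does not

**Growth curve.** Four phases, continuous at every junction: baseline
capacitance through `lag_end` (12 h default); a logistic segment rescaled
to start exactly at baseline and reach exactly `c_cell_max` at
`stationary_start` (48 h); plateau until `dying_onset` (60 h, matching the
nutrient-exhaustion onset the cultivation design targets); exponential
decay toward baseline after. Defaults: baseline 2 nF (settled but sparse
cells), maximum 20 nF (confluent monolayer), logistic rate 0.15 h⁻¹, dying
rate 0.05 h⁻¹. Cell density is taken proportional to the capacitance
excess over baseline.

**Spectra.** The forward model is the lumped circuit itself, with
independent relative Gaussian noise on Re and Im (default 1%, a plausible
instrument-level figure; no noise model is asserted by measurement data, so
the level is swept in tests rather than trusted). Reference circuit:
R_med = 100 Ω, R_cell = 1 kΩ, R_el = 500 Ω, C_el = 100 nF — both branch
corner frequencies sit in or near the 5–100 kHz band, which is what makes
the five parameters identifiable from one sweep. Each bundled experiment
includes a cell-free calibration sweep (medium + electrode only) for
electrode pinning.

**Images.** Elongated soft-edged ellipses (fibroblast-like aspect ratio
2–5, minor semi-axis 10–16 px at 256×256) with interior texture, placed
with overlap-rejection bias (relaxed as the field crowds) until mask
coverage lands within one percentage point of the target, on a
gradient-shaded background with Gaussian noise (σ = 0.005) and cell/
background contrast 0.30. These conditions describe a well-illuminated 10×
brightfield/phase image — the regime in which a classical Canny pipeline
is applicable at all. Cells stay fully inside the frame so every outline
is closed. No photorealism is attempted (no phase halos, no optical PSF,
no camera fixed-pattern noise); consequently, passing tests demonstrate
correctness of the pipeline mechanics and its behaviour on
known-truth area fractions, not performance on any particular microscope's
images. Density maps to coverage linearly (baseline 7%, maximum 60% by
default) with saturation at 90% confluence.

**Post-dying imaging failure.** With `debris_mode` on, timepoints after the
dying onset receive scattered high-contrast fragments excluded from the
truth mask, with a per-timepoint random area budget (uniform 5–65%), and
the attached-cell footprint collapses at three times the capacitance dying
rate (dead cells detach before the lumped capacitance fully decays). Both
effects together reproduce the observed failure mode: coverage estimates
become erratic after ~60 h while the impedance readout keeps tracking the
decline. Fragments are drawn larger than the median kernel; smaller ones
would be filtered away and could not corrupt anything.

All generators are bit-reproducible under a fixed seed; per-timepoint seeds
are spawned from one master generator.

## Problem sizes and numerical conventions

Default analyses use 30 log-spaced frequencies per sweep, hourly or 4-hourly
time grids over 0–96 h, 256×256 renders (192×192 in multi-run divergence
studies) and three images per timepoint. Masks are {0,1} rasters, row-major,
origin top-left; mask PNGs store foreground as 255. Tables are CSV with 15
significant digits, so write/read round trips preserve 12+ digits.
Degenerate inputs fail loudly: non-positive circuit parameters or
frequencies, empty masks or image groups, inverted Canny thresholds and
missing electrode constraints all raise errors naming the offending field.

## Known limitations

* The circuit is a lumped description; it cannot separate cell-layer
  changes from medium conductivity drift beyond what R_med vs R_cell/C_cell
  absorb, and it assumes the electrode branch is truly constant.
* The concentration estimator inherits every bias of coverage: it is blind
  to multilayering, cell spreading and shape changes, and is meaningless
  once debris dominates.
* The phase classifier assumes the canonical phase order and will not
  re-enter a phase (e.g. a second growth spurt after re-feeding is outside
  its vocabulary).
* Fitting near-degenerate spectra (cell branch vanishing) leaves C_cell
  weakly constrained; `fit_series` mitigates this with warm starts, and the
  converged flag plus residual norms should be inspected for early, sparse
  timepoints.
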