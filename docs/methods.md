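# Methods

## The phasor model

An emission spectrum I(λ) sampled on a detection range [λ_min, λ_max] maps to
the spectral phasor (G, S) by its first-harmonic Fourier projections over the
phase axis θ(λ) = 2π(λ − λ_min)/(λ_max − λ_min). The defaults are
λ_min = 400 nm, λ_max = 700 nm and 300 samples (1 nm bins). Only the first
harmonic is used: the hardware analogue is a filter pair with a single
sine/cosine period across the range, and higher harmonics have no filter
counterpart here.

Key properties the implementation relies on (and the tests verify):

- **Convexity** — any nonnegative spectrum lands in the closed unit disk;
  modulation 1 only for a single-bin (monochromatic) spectrum, 0 for a flat
  spectrum.
- **Linearity** — the phasor of a mixture is the intensity-fraction-weighted
  combination of the component phasors, exact to arithmetic precision. This
  survives detection-range truncation, because truncation is itself linear
  on spectra: a red-edge emitter's phasor shifts, but mixtures of truncated
  spectra still obey the rule of linear addition.

### Sampling convention

Grid samples sit at bin centers λ_min + (k + 0.5)Δ. Over one full period the
bin-center phases are equally spaced, so Σ cos θ_k = Σ sin θ_k = 0 exactly
and the flat-spectrum → origin identity holds to machine precision rather
than up to a discretization residue. Emission falling outside the grid is
silently truncated with no renormalization — that is what a physical
400–700 nm bandpass in the detection path does.

## The acquisition forward model

Each voxel's expected photon count per exposure is brightness(v) ·
Σ_λ X_v(λ) T(λ), with T the sine filter, cosine filter, or 1 (open channel).
A recording is gain · Poisson(N) + b + N(0, σ_read), with hot pixels planted
independently per channel (the three exposures are distinct frames on a
filter wheel) and negative read-noise excursions clipped at zero. One seeded
`numpy` generator drives Poisson, read noise and hot-pixel placement, so an
entire simulation is reproducible from a single integer. There is no PSF,
scattering or photobleaching model: phantoms are piecewise-constant label
fields, which is sufficient to exercise every analysis path but means the
tests say nothing about optical blur or motion in real data.

Default fixture conditions: camera offset b = 100 a.u., gain 1, and 10⁴
expected photons per voxel per exposure in the phantom builders — a bright,
well-exposed sCMOS-like regime chosen once as representative; the raw-data
scale of real acquisitions varies and is configurable. Phantom compositions
are specified as **intensity fractions**: the builders divide each
fluorophore's weight by its truncated band integral so that a programmed
fraction f is exactly the fraction of detected photons, which is the quantity
the phasor geometry estimates.

The multichannel renderer integrates the same scenes over n equal wavelength
bins (32 by default in the tests, emulating a commercial spectral detector)
and is transformed computationally with phases at channel centers. Agreement
between this path and the filter path is limited only by channel binning,
≲ 0.01 in G and S at 32 channels over 300 grid samples.

## The hardware transform and calibration

G = ((I_cos − b)/(I_total − b) − o_c)/m_c and likewise S from I_sin, with
default calibration o = m = 0.5 (the ideal filters). A measured filter
transmission is calibrated by ordinary least squares on the two-parameter
model o + m·sinθ (or cos); with a, e.g., 10% transmission floor
(o = 0.55, m = 0.45) the fitted calibration removes the coordinate bias the
ideal transform would exhibit. The fit fails loudly when the recovered
amplitude is nonpositive.

Voxels with I_total − b ≤ threshold are masked invalid (NaN coordinates plus
a boolean mask); the default threshold is 50 a.u., in the middle of the
25–100 a.u. range appropriate for typical samples, and configurable. The
threshold also guards the division: no valid voxel divides by a nonpositive
denominator. Noisy G/S values outside [−1, 1] are deliberately retained so
field statistics stay unbiased; only histogram display clips.

### Preprocessing

- **Median filter**: 3×3 within each z-plane, edge-reflected (symmetric)
  padding, applied to the three raw intensity stacks *before* the phasor
  division — hot pixels corrupt the ratio nonlinearly, so they must be
  removed from intensities, not from G/S. Filtering raw intensities before
  or after offset subtraction is equivalent (the median commutes with adding
  a constant), so the order is a non-issue; this implementation filters raw
  values.
- **2×2 binning** sums blocks rather than averaging, preserving photon
  statistics; an odd trailing row/column is dropped with a warning. The CLI
  scales offset and threshold by 4 after binning since four offsets are
  summed per output pixel.
- **Histogram**: 256×256 bins on [−1, 1]², left-closed right-open with the
  last bin closed. A uniform display jitter (halfwidth 0.02 by default; 0.08
  suits weak-signal data where few distinct intensity ratios occur) breaks
  up quantization banding. Jittered points leaving the unit square are
  dropped but counted, so counts + out-of-range = number of valid voxels.
  Jitter is display-only: selection, projection and every quantitative path
  consume unjittered coordinates.

## Linear-combination analyses

- **Segment fractions**: orthogonal projection onto the mixing line, t = 1
  at endpoint A. Orthogonal (not nearest-in-disk) projection because noise
  displaces points symmetrically about the line, making the projection the
  unbiased position estimate. Raw and clamped values are both kept so
  out-of-range mass can be audited.
- **Triangle fractions**: the standard 2×2 barycentric solve; raw fractions
  sum to 1 exactly, negative coordinates are clamped and renormalized.
  Four-component simultaneous unmixing is *not* offered: with 2-D phasor
  coordinates plus the sum-to-one constraint, four unknowns are
  under-determined, so the package supports the operational practice —
  polygon selection plus pairwise/triangle analysis — and stops there.
- **rr and dr**: t along the NADH–FAD (resp. relaxed–unrelaxed) trajectory,
  ratio t/(1−t) capped at 100 by default (t → 1 diverges; the cap keeps maps
  displayable and is recorded on the result). Both t and the ratio are
  returned because either scale may be profiled. Endpoints are supplied as
  named phasor points (CSV `name,G,S`), typically from pure-solution
  measurements or simulated pure spectra.
- **Half-plane pair coloring**: the phasor plane is split by the line through
  the midpoints connecting the two pairs' corresponding pure points; each
  voxel projects along its half's mixing segment. Ties on the dividing line
  go to the first pair (a deterministic rule, required because the line can
  pass through data).
- **Spectral-window mapping**: each voxel's phase maps back to a center
  wavelength, labeled by ordered half-open windows [lo, hi) — half-open so a
  boundary wavelength belongs to exactly one window.
- **Slice profiles**: per-plane mean/sd/count of any map along z, y or x,
  over valid (optionally image-masked) voxels; empty slices report n = 0
  with NaN moments.

## Selection

Polygon gating uses an even-odd (ray-casting) test, boundary-inclusive, with
a 1e−12 collinearity tolerance for the on-edge check — matching the visual
practice of drawing a polygon around a cluster and expecting points on the
outline to be included. Overlapping polygons resolve by explicit list order.
Selections never include invalid voxels and never see jitter.

## Numerical choices and degenerate inputs

- Segment endpoints closer than 1e−6 and triangles with twice-area below
  1e−9 are rejected as degenerate.
- The phasor of the zero spectrum, and the phase of (G, S) = (0, 0), are
  undefined: the former raises, the latter returns NaN phase with zero
  modulation.
- Filter minima are located by dense evaluation plus bounded scalar
  minimisation (analytic curves) or parabolic refinement of the discrete
  argmin (measured curves).
- The ideal o = m = 0.5 filter pair has mean transmission 0.5 per filter by
  construction; manufactured filters can differ (their average transmission
  is a property of the coating, not of this model).

## What the synthetic data does and does not show

The phantoms (uniform, layered, gradient) emulate the *spectral* structure
of real scenes — overlapping Gaussian emission bands, programmed mixing
fractions, axial gradients, shot noise, camera offset, read noise, hot
pixels — at sizes (≈ 16³ voxels, 10⁴ photons) chosen so the full suite runs
in seconds. They do not emulate optical blur, scattering, spectral shapes
beyond single Gaussians (real NADH/FAD emission in tissue is broadened by
bound/free mixtures), autofluorescent background mixed into every voxel, or
sample motion between the three exposures. Passing tests therefore establish
the correctness of the transform, geometry and bookkeeping — not robustness
to those real-data effects, which enter through the threshold, calibration
and median-filter knobs in practice.
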