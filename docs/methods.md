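# Methods

## The measurement problem

A pair of soft vocal-fold replicas separated by a narrow glottal slit
self-oscillates under airflow. In transillumination high-speed video the
slit appears as a dark region between bright folds; the phonatory state of
the replica is summarized by the glottal area waveform A(t), kymographic
open/close patterns along the anterior–posterior axis, left/right fold
deflection trajectories, and scalar metrics (F0, maximum glottal area,
phonation onset pressure, SPL). This package implements that chain of
measurements and, because raw recordings are not redistributable, a
forward model that renders videos with exact analytic ground truth so the
whole chain can be scored.

## Synthetic kinematic model

The left/right glottal edges at axis position y ∈ [0, L] (L = fold length,
posterior at y = 0) and time t are

    x_{l,r}(y, t) = ∓[ g₀/2 + a_{l,r} · sin(πy/L)^q · max(0, sin(2πf₀t + φ(y))) ]

with rest gap g₀, per-fold amplitudes a_l, a_r, envelope exponent q, and a
phase φ(y) linear from 0 (posterior) to the anterior–posterior lag Λ
(positive Λ = anterior phase-advanced). The half-wave rectification is a
minimal model of collision closure: the folds touch (at the rest slit) for
half of each cycle and the instantaneous gap never goes negative, while
the open phase is sinusoidal — matching the mostly-sinusoidal waves such
replicas exhibit. The model is deliberately kinematic: it reproduces the
*observables* the analysis consumes (periodicity, closure, axial envelope,
asymmetry, phase propagation), not the fluid–structure mechanics that
produce them. Rendering uses folds at intensity 0.8, slit at 0.1, exact
linear anti-aliasing of each edge within its boundary pixel, and optional
additive Gaussian intensity noise clipped to [0, 1]. Image convention:
origin top-left, rows = anterior–posterior axis (posterior = row 0),
columns = medial–lateral, midline at the central column.

Defaults are the study conditions: 20,000 fps, 0.01 mm/px, 0.02-s window
(400 frames), rest gap 0.3 mm. Values the acquisition does not pin down
were chosen once at a realistic infant scale and kept: fold length 1.2 mm
(quarter-scale replica), amplitudes 0.2 mm per fold (peak surface strain
well above 15%), envelope exponent q = 1. The frame is auto-sized to the
kinematics (fold rows + 20-px margins, max gap + 30-px fold flanks, giving
160×130 px at defaults) and is fully configurable; an explicit shape too
small for the rendered glottis raises an error naming the violated
dimension.

Ground truth carries the analytic F0, per-row edge positions, and the area
integral evaluated by midpoint quadrature at 8× the rendered row
resolution. Left/right asymmetry experiments use g₀ = 0: the deflections
δ are defined from the midline, so with a nonzero rest gap a 2:1 amplitude
ratio would be diluted by the shared rest half-gap and no estimator could
report 2:1; with collision closure (g₀ = 0) the ratio of mean deflections
equals the amplitude ratio exactly.

The pressure-sweep generator produces a linear ramp with a sinusoidal
oscillation switched on when the ramp crosses the onset pressure, with a
raised-cosine envelope growth over 10 cycles; the diffusion generator fills
a disk ROI from a lateral deposition point so each requested coverage
fraction is met to one pixel quantum; the Live/Dead generator places
Gaussian blobs with ≥ 4-radius separation (rejection sampling) so counting
is exact by construction.

## Segmentation and area quantification

Frames are reduced to luminance (Rec. 709 weights), thresholded with a
local-mean adaptive rule (pixel dark if below the mean of a square
neighbourhood minus offset 0.1), and restricted to the largest dark
8-connected component; per-frame Otsu is available as an alternative.
The local window (default 101 px) must exceed the widest expected glottal
gap — a window that fits inside the dark slit sees an all-dark
neighbourhood and loses the interior — and the default covers the default
geometry's ~70-px maximal gap with margin. Empty masks are valid data
(closed phase), never errors. Pixel counts are converted through the
squared pixel pitch (0.01 mm/px ⇒ 0.0001 mm²/px) and smoothed with a
centred moving average (default 5 frames; truncated symmetrically at the
record ends, so the smoother is mean-preserving on the interior). On
noise-free default renders the smoothed waveform agrees with analytic
truth to < 1% relative RMS; at 1,200 Hz the 5-frame window attenuates the
oscillatory component (~13% of its amplitude at 16.7 frames/cycle), which
shows up as ~6% relative RMS — an inherent smoothing trade-off, not a
segmentation error.

## Kymography and edge tracking

Kymogram columns are verbatim scanline copies at
row = r₀ + round(fraction · (glottal rows − 1)), where the glottal row
span comes from the union of all frame masks — "mid-glottal plane" means
the middle of the segmented glottal extent, not of the image, so the
analysis is robust to framing. Edges are the outermost mask pixels on the
scanline, measured to pixel centres; sub-pixel edge refinement is
deliberately omitted, so per-frame gap reconstructions carry up to ~1 px
quantization per edge (2 px on the gap, 0.02 mm at default calibration).

The anatomical midline is estimated per scanline from the rest
configuration: over open frames, the per-frame slit centre is regressed
against the per-frame gap and extrapolated to zero gap. Under the
kinematic model the centre is exactly linear in the gap
(centre = midline + gap·(a_r − a_l)/(2(a_l + a_r))), so the intercept is
the midline exactly for any asymmetry, and the regression averages pixel
quantization to sub-pixel accuracy. A union-mask median was rejected: it
shifts toward the larger-amplitude fold and biases every deflection
metric. Closed frames are flagged, never interpolated.

## Motion analysis

Optical flow is iterative, regularized Lucas–Kanade: both frames Gaussian
pre-smoothed (σ = 1.5 px), gradients pooled over a 15-px square window,
the 2×2 normal equations solved per pixel with Tikhonov damping (1e-4),
and three warp-and-refine passes to track displacements beyond the linear
range (edge speeds reach ~4 px/frame at 1,200 Hz). Flow is left undefined
(zero, excluded from the ROI) where the structure-tensor trace falls below
1e-3 — the textureless slit interior and the flat fold surface carry no
motion information, and unregularized estimates there are unbounded. The
estimator's contract is translation recovery (a rigid 1-px lateral shift
of a textured frame is recovered within ±0.2 px); no specific algorithm
is essential.

The GOFW aggregates sign(column − midline) · u over the ROI (the pair's
mask union dilated by 5 px, intersected with the defined-flow region):
positive = walls diverging. The vertical component v is retained in the
flow fields but unused by the waveform. On noise-free simulations the
GOFW correlates with the analytic dA/dt at r > 0.97 and is antisymmetric
under time reversal to ~2% RMS.

Trajectory phase metrics (left-vs-right lag; anterior–posterior lag) use
parabolic interpolation of the cross-correlation peak, converted to
radians at the dominant frequency; the anterior–posterior lag is the slope
of per-scanline phase against axis fraction, reported over the full
posterior→anterior span. An imposed π/4 lag is recovered to ~0.02 rad.

## Phonatory metrics

F0 uses the normalized (unbiased) autocorrelation with a parabolic
sub-sample peak; among peaks within 80% of the strongest, the smallest lag
wins (octave-error guard). A 0.02-s record gives 50-Hz FFT bins, which is
why interpolated autocorrelation, not a bare spectral peak, is used; the
estimator is < 0.7% biased across 100–1,200 Hz at up to 5% intensity
noise. Records with no autocorrelation peak above 0.25 report F0 as
absent — stiff, non-oscillating replica configurations are a real outcome,
not an error. Onset detection removes the ramp, locates the dominant
oscillation band (Welch), band-passes ±40%, and takes the Hilbert
envelope; the onset is the low-passed pressure at the first instant the
envelope exceeds k = 5 times the pre-onset noise floor (median envelope
over the leading 5% of the record) for m = 3 cycles. The method assumes
the record starts before onset; k and m are configurable and logged. SPL
uses the standard 20 µPa reference.

## Bioassays

Coverage is the stained-pixel fraction inside the construct ROI at a fixed
normalized-intensity threshold (0.5); the real assay's colorimetric
criterion is unknown, so only recovery of synthetic fixtures is claimed.
Viability is 100·live/(live+dead), undefined (flagged) for zero cells,
with counts from Gaussian smoothing + local-maximum detection; CCK-8
normalization subtracts the blank mean and clips negatives to zero with a
flag.

## What the synthetic data does and does not show

The generator reproduces the geometry, contrast, noise, frame rate and
kinematic structure of replica recordings, so passing tests demonstrate
that the *analysis chain* is correct and calibrated. It does not emulate
specular highlights, uneven illumination, camera vignetting, motion blur,
mucosal-wave surface texture, or three-dimensional fold geometry; real
recordings may need per-case threshold/window tuning, and quantitative
claims here are claims about the estimators, not about any physical
replica. The physical headline values of such experiments (pressures of
~13 kPa, SPL above 130 dB, F0 over 1,200 Hz at ~18 kPa, viability
percentages) are properties of physical replicas and micrographs and are
not reproduced computationally; the pipeline instead demonstrates
parameter *recovery* over those same operating ranges.

## Problem sizes and determinism

Default analyses use 400-frame videos at 160×130 px; unit tests use
shorter 0.008-s (160-frame) records of the same geometry, chosen so the
full suite and the acceptance script each run in a few minutes on one
core. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give bit-identical frames
and byte-identical CSV outputs (fixed `%.9g` float formatting).

## Known limitations

- Edge positions are pixel-quantized (no sub-pixel edge model); gap-level
  quantities carry ~0.01–0.02 mm quantization at default calibration.
- The 5-frame smoothing window attenuates high-F0 area oscillations (see
  above); reduce the window for F0 ≳ 1 kHz if waveform amplitude matters.
- Onset detection needs a pre-onset segment (≥ 5% of the record) to learn
  the noise floor and assumes a roughly linear ramp.
- The GOFW is reported in px/frame (a mean wall speed); it is a relative
  waveform, not a calibrated volume-velocity.
- `estimate_ap_phase_lag` assumes a common dominant frequency across
  scanlines; it returns absent when no oscillation is detected.
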