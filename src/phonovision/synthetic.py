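"""Synthetic glottal videos, pressure sweeps, and bioassay images with exact
analytic ground truth.

The video generator emulates transilluminated high-speed recordings of a
pair of vocal-fold replicas: a dark oscillating slit (the glottis) between
bright folds, sampled at 20,000 fps with 0.01 mm/pixel over a 0.02-s window
by default.  Edges follow a half-wave-rectified sinusoid with a sin^q
anterior–posterior amplitude envelope and an optional linear phase lag
along the axis; rectification models collision closure, so the
instantaneous gap never drops below the rest gap.

Every generator takes an explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .datatypes import Calibration, FrameStack, GlottalKinematics, GroundTruth, SignalTrace

#: intensity of the bright fold tissue and the dark glottal slit
FOLD_INTENSITY = 0.8
GLOTTIS_INTENSITY = 0.1

#: fine-quadrature oversampling of the analytic area integral (per rendered row)
_QUAD_OVERSAMPLE = 8


def edge_positions(
    kin: GlottalKinematics, t: np.ndarray, y_fraction: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic left/right edge positions (mm from midline).

    ``t`` is time in seconds, ``y_fraction`` the anterior–posterior position
    as a fraction of fold length (0 = posterior).  Returns ``(x_left,
    x_right)`` with shape ``(len(t), len(y_fraction))``; left is <= 0.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    yf = np.atleast_1d(np.asarray(y_fraction, dtype=float))
    envelope = np.sin(np.pi * yf) ** kin.axis_profile_exponent
    phase = 2.0 * np.pi * kin.f0 * t[:, None] + kin.ap_phase_lag * yf[None, :]
    excursion = envelope[None, :] * np.maximum(0.0, np.sin(phase))
    x_left = -(kin.rest_gap / 2.0 + kin.amp_left * excursion)
    x_right = kin.rest_gap / 2.0 + kin.amp_right * excursion
    return x_left, x_right


def _analytic_area(kin: GlottalKinematics, t: np.ndarray, n_fine: int) -> np.ndarray:
    """Glottal area (mm²) per frame by fine midpoint quadrature along the axis."""
    yf = (np.arange(n_fine) + 0.5) / n_fine
    xl, xr = edge_positions(kin, t, yf)
    return (xr - xl).mean(axis=1) * kin.fold_length


def generate_glottal_video(
    kin: GlottalKinematics,
    calib: Calibration,
    noise_sigma: float = 0.0,
    seed: int = 0,
    image_shape: tuple[int, int] | None = None,
    row_margin: int = 20,
    col_margin: int = 30,
) -> tuple[FrameStack, GroundTruth]:
    """Render a synthetic glottal high-speed video plus its ground truth.

    Parameters
    ----------
    kin, calib
        Kinematic and acquisition parameters.
    noise_sigma
        Standard deviation of additive Gaussian intensity noise (clipped to
        [0, 1] after addition).
    seed
        Seed for the noise field; fixed seed gives a bit-identical stack.
    image_shape
        Optional explicit ``(H, W)``.  By default the frame is sized to the
        kinematics: fold rows plus ``row_margin`` above/below, maximal gap
        plus ``col_margin`` of bright fold on each side.

    Returns
    -------
    (FrameStack, GroundTruth)

    Raises
    ------
    ValueError
        If an explicit ``image_shape`` cannot contain the rendered glottis;
        the message names the violated dimension.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    s = calib.mm_per_pixel
    n_frames = int(round(calib.fps * kin.duration))
    if n_frames < 1:
        raise ValueError("duration is shorter than one frame period")
    n_rows = max(1, int(round(kin.fold_length / s)))
    half_left = kin.rest_gap / 2.0 + kin.amp_left
    half_right = kin.rest_gap / 2.0 + kin.amp_right

    if image_shape is None:
        height = n_rows + 2 * row_margin
        width = int(np.ceil((half_left + half_right) / s)) + 2 * col_margin
    else:
        height, width = image_shape
        if n_rows > height:
            raise ValueError(
                f"fold_length ({kin.fold_length} mm = {n_rows} rows) exceeds the "
                f"image height of {height} rows"
            )
    mid_col = (width - 1) / 2.0
    if mid_col - half_left / s < 0.0 or mid_col + half_right / s > width - 1:
        raise ValueError(
            f"rendered glottis (max gap {kin.max_gap:.3g} mm = "
            f"{kin.max_gap / s:.0f} px) is wider than the image width of {width} px"
        )

    row0 = (height - n_rows) // 2
    t = np.arange(n_frames) / calib.fps
    row_fractions = (np.arange(n_rows) + 0.5) / n_rows
    x_left, x_right = edge_positions(kin, t, row_fractions)  # (T, R)

    # anti-aliased rendering: per pixel, intensity interpolates linearly with
    # the fraction of the pixel covered by the dark slit
    frames = np.full((n_frames, height, width), FOLD_INTENSITY, dtype=np.float32)
    col_lo = np.arange(width) - 0.5
    col_hi = np.arange(width) + 0.5
    contrast = FOLD_INTENSITY - GLOTTIS_INTENSITY
    for k in range(n_frames):
        c_left = mid_col + x_left[k] / s  # (R,)
        c_right = mid_col + x_right[k] / s
        coverage = np.clip(
            np.minimum(c_right[:, None], col_hi[None, :])
            - np.maximum(c_left[:, None], col_lo[None, :]),
            0.0,
            1.0,
        )
        frames[k, row0 : row0 + n_rows, :] -= (contrast * coverage).astype(np.float32)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        frames += rng.standard_normal(frames.shape, dtype=np.float32) * np.float32(noise_sigma)
        np.clip(frames, 0.0, 1.0, out=frames)

    truth = GroundTruth(
        true_f0=kin.f0,
        true_area=_analytic_area(kin, t, n_rows * _QUAD_OVERSAMPLE),
        true_left_edge=x_left,
        true_right_edge=x_right,
        row_fractions=row_fractions,
        time=t,
        params=kin,
        calib=calib,
        seed=seed,
        glottal_rows=(row0, row0 + n_rows - 1),
        midline_col=mid_col,
    )
    return FrameStack(frames, calib), truth


def generate_pressure_sweep(
    onset_pressure: float,
    ramp_rate: float,
    osc_amp: float,
    f0: float,
    fs: float,
    duration: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
    growth_cycles: int = 10,
) -> SignalTrace:
    """Linear subglottal-pressure ramp with oscillation switching on at onset.

    The ramp rises from 0 at ``ramp_rate`` kPa/s.  Once it crosses
    ``onset_pressure`` a sinusoid of amplitude ``osc_amp`` and frequency
    ``f0`` is superimposed, its envelope growing smoothly (raised cosine)
    over ``growth_cycles`` cycles.  The true onset is stored in
    ``metadata["true_onset_pressure"]`` / ``["true_onset_time"]``; if the
    ramp never reaches onset within ``duration``, or ``osc_amp`` is zero,
    the metadata marks the onset absent.
    """
    for name, val in [("onset_pressure", onset_pressure), ("ramp_rate", ramp_rate),
                      ("osc_amp", osc_amp), ("noise_sigma", noise_sigma)]:
        if val < 0:
            raise ValueError(f"{name} must be >= 0")
    if not fs > 2 * f0:
        raise ValueError(f"fs ({fs}) must exceed twice f0 ({f0})")
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    ramp = ramp_rate * t

    onset_time = onset_pressure / ramp_rate if ramp_rate > 0 else np.inf
    metadata: dict = {"ramp_rate_kpa_s": ramp_rate, "osc_f0_hz": f0}
    osc = np.zeros(n)
    if osc_amp > 0 and onset_time <= duration:
        tau = t - onset_time
        growth_time = growth_cycles / f0
        envelope = np.where(
            tau < 0,
            0.0,
            np.where(tau >= growth_time, 1.0, 0.5 * (1 - np.cos(np.pi * tau / growth_time))),
        )
        osc = osc_amp * envelope * np.sin(2 * np.pi * f0 * tau)
        metadata["true_onset_pressure"] = onset_pressure
        metadata["true_onset_time"] = onset_time
    else:
        metadata["true_onset_pressure"] = None
        metadata["true_onset_time"] = None

    samples = ramp + osc
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sigma, n)
    return SignalTrace(samples=samples, fs=fs, kind="pressure", metadata=metadata)


def generate_diffusion_series(
    n_timepoints: int,
    coverage_targets,
    image_size: tuple[int, int] = (128, 128),
    seed: int = 0,
    noise_sigma: float = 0.02,
) -> tuple[list[np.ndarray], np.ndarray, list[float]]:
    """Brightfield-style dye-diffusion image series over a construct ROI.

    The construct is a centred disk; the stained sub-region grows from one
    side (asymmetric deposition) by filling ROI pixels in order of distance
    from the deposition point, so each requested coverage fraction is met
    within one pixel-area quantum.  Targets must be nondecreasing
    (diffusion is monotone).

    Returns ``(images, roi_mask, true_fractions)`` where ``true_fractions``
    are the exactly realized stained-pixel fractions.
    """
    targets = [float(f) for f in coverage_targets]
    if len(targets) != n_timepoints:
        raise ValueError("coverage_targets length must equal n_timepoints")
    if any(f < 0 or f > 1 for f in targets):
        raise ValueError("coverage targets must lie in [0, 1]")
    if any(b < a for a, b in zip(targets, targets[1:])):
        raise ValueError("coverage targets must be nondecreasing (diffusion is monotone)")

    h, w = image_size
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = 0.35 * min(h, w)
    roi = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
    roi_idx = np.flatnonzero(roi.ravel())
    # fill order: distance from the deposition point at the left ROI edge,
    # with a lexicographic tiebreak for determinism
    dep_r, dep_c = cy, cx - radius
    dist = (rr.ravel()[roi_idx] - dep_r) ** 2 + (cc.ravel()[roi_idx] - dep_c) ** 2
    order = roi_idx[np.lexsort((roi_idx, dist))]

    rng = np.random.default_rng(seed)
    images, true_fractions = [], []
    for frac in targets:
        n_stain = int(round(frac * len(roi_idx)))
        img = np.full(h * w, 0.9)
        img[roi_idx] = 0.75
        img[order[:n_stain]] = 0.30
        img = img.reshape(h, w)
        if noise_sigma > 0:
            img = np.clip(img + rng.normal(0.0, noise_sigma, img.shape), 0.0, 1.0)
        images.append(img)
        true_fractions.append(n_stain / len(roi_idx))
    return images, roi, true_fractions


def generate_livedead_image(
    n_live: int,
    n_dead: int,
    image_size: tuple[int, int] = (256, 256),
    blob_radius: float = 4.0,
    seed: int = 0,
    max_tries: int = 10_000,
) -> tuple[np.ndarray, dict]:
    """Two-channel fluorescence-style image with known live/dead cell counts.

    Channel 0 carries ``n_live`` bright Gaussian blobs (live stain), channel
    1 ``n_dead`` (dead stain).  Blob centres are placed by rejection
    sampling with a minimum separation of four radii between any two cells,
    which keeps downstream counting exact; an overcrowded request raises
    after ``max_tries`` attempts.

    Returns ``(image, truth)`` with ``image`` of shape ``(2, H, W)`` and
    ``truth = {"n_live", "n_dead", "viability_pct"}`` (viability ``None``
    when there are no cells).
    """
    if n_live < 0 or n_dead < 0:
        raise ValueError("cell counts must be >= 0")
    h, w = image_size
    margin = 3.0 * blob_radius
    min_sep2 = (4.0 * blob_radius) ** 2
    rng = np.random.default_rng(seed)

    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_live + n_dead:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_live + n_dead} blobs of radius {blob_radius} "
                f"in a {h}x{w} image without overlap after {max_tries} tries"
            )
        tries += 1
        r = rng.uniform(margin, h - 1 - margin)
        c = rng.uniform(margin, w - 1 - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep2 for r0, c0 in centers):
            centers.append((r, c))

    image = np.full((2, h, w), 0.05)
    sigma = blob_radius / 2.0
    rr, cc = np.mgrid[0:h, 0:w]
    for i, (r, c) in enumerate(centers):
        channel = 0 if i < n_live else 1
        image[channel] += np.exp(-(((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2)))
    image = np.clip(image + rng.normal(0.0, 0.01, image.shape), 0.0, 1.0)

    total = n_live + n_dead
    truth = {
        "n_live": n_live,
        "n_dead": n_dead,
        "viability_pct": 100.0 * n_live / total if total > 0 else None,
    }
    return image, truth
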