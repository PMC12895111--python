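"""Videokymography: space–time kymograms at chosen anterior–posterior
positions, left/right edge tracking, and anterior–posterior phase-lag
estimation across multiple scanlines.

Axis fractions refer to the segmented glottal extent (the row span covered
by the union of all frame masks), not to the full image, so the analysis is
robust to framing.
"""

from __future__ import annotations

import numpy as np

from .datatypes import EdgeTrack, FrameStack, GlottalMaskSeries, Kymogram
from .metrics import estimate_f0
from .segmentation import SegmentationConfig, area_waveform
from .signal_ops import xcorr_delay

DEFAULT_FRACTIONS = (0.25, 0.5, 0.75)


def glottal_row_span(masks: GlottalMaskSeries) -> tuple[int, int]:
    """First and last image row touched by the union of all glottal masks."""
    union_rows = masks.masks.any(axis=(0, 2))
    idx = np.flatnonzero(union_rows)
    if len(idx) == 0:
        raise ValueError("no glottal extent: the union of segmentation masks is empty")
    return int(idx[0]), int(idx[-1])


def _ensure_masks(
    stack: FrameStack, masks: GlottalMaskSeries | None, cfg: SegmentationConfig | None
) -> GlottalMaskSeries:
    if masks is not None:
        return masks
    series, _ = area_waveform(stack, cfg)
    return series


def extract_kymogram(
    stack: FrameStack,
    axis_fraction: float,
    masks: GlottalMaskSeries | None = None,
    cfg: SegmentationConfig | None = None,
) -> Kymogram:
    """Kymogram at one anterior–posterior fraction of the glottal extent.

    Column ``t`` of the matrix is a verbatim copy of frame ``t``'s scanline
    at ``row = row_min + round(axis_fraction * (glottal rows - 1))``.
    """
    if not 0.0 <= axis_fraction <= 1.0:
        raise ValueError(f"axis_fraction must lie in [0, 1], got {axis_fraction}")
    masks = _ensure_masks(stack, masks, cfg)
    r0, r1 = glottal_row_span(masks)
    row = r0 + int(round(axis_fraction * (r1 - r0)))
    matrix = np.ascontiguousarray(stack.frames[:, row, :].T)
    return Kymogram(matrix=matrix, axis_fraction=axis_fraction, row=row, calib=stack.calib)


def estimate_midline(left_px: np.ndarray, right_px: np.ndarray, open_mask: np.ndarray,
                     width: int) -> float:
    """Anatomical midline column from edge-pixel series on one scanline.

    The slit is symmetric about the midline in the rest (collision)
    configuration, so the per-frame slit centre is extrapolated to zero
    gap: regress centre against gap over the open frames and take the
    intercept.  Exact on the noise-free kinematic model for any left/right
    amplitude asymmetry; falls back to the mean centre when the gap does
    not vary, and to the image centre when the glottis never opens.
    """
    if not open_mask.any():
        return (width - 1) / 2.0
    left = left_px[open_mask].astype(float)
    right = right_px[open_mask].astype(float)
    centers = (left + right) / 2.0
    gaps = right - left
    if len(gaps) < 3 or float(np.std(gaps)) < 1e-9:
        return float(np.mean(centers))
    slope, intercept = np.polyfit(gaps, centers, 1)
    return float(intercept)


def trace_edges(kymo: Kymogram, masks: GlottalMaskSeries) -> EdgeTrack:
    """Left/right glottal edge positions through time on one scanline.

    Edges are the outermost mask-true pixel centres on the scanline,
    converted to mm from the estimated midline; closed frames carry (0, 0)
    and are flagged.
    """
    line = masks.masks[:, kymo.row, :]  # (T, W)
    n_frames, width = line.shape
    open_mask = line.any(axis=1)
    left_px = np.zeros(n_frames)
    right_px = np.zeros(n_frames)
    for t in np.flatnonzero(open_mask):
        cols = np.flatnonzero(line[t])
        left_px[t] = cols[0]
        right_px[t] = cols[-1]

    midline = estimate_midline(left_px, right_px, open_mask, width)
    scale = masks.calib.mm_per_pixel
    left_mm = np.where(open_mask, np.minimum(left_px - midline, 0.0) * scale, 0.0)
    right_mm = np.where(open_mask, np.maximum(right_px - midline, 0.0) * scale, 0.0)
    return EdgeTrack(
        left_mm=left_mm,
        right_mm=right_mm,
        closed=~open_mask,
        axis_fraction=kymo.axis_fraction,
        midline_col=midline,
        calib=masks.calib,
    )


def multi_position_kymograms(
    stack: FrameStack,
    fractions=DEFAULT_FRACTIONS,
    masks: GlottalMaskSeries | None = None,
    cfg: SegmentationConfig | None = None,
) -> list[tuple[Kymogram, EdgeTrack]]:
    """Kymogram + edge track at each axis fraction, sharing one segmentation."""
    fractions = list(fractions)
    if any(b < a for a, b in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be sorted ascending")
    masks = _ensure_masks(stack, masks, cfg)
    out = []
    for frac in fractions:
        kymo = extract_kymogram(stack, frac, masks=masks)
        out.append((kymo, trace_edges(kymo, masks)))
    return out


def estimate_ap_phase_lag(
    tracks: list[EdgeTrack], fractions, fps: float
) -> float | None:
    """Full-span anterior–posterior phase lag, radians, from >= 2 tracks.

    The gap signal at each scanline is cross-correlated against the most
    posterior one; the per-position phase (at the dominant frequency, via
    parabolic refinement of the correlation peak) is regressed against the
    axis fraction, and the slope is reported as the posterior-to-anterior
    (fraction 0 to 1) lag.  Positive = anterior phase-advanced.  Returns
    ``None`` when no oscillation is detectable.
    """
    fractions = np.asarray(list(fractions), dtype=float)
    if len(tracks) != len(fractions) or len(tracks) < 2:
        raise ValueError("need >= 2 tracks with matching fractions")
    gaps = [trk.gap_mm for trk in tracks]
    f0 = estimate_f0(gaps[0], fps)
    if f0 is None:
        return None
    max_lag = max(2, int(round(0.5 * fps / f0)))
    phases = []
    for g in gaps:
        delay = xcorr_delay(gaps[0], g, max_lag)
        if delay is None:
            return None
        # a positive generator phase means the signal leads (arrives earlier)
        phases.append(-2.0 * np.pi * f0 * delay / fps)
    slope = np.polyfit(fractions, np.asarray(phases), 1)[0]
    return float(slope)
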