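"""Shared data containers for the phonatory video-analysis pipeline.

Conventions used throughout the package:

* image origin is top-left; the row index runs along the anterior–posterior
  glottal axis (posterior = row 0) and the column index along the
  medial–lateral axis;
* the anatomical midline is a column coordinate (pixel centres), lateral
  positions are signed millimetres from the midline (left ≤ 0 ≤ right);
* frame intensities live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class Calibration:
    """Acquisition calibration of a high-speed recording.

    Parameters
    ----------
    fps : float
        Frame rate in frames per second.
    mm_per_pixel : float
        Spatial scale, millimetres per pixel (isotropic).
    """

    fps: float = 20_000.0
    mm_per_pixel: float = 0.01

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not self.mm_per_pixel > 0:
            raise ValueError(f"mm_per_pixel must be positive, got {self.mm_per_pixel}")

    @property
    def frame_period(self) -> float:
        """Seconds between consecutive frames."""
        return 1.0 / self.fps


@dataclass(frozen=True)
class GlottalKinematics:
    """Analytic kinematics of the oscillating glottal slit.

    The left/right edge model at axis position ``y`` (mm from the posterior
    end, ``0 <= y <= fold_length``) and time ``t`` is::

        x_{l,r}(y, t) = -/+ [ rest_gap/2
                              + amp_{l,r} * sin(pi*y/L)**q
                                * max(0, sin(2*pi*f0*t + phi(y))) ]

    with ``phi`` linear from 0 at the posterior end to ``ap_phase_lag`` at
    the anterior end.  The half-wave rectification models collision closure:
    the instantaneous gap never drops below ``rest_gap``.

    Attributes
    ----------
    f0 : float
        Oscillation frequency, Hz.
    rest_gap : float
        Medial gap at rest, mm.
    amp_left, amp_right : float
        Peak lateral edge excursions, mm.
    axis_profile_exponent : float
        Shaping power ``q`` of the anterior–posterior amplitude envelope.
    ap_phase_lag : float
        Phase difference between the anterior and posterior ends, radians
        (positive = anterior phase-advanced).
    fold_length : float
        Anterior–posterior extent of the glottis, mm.
    duration : float
        Record length, seconds.
    """

    f0: float = 250.0
    rest_gap: float = 0.3
    amp_left: float = 0.2
    amp_right: float = 0.2
    axis_profile_exponent: float = 1.0
    ap_phase_lag: float = 0.0
    fold_length: float = 1.2
    duration: float = 0.02

    def __post_init__(self) -> None:
        if not self.f0 > 0:
            raise ValueError(f"f0 must be positive, got {self.f0}")
        if self.rest_gap < 0:
            raise ValueError(f"rest_gap must be >= 0, got {self.rest_gap}")
        if self.amp_left < 0 or self.amp_right < 0:
            raise ValueError("amplitudes must be >= 0")
        if not self.fold_length > 0:
            raise ValueError(f"fold_length must be positive, got {self.fold_length}")
        if not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.axis_profile_exponent < 0:
            raise ValueError("axis_profile_exponent must be >= 0")

    @property
    def max_gap(self) -> float:
        """Largest possible instantaneous gap, mm."""
        return self.rest_gap + self.amp_left + self.amp_right


@dataclass
class FrameStack:
    """Ordered grayscale frames with acquisition calibration.

    ``frames`` has shape ``(T, H, W)`` with intensities in [0, 1]; rows are
    the anterior–posterior axis when ``axis_orientation == "rows"``.
    """

    frames: np.ndarray
    calib: Calibration
    axis_orientation: str = "rows"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"frame intensities must lie in [0, 1], got [{lo}, {hi}]")
        if self.axis_orientation not in ("rows", "columns"):
            raise ValueError("axis_orientation must be 'rows' or 'columns'")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def time(self) -> np.ndarray:
        """Acquisition time of each frame, seconds."""
        return np.arange(self.n_frames) / self.calib.fps


@dataclass
class GroundTruth:
    """Analytic record produced alongside a synthetic video.

    ``true_left_edge`` / ``true_right_edge`` are ``(T, R)`` arrays of lateral
    edge positions (mm from midline) at the R rendered glottal row centres;
    ``row_fractions`` are the corresponding anterior–posterior fractions.
    ``true_area`` is the fine-quadrature integral of the gap profile, mm².
    """

    true_f0: float
    true_area: np.ndarray
    true_left_edge: np.ndarray
    true_right_edge: np.ndarray
    row_fractions: np.ndarray
    time: np.ndarray
    params: GlottalKinematics
    calib: Calibration
    seed: Optional[int] = None
    glottal_rows: Optional[tuple] = None
    midline_col: Optional[float] = None

    def gap_at_fraction(self, fraction: float) -> np.ndarray:
        """True gap (right − left, mm) vs time at an axis fraction."""
        gaps = self.true_right_edge - self.true_left_edge
        out = np.empty(gaps.shape[0])
        for t in range(gaps.shape[0]):
            out[t] = np.interp(fraction, self.row_fractions, gaps[t])
        return out

    def area_rate(self) -> np.ndarray:
        """Time derivative of the true area, mm²/s."""
        return np.gradient(self.true_area, 1.0 / self.calib.fps)


@dataclass
class GlottalMaskSeries:
    """Per-frame binary glottal masks plus pixel counts."""

    masks: np.ndarray  # (T, H, W) boolean
    pixel_counts: np.ndarray  # (T,) int
    calib: Calibration

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        self.pixel_counts = np.asarray(self.pixel_counts, dtype=np.int64)
        if self.masks.ndim != 3:
            raise ValueError("masks must be (T, H, W)")
        if len(self.pixel_counts) != self.masks.shape[0]:
            raise ValueError("pixel_counts length must match number of masks")


@dataclass
class AreaWaveform:
    """Glottal area per frame, raw and moving-average smoothed, mm²."""

    time: np.ndarray
    area_raw: np.ndarray
    area_smooth: np.ndarray
    window: int

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.area_raw) == len(self.area_smooth) == n):
            raise ValueError("time, area_raw and area_smooth must share a length")
        if np.any(np.asarray(self.area_raw) < 0) or np.any(np.asarray(self.area_smooth) < 0):
            raise ValueError("areas must be >= 0")


@dataclass
class Kymogram:
    """Space–time intensity matrix at one anterior–posterior scanline.

    ``matrix`` has scanline pixels as rows and time as columns (shape
    ``(W, T)``); column ``t`` is a verbatim copy of frame ``t``'s scanline.
    """

    matrix: np.ndarray
    axis_fraction: float
    row: int
    calib: Calibration


@dataclass
class EdgeTrack:
    """Traced left/right glottal edges on one scanline, mm from midline."""

    left_mm: np.ndarray
    right_mm: np.ndarray
    closed: np.ndarray  # boolean, True where the glottis is closed on the scanline
    axis_fraction: float
    midline_col: float
    calib: Calibration

    def __post_init__(self) -> None:
        if np.any(self.right_mm - self.left_mm < -1e-12):
            raise ValueError("right edge must not lie medial to the left edge")

    @property
    def gap_mm(self) -> np.ndarray:
        return self.right_mm - self.left_mm


@dataclass
class FlowField:
    """Dense displacement field between one consecutive frame pair.

    ``u`` is the lateral (column) and ``v`` the axial (row) displacement in
    px/frame over the dilated glottal ROI bounding box; pixels outside the
    ROI are zero, with the ROI itself in ``roi``.
    """

    u: np.ndarray
    v: np.ndarray
    roi: np.ndarray
    bbox: tuple  # (row0, row1, col0, col1) in source-frame coordinates
    pair_index: int


@dataclass
class FoldTrajectoryPair:
    """Left/right deflection time series at one axis fraction.

    ``symmetry_index = 1 - mean|dl - dr| / mean(dl + dr)`` and ``phase_lag``
    is the left-vs-right cross-correlation lag in radians at the dominant
    frequency.  Both are ``None`` (with ``valid=False``) for all-closed
    tracks where they are undefined.
    """

    delta_left: np.ndarray
    delta_right: np.ndarray
    axis_fraction: float
    symmetry_index: Optional[float]
    phase_lag: Optional[float]
    valid: bool = True


@dataclass
class SignalTrace:
    """A 1-D physical time series (pressure in kPa or acoustic in Pa)."""

    samples: np.ndarray
    fs: float
    kind: str  # "pressure" | "acoustic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.kind not in ("pressure", "acoustic"):
            raise ValueError("kind must be 'pressure' or 'acoustic'")

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class PhonatoryMetrics:
    """Scalar phonatory descriptors of one recording."""

    f0: Optional[float]
    max_area: float
    onset_pressure: Optional[float] = None
    spl: Optional[float] = None
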