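"""Image-based bioassay quantification: dye-diffusion coverage fractions,
Live/Dead cell counting with viability, and CCK-8 blank normalization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

from .datatypes import Calibration  # noqa: F401  (re-exported for CLI convenience)


def coverage_fraction(image: np.ndarray, roi_mask: np.ndarray, stain_threshold: float = 0.5) -> float:
    """Fraction of the construct ROI covered by stain (dark pixels).

    A pixel counts as stained when its normalized intensity falls below
    ``stain_threshold``.  Pixels outside the ROI never influence the
    result.
    """
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool)
    if image.shape != roi.shape:
        raise ValueError("image and roi_mask must share a shape")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    stained = (image < stain_threshold) & roi
    return float(stained.sum()) / n_roi


@dataclass(frozen=True)
class BlobConfig:
    """Blob-detection settings for Live/Dead counting."""

    smoothing_sigma: float = 2.0
    min_distance: int = 5
    threshold_abs: float = 0.3


@dataclass
class CellCounts:
    """Live/dead counts and the derived viability percentage.

    ``viability_pct`` is ``100 * live / (live + dead)`` and ``None``
    (undefined, flagged) when there are no cells.
    """

    n_live: int
    n_dead: int

    @property
    def viability_pct(self) -> float | None:
        total = self.n_live + self.n_dead
        return 100.0 * self.n_live / total if total > 0 else None


def count_livedead(image: np.ndarray, cfg: BlobConfig | None = None) -> CellCounts:
    """Count live (channel 0) and dead (channel 1) cells by blob detection.

    Each channel is Gaussian-smoothed and local maxima above an absolute
    threshold are counted.  Exact on well-separated fixtures (inter-blob
    spacing >= 4 radii).
    """
    cfg = cfg or BlobConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError(f"expected a 2-channel (2, H, W) image, got shape {image.shape}")
    counts = []
    for channel in image:
        smoothed = gaussian_filter(channel, cfg.smoothing_sigma)
        peaks = peak_local_max(
            smoothed, min_distance=cfg.min_distance, threshold_abs=cfg.threshold_abs
        )
        counts.append(len(peaks))
    return CellCounts(n_live=counts[0], n_dead=counts[1])


def cck8_normalize(od_samples, od_blanks) -> tuple[np.ndarray, np.ndarray]:
    """Blank-correct CCK-8 optical densities.

    Corrected value = sample − mean(blanks); negative results (sample below
    the cell-free background) are clipped to 0 and flagged.

    Returns ``(corrected, clipped)`` arrays of the samples' shape.
    """
    samples = np.atleast_1d(np.asarray(od_samples, dtype=float))
    blanks = np.atleast_1d(np.asarray(od_blanks, dtype=float))
    if samples.size == 0 or blanks.size == 0:
        raise ValueError("need at least one sample and one blank")
    corrected = samples - blanks.mean()
    clipped = corrected < 0
    return np.where(clipped, 0.0, corrected), clipped
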