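"""Phase-contrast and fluorescence segmentation of adherent colonies.

The phase pipeline exploits the phase halo: colonies carry a bright rim, so
a white top-hat extracts bright morphological features, a percentile
contrast stretch normalises exposure, Otsu (or a fixed cut) binarises, small
specks are removed, and hole filling recovers colony interiors enclosed by
their rims. All outputs are boolean masks and dimensionless area fractions —
every downstream readout (fold increase, reporter fraction) is a ratio, so
no µm-per-pixel calibration is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, morphology
from skimage.filters import threshold_otsu

from ..transport import InvalidParameterError


@dataclass(frozen=True)
class SegmentationParams:
    tophat_radius: int = 15
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    threshold_method: str = "otsu"  # or "fixed"
    fixed_threshold: float = 0.5
    min_object_px: int = 64
    #: minimal Otsu inter-class separation (raw normalised units) below which a
    #: fluorescence image is declared signal-free instead of thresholding noise
    min_contrast: float = 0.10

    def __post_init__(self) -> None:
        lo, hi = self.stretch_percentiles
        if not 0.0 <= lo < hi <= 100.0:
            raise InvalidParameterError("stretch percentiles must satisfy 0 <= lo < hi <= 100")
        if self.tophat_radius <= 0:
            raise InvalidParameterError("tophat_radius must be > 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise InvalidParameterError("threshold_method must be 'otsu' or 'fixed'")


@dataclass(frozen=True)
class AreaMeasurement:
    image_id: str
    cell_area_fraction: float


@dataclass(frozen=True)
class Sox1Result:
    """Reporter-positive area over total cell area; NaN + flag when no cells."""

    sox1_area_fraction_of_cells: float
    defined: bool = True


def _as_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise InvalidParameterError("expected a 2D grayscale image")
    img = image.astype(float)
    if np.issubdtype(image.dtype, np.integer):
        img /= np.iinfo(image.dtype).max
    return img


def _stretch(img: np.ndarray, percentiles: tuple[float, float]) -> np.ndarray:
    lo, hi = np.percentile(img, percentiles)
    if hi <= lo:
        return np.zeros_like(img)
    return exposure.rescale_intensity(img, in_range=(lo, hi), out_range=(0.0, 1.0))


def _threshold(img: np.ndarray, params: SegmentationParams) -> np.ndarray | None:
    if params.threshold_method == "fixed":
        return img > params.fixed_threshold
    if np.ptp(img) == 0:
        return None  # degenerate histogram
    return img > threshold_otsu(img)


def segment_phase(image: np.ndarray,
                  params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Boolean cell mask from a phase-contrast image.

    Pipeline order is fixed: white top-hat (radius ``tophat_radius``) →
    percentile contrast stretch → threshold → remove objects smaller than
    ``min_object_px`` → fill holes. A constant image under Otsu yields an
    empty mask with a warning.
    """
    img = _as_float(image)
    footprint = morphology.disk(params.tophat_radius, decomposition="sequence")
    bright = morphology.white_tophat(img, footprint=footprint)
    stretched = _stretch(bright, params.stretch_percentiles)
    binary = _threshold(stretched, params)
    if binary is None:
        warnings.warn("constant image: Otsu threshold undefined, returning empty mask",
                      stacklevel=2)
        return np.zeros_like(img, dtype=bool)
    cleaned = morphology.remove_small_objects(binary, max_size=params.min_object_px - 1)
    return ndi.binary_fill_holes(cleaned)


def segment_fluorescence(image: np.ndarray,
                         params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Boolean reporter mask: contrast stretch → threshold (no top-hat).

    Before thresholding, the raw image is checked for genuine signal: if the
    Otsu inter-class separation is below ``min_contrast`` the channel is
    treated as background-only (noise must not be stretched into a mask).
    """
    img = _as_float(image)
    if np.ptp(img) == 0:
        return np.zeros_like(img, dtype=bool)  # flat field: no signal
    t = threshold_otsu(img)
    fg, bg = img[img > t], img[img <= t]
    if fg.size == 0 or bg.size == 0 or fg.mean() - bg.mean() < params.min_contrast:
        return np.zeros_like(img, dtype=bool)
    stretched = _stretch(img, params.stretch_percentiles)
    binary = _threshold(stretched, params)
    if binary is None:
        return np.zeros_like(img, dtype=bool)
    return morphology.remove_small_objects(binary, max_size=params.min_object_px - 1)


def cell_area(mask: np.ndarray) -> float:
    """Foreground fraction of a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum()) / mask.size


def fold_increase(area_t: float, area_0: float) -> float:
    """Cell area at time t over the initial attached-cell area."""
    if area_0 <= 0:
        raise InvalidParameterError("initial area must be > 0 for a fold increase")
    return area_t / area_0


def sox1_fraction(phase_mask: np.ndarray, fluor_image: np.ndarray,
                  params: SegmentationParams = SegmentationParams()) -> Sox1Result:
    """Reporter-positive fraction of the cell area.

    The fluorescence channel is segmented (stretch → threshold) and
    intersected with the phase mask; the intersection guarantees the
    fraction lies in [0, 1]. An empty phase mask yields an undefined
    (NaN, flagged) result.
    """
    phase_mask = np.asarray(phase_mask, dtype=bool)
    if phase_mask.shape != np.asarray(fluor_image).shape:
        raise InvalidParameterError("phase mask and fluorescence image shapes differ")
    n_cells = int(phase_mask.sum())
    if n_cells == 0:
        return Sox1Result(sox1_area_fraction_of_cells=float("nan"), defined=False)
    fluor_mask = segment_fluorescence(fluor_image, params)
    return Sox1Result(float((fluor_mask & phase_mask).sum()) / n_cells)
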