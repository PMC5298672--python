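"""Convert a spectrometer photograph into a 1000-point wavelength-calibrated spectrum.

The device photographs a diffracted visible-light spectrum: the image shows a
bright circular aperture enclosing a horizontal spectrum band.  Extraction
proceeds in four steps:

1. :func:`detect_roi` — threshold the summed-RGB image, take the largest
   connected bright component, fit its minimum enclosing circle, and place the
   spectrum band box at a fixed position relative to the circle (the band sits
   in the same place in the aperture; only the aperture's position and size
   drift between photographs, e.g. after the camera is re-seated).
2. :func:`extract_column_means` — mean summed-RGB intensity (0–765) of each
   pixel column inside the band box; this is taken as a reflectance proxy.
3. :func:`resample_to_scale` — map the 700–800-odd source columns onto a fixed
   1..1000 scale, leaving single-position gaps where no column lands.
4. :func:`fill_gaps` — interpolate the gaps from their occupied neighbours.

Position ``p`` on the 1..1000 scale corresponds to a wavelength of
``390 + (p - 1) * 310 / 999`` nanometres: the band's left and right edges are
calibrated to 390 nm and 700 nm.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy.spatial import ConvexHull, QhullError
from shapely import MultiPoint, minimum_bounding_circle, minimum_bounding_radius
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import (
    AllGaps,
    AmbiguousRegion,
    EmptyBand,
    NoRegionFound,
    OutOfRange,
    TooFewColumns,
)

N_POINTS = 1000
WAVELENGTH_MIN_NM = 390.0
WAVELENGTH_MAX_NM = 700.0
MAX_RGB_SUM = 765.0  # 3 * 255


@dataclass(frozen=True)
class ExtractionConfig:
    """Device calibration constants for image→spectrum extraction.

    Parameters
    ----------
    threshold_frac : float
        Brightness threshold for aperture detection, as a fraction of the
        maximum summed-RGB value (765).
    use_otsu : bool
        If True, replace the fixed threshold with Otsu's method on the
        summed-RGB image.
    band_x_frac, band_y_frac : float
        Half-extent of the spectrum band box, as fractions of the circle
        radius.  The defaults place a wide, thin horizontal band through the
        circle centre.  These are device constants: the band is always in the
        same position within the aperture.
    flip : bool
        Reverse column order before resampling (for devices whose optics put
        long wavelengths on the left).
    min_band_width, max_band_width : int
        Plausibility bounds on the band-box width in pixels; the real device
        produces 700–800 columns.
    """

    threshold_frac: float = 0.2
    use_otsu: bool = False
    band_x_frac: float = 0.8
    band_y_frac: float = 0.1
    flip: bool = False
    min_band_width: int = 200
    max_band_width: int = 2000


@dataclass(frozen=True)
class RegionOfInterest:
    """Detected aperture circle and the spectrum band box placed inside it.

    ``band_box`` is ``(left, top, right, bottom)`` in pixel coordinates with
    half-open bounds, i.e. the band is ``image[top:bottom, left:right]``.
    """

    center_x: float
    center_y: float
    radius: float
    band_box: tuple[int, int, int, int]

    @property
    def band_width(self) -> int:
        return self.band_box[2] - self.band_box[0]

    @property
    def band_height(self) -> int:
        return self.band_box[3] - self.band_box[1]


@dataclass
class RawSpectrum:
    """Column intensities on the 1..1000 scale, before gap filling.

    ``values[p-1]`` holds the mean intensity at scale position ``p`` where
    occupied, ``nan`` where no source column mapped there; ``gap_mask`` is
    True at the gaps.
    """

    values: np.ndarray
    gap_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.values.shape != (N_POINTS,) or self.gap_mask.shape != (N_POINTS,):
            raise ValueError(f"RawSpectrum must have exactly {N_POINTS} positions")


@dataclass
class Spectrum:
    """A gap-free 1000-point spectrum on the 390–700 nm axis."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_POINTS,):
            raise ValueError(f"Spectrum must have exactly {N_POINTS} values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Spectrum values must be finite")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        """Wavelength axis: position p maps to 390 + (p-1)*310/999 nm."""
        return position_to_wavelength(np.arange(1, N_POINTS + 1))

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, N_POINTS + 1)


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG photograph as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def _as_rgb_array(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image array")
    return arr


def detect_roi(image, config: ExtractionConfig | None = None,
               threshold_frac: float | None = None) -> RegionOfInterest:
    """Locate the bright aperture circle and place the spectrum band box.

    The summed-RGB image is thresholded (fixed fraction of 765 by default, or
    Otsu), the largest connected bright component is taken as the aperture,
    and its minimum enclosing circle fitted.  The band box is positioned at
    the configured fractional coordinates relative to the circle.

    Raises
    ------
    NoRegionFound
        If no pixel exceeds the threshold.
    AmbiguousRegion
        If the two largest bright components differ in area by < 10 %.
    """
    cfg = config or ExtractionConfig()
    if threshold_frac is not None:
        cfg = dataclasses.replace(cfg, threshold_frac=threshold_frac)
    arr = _as_rgb_array(image)
    gray = arr.sum(axis=2, dtype=np.float64)

    if cfg.use_otsu:
        thresh = threshold_otsu(gray)
    else:
        thresh = cfg.threshold_frac * MAX_RGB_SUM
    mask = gray > thresh
    if not mask.any():
        raise NoRegionFound(f"no pixel above threshold {thresh:.1f} (summed RGB)")

    labels = label(mask, connectivity=2)
    props = sorted(regionprops(labels), key=lambda r: r.area, reverse=True)
    if len(props) >= 2 and props[0].area > 0:
        rel_diff = (props[0].area - props[1].area) / props[0].area
        if rel_diff < 0.10:
            raise AmbiguousRegion(
                f"two bright regions of nearly equal area "
                f"({props[0].area} vs {props[1].area} px)"
            )
    component = props[0]

    # minimum enclosing circle of the component, via its convex hull
    coords = component.coords[:, ::-1].astype(float)  # (x, y)
    try:
        hull_pts = coords[ConvexHull(coords).vertices]
    except QhullError:  # tiny or collinear component
        hull_pts = coords
    geom = MultiPoint(hull_pts)
    circle = minimum_bounding_circle(geom)
    cx, cy = circle.centroid.x, circle.centroid.y
    radius = minimum_bounding_radius(geom)

    left = int(round(cx - cfg.band_x_frac * radius))
    right = int(round(cx + cfg.band_x_frac * radius))
    top = int(round(cy - cfg.band_y_frac * radius))
    bottom = int(round(cy + cfg.band_y_frac * radius))
    h, w = gray.shape
    left, right = max(left, 0), min(right, w)
    top, bottom = max(top, 0), min(bottom, h)

    width = right - left
    if not (cfg.min_band_width <= width <= cfg.max_band_width):
        warnings.warn(
            f"band box width {width} px outside plausible range "
            f"[{cfg.min_band_width}, {cfg.max_band_width}]",
            stacklevel=2,
        )
    return RegionOfInterest(center_x=cx, center_y=cy, radius=radius,
                            band_box=(left, top, right, bottom))


def extract_column_means(image, roi: RegionOfInterest) -> list[tuple[int, float]]:
    """Mean summed-RGB intensity of each pixel column of the band box.

    Returns one ``(column_index, intensity)`` pair per column, with the
    intensity in [0, 765] — the mean over the band rows of R+G+B.
    """
    arr = _as_rgb_array(image)
    left, top, right, bottom = roi.band_box
    if right <= left or bottom <= top:
        raise EmptyBand("band box has zero area")
    band = arr[top:bottom, left:right].astype(np.float64)
    col_means = band.sum(axis=2).mean(axis=0)
    return [(left + i, float(v)) for i, v in enumerate(col_means)]


def resample_to_scale(columns: list[tuple[int, float]],
                      n_points: int = N_POINTS) -> RawSpectrum:
    """Map N source columns onto the fixed 1..n scale.

    Column i (1-based, of N) maps to position ``round(1 + (i-1)*(n-1)/(N-1))``
    with round-half-up, so the first column lands on 1 and the last on n.
    Positions receiving no column are flagged as gaps; positions receiving
    several columns get their mean.
    """
    n_cols = len(columns)
    if n_cols < 2:
        raise TooFewColumns(f"need at least 2 source columns, got {n_cols}")
    intensities = np.array([v for _, v in columns], dtype=float)
    i = np.arange(n_cols, dtype=float)
    pos = np.floor(1 + i * (n_points - 1) / (n_cols - 1) + 0.5).astype(int)  # round half up

    sums = np.zeros(n_points)
    counts = np.zeros(n_points)
    np.add.at(sums, pos - 1, intensities)
    np.add.at(counts, pos - 1, 1)
    gap_mask = counts == 0
    values = np.full(n_points, np.nan)
    occ = ~gap_mask
    values[occ] = sums[occ] / counts[occ]
    return RawSpectrum(values=values, gap_mask=gap_mask)


def fill_gaps(raw: RawSpectrum) -> Spectrum:
    """Fill gap positions from their occupied neighbours.

    A single-position gap gets the mean of its two flanking neighbours; a
    wider gap is filled by linear interpolation between the flanking occupied
    positions (which degenerates to the neighbour mean for width-1 gaps); a
    gap at either end copies the nearest occupied value.  Occupied positions
    are never modified.
    """
    occ = ~raw.gap_mask
    if not occ.any():
        raise AllGaps("raw spectrum has no occupied positions")
    idx = np.arange(N_POINTS)
    filled = np.interp(idx, idx[occ], raw.values[occ])
    filled[occ] = raw.values[occ]  # exact pass-through of occupied values
    return Spectrum(values=filled)


def position_to_wavelength(p):
    """Wavelength in nm for position(s) p on the 1..1000 scale.

    ``p = 1`` maps to 390 nm and ``p = 1000`` to 700 nm, linearly.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 1) or np.any(p > N_POINTS):
        raise OutOfRange("position must lie in [1, 1000]")
    wl = WAVELENGTH_MIN_NM + (p - 1) * (WAVELENGTH_MAX_NM - WAVELENGTH_MIN_NM) / (N_POINTS - 1)
    return float(wl) if wl.ndim == 0 else wl


def extract_spectrum(image, config: ExtractionConfig | None = None) -> Spectrum:
    """Full photograph→spectrum pipeline.

    Composition of ROI detection, column means, 1000-scale resampling and gap
    filling; deterministic for a fixed image and configuration.
    """
    cfg = config or ExtractionConfig()
    roi = detect_roi(image, cfg)
    columns = extract_column_means(image, roi)
    if cfg.flip:
        vals = [v for _, v in columns][::-1]
        columns = [(i, v) for (i, _), v in zip(columns, vals)]
    raw = resample_to_scale(columns)
    return fill_gaps(raw)
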