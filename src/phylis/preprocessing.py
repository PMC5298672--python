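"""Chemometric preprocessing of 1000-point spectra.

Four base transforms — none, first derivative, second derivative, and
first-order Savitzky–Golay smoothing — each optionally followed by
moving-window baseline subtraction (default window radius 20 positions), and
always finishing with normalisation to an absolute maximum of 1.  The full
grid is the 4 × 2 combinations enumerated by :func:`preprocess_grid`.

All operations are length-preserving.  Windowed operations shrink their
window at the spectrum ends rather than padding, so no data is invented
beyond the measured range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ZeroSpectrumWarning
from .image_extraction import Spectrum


class Method(str, Enum):
    """Base preprocessing transform."""

    NONE = "none"
    DERIV1 = "deriv1"
    DERIV2 = "deriv2"
    SAVGOL1 = "savgol1"


@dataclass(frozen=True)
class PreprocessSpec:
    """One cell of the preprocessing grid.

    Parameters
    ----------
    method : Method
        Base transform applied first.
    window_subtract : bool
        Whether moving-window baseline subtraction follows the base transform.
    window_radius : int
        Half-width of the subtraction window, in scale positions.
    savgol_window : int
        Odd full width of the Savitzky–Golay window.
    """

    method: Method = Method.NONE
    window_subtract: bool = False
    window_radius: int = 20
    savgol_window: int = 11

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")
        if self.savgol_window < 3 or self.savgol_window % 2 == 0:
            raise ValueError("savgol_window must be odd and >= 3")

    @property
    def name(self) -> str:
        suffix = "+mws" if self.window_subtract else ""
        return f"{Method(self.method).value}{suffix}"


def _as_series(s) -> np.ndarray:
    if isinstance(s, Spectrum):
        s = s.values
    return np.asarray(s, dtype=float)


def first_derivative(s) -> np.ndarray:
    """First-order derivative: central differences, one-sided at the ends."""
    return np.gradient(_as_series(s))


def second_derivative(s) -> np.ndarray:
    """Second-order derivative: s[p+1] - 2 s[p] + s[p-1] in the interior.

    The two end positions replicate the nearest interior value.
    """
    x = _as_series(s)
    out = np.empty_like(x)
    out[1:-1] = x[2:] - 2 * x[1:-1] + x[:-2]
    out[0] = out[1]
    out[-1] = out[-2]
    return out


def _window_sums(x: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Shrink-to-fit windowed sums and counts via cumulative sums."""
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - radius, 0)
    hi = np.minimum(idx + radius, n - 1)
    c = np.concatenate(([0.0], np.cumsum(x)))
    sums = c[hi + 1] - c[lo]
    counts = (hi - lo + 1).astype(float)
    return sums, counts


def savgol_smooth(s, window: int = 11, polyorder: int = 1) -> np.ndarray:
    """First-order Savitzky–Golay smoothing with shrink-to-fit edges.

    At each position a least-squares line is fitted over the window centred
    there (truncated at the spectrum ends) and evaluated at the centre.  For
    a full symmetric window this equals the classical Savitzky–Golay
    moving-average weights for polynomial order 1.
    """
    if polyorder != 1:
        raise ValueError("only first-order (linear) smoothing is supported")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    x = _as_series(s)
    n = x.size
    radius = window // 2
    j = np.arange(n, dtype=float)
    s0_y, cnt = _window_sums(x, radius)
    s_j, _ = _window_sums(j, radius)
    s_jj, _ = _window_sums(j * j, radius)
    s_jy, _ = _window_sums(j * x, radius)
    # linear fit y = a + b*(j - j̄), evaluated at the centre position p
    jbar = s_j / cnt
    ybar = s0_y / cnt
    sxx = s_jj - s_j * jbar
    sxy = s_jy - s_j * ybar
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(sxx > 0, sxy / sxx, 0.0)
    return ybar + b * (j - jbar)


def moving_window_subtract(s, radius: int = 20) -> np.ndarray:
    """Local baseline removal: subtract the mean of the surrounding window.

    ``out[p] = s[p] - mean(s[p-radius .. p+radius])`` with the window
    truncated at the ends.  Annihilates constant spectra everywhere and
    linear ramps in the interior.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    x = _as_series(s)
    sums, counts = _window_sums(x, radius)
    return x - sums / counts


def normalize_absmax(s) -> np.ndarray:
    """Scale a series so its absolute maximum is exactly 1.

    Idempotent and invariant to positive rescaling.  An all-zero series is
    returned unchanged with a :class:`ZeroSpectrumWarning`.
    """
    x = _as_series(s)
    m = np.max(np.abs(x))
    if m == 0:
        warnings.warn("all-zero series cannot be normalised; returning zeros",
                      ZeroSpectrumWarning, stacklevel=2)
        return x.copy()
    return x / m


def apply_preprocess(s, spec: PreprocessSpec) -> np.ndarray:
    """Apply one preprocessing combination: method → subtraction → normalise."""
    x = _as_series(s)
    if spec.method in (Method.NONE, "none"):
        out = x.copy()
    elif spec.method in (Method.DERIV1, "deriv1"):
        out = first_derivative(x)
    elif spec.method in (Method.DERIV2, "deriv2"):
        out = second_derivative(x)
    elif spec.method in (Method.SAVGOL1, "savgol1"):
        out = savgol_smooth(x, window=spec.savgol_window, polyorder=1)
    else:
        raise ValueError(f"unknown method: {spec.method!r}")
    if spec.window_subtract:
        out = moving_window_subtract(out, radius=spec.window_radius)
    return normalize_absmax(out)


def preprocess_grid(window_radius: int = 20,
                    savgol_window: int = 11) -> list[PreprocessSpec]:
    """The full 4 methods × 2 subtraction-flag grid (8 combinations)."""
    return [
        PreprocessSpec(method=m, window_subtract=ws,
                       window_radius=window_radius, savgol_window=savgol_window)
        for m in Method
        for ws in (False, True)
    ]
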