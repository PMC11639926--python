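"""Enhancement of demodulated images: equalization, ratio image, median filter.

The AC image carries the bruise contrast but inherits the illumination and
curvature shading of the fruit (bright center, dark rim), which breaks
global thresholding.  Dividing AC by DC cancels any multiplicative gain
common to both -- the ratio image RT = AC/DC is flat over sound tissue
while the bruise, which suppresses the modulated component much more than
the mean reflectance, stays dark.  A median filter then removes the small
dark speckle left by surface pits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .demodulation import DemodulatedPair, ForegroundMask
from .utils import N_LEVELS, as_image, check_same_shape, from_levels, to_levels

logger = logging.getLogger(__name__)

#: division guard: DC below one 8-bit quantum carries no signal
DIVISION_EPS = 1.0 / 255.0


@dataclass(frozen=True)
class RatioImage:
    """AC/DC ratio image, zero outside the mask, with division-guard count."""

    rt: np.ndarray
    mask: ForegroundMask
    n_guarded: int = 0

    def __post_init__(self):
        rt = as_image(self.rt, "rt")
        if (rt < 0).any():
            raise ValueError("rt must be >= 0")
        object.__setattr__(self, "rt", rt)
        check_same_shape(rt, self.mask.mask)


def histogram_equalize(image: np.ndarray, mask: ForegroundMask | np.ndarray) -> np.ndarray:
    """Global 256-level histogram equalization over masked pixels.

    The classic integer mapping ``(cdf(v) - cdf_min) / (n - cdf_min)`` is
    computed from masked pixels only; background stays 0.  The mapping is
    monotone, so the rank order of masked pixels is preserved.  A constant
    masked region (degenerate histogram) is returned unchanged.
    """
    arr = as_image(image)
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)
    check_same_shape(arr, m)
    if not m.any():
        raise ValueError("mask is empty")
    levels = to_levels(arr)
    counts = np.bincount(levels[m], minlength=N_LEVELS)
    cdf = np.cumsum(counts)
    n = cdf[-1]
    cdf_min = cdf[np.nonzero(counts)[0][0]]
    if n == cdf_min:  # all masked pixels share one level
        return arr * m
    lut = np.floor((cdf - cdf_min) / (n - cdf_min) * (N_LEVELS - 1) + 0.5)
    out = from_levels(lut[levels])
    return out * m


def ratio_image(
    pair: DemodulatedPair,
    mask: ForegroundMask,
    eps: float = DIVISION_EPS,
    equalize_ac: bool = False,
) -> RatioImage:
    """Compute RT = AC/DC inside the mask; guard pixels with DC <= eps.

    ``equalize_ac=True`` equalizes the AC image over the mask before the
    division; the default consumes the raw demodulated AC.
    """
    check_same_shape(pair.ac, pair.dc, mask.mask)
    ac = histogram_equalize(pair.ac, mask) if equalize_ac else pair.ac
    ok = mask.mask & (pair.dc > eps)
    n_guarded = int((mask.mask & ~ok).sum())
    if n_guarded:
        logger.info("ratio_image: %d masked pixels guarded (DC <= %g)", n_guarded, eps)
    rt = np.zeros_like(pair.ac)
    np.divide(ac, pair.dc, out=rt, where=ok)
    rt[~ok] = 0.0
    return RatioImage(rt=rt, mask=mask, n_guarded=n_guarded)


def median_filter(
    image: np.ndarray,
    window: tuple[int, int] = (10, 10),
    mask: ForegroundMask | np.ndarray | None = None,
) -> np.ndarray:
    """Sliding-window median with reflect (symmetric) edge padding.

    For an even window dimension ``s`` the output pixel sits at position
    ``ceil(s/2)`` (1-based) within the window, i.e. the window extends
    ``ceil(s/2) - 1`` pixels before and ``s - ceil(s/2)`` after the output
    pixel.  Odd windows are centered as usual.

    With ``mask`` given, background pixels are excluded from every window
    (so the zeroed background cannot bleed a dark rim into the fruit edge)
    and the output is 0 outside the mask.
    """
    arr = as_image(image)
    h, w = int(window[0]), int(window[1])
    if h < 1 or w < 1:
        raise ValueError("window must be >= 1 in each dimension")
    if h > arr.shape[0] or w > arr.shape[1]:
        raise ValueError("window larger than image")
    before_r = (h + 1) // 2 - 1
    before_c = (w + 1) // 2 - 1
    pad = ((before_r, h - 1 - before_r), (before_c, w - 1 - before_c))
    if mask is None:
        padded = np.pad(arr, pad, mode="symmetric")
        windows = np.lib.stride_tricks.sliding_window_view(padded, (h, w))
        return np.median(windows, axis=(2, 3))
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)
    check_same_shape(arr, m)
    work = np.where(m, arr, np.nan)
    padded = np.pad(work, pad, mode="symmetric")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (h, w))
    with warnings.catch_warnings():
        # windows fully outside the mask are all-NaN by construction
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmedian(windows, axis=(2, 3))
    out[~m] = 0.0
    return np.nan_to_num(out, nan=0.0)


def rescale_unit(image: np.ndarray, mask: ForegroundMask | np.ndarray) -> np.ndarray:
    """Linearly rescale masked pixels to span [0, 1]; background stays 0.

    Ratio images have no fixed range, so they are min-max rescaled over
    the mask before 256-level quantization.  A constant masked region maps
    to 0.
    """
    arr = as_image(image)
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)
    check_same_shape(arr, m)
    if not m.any():
        raise ValueError("mask is empty")
    lo = arr[m].min()
    hi = arr[m].max()
    if hi <= lo:
        return np.zeros_like(arr)
    out = (arr - lo) / (hi - lo)
    np.clip(out, 0.0, 1.0, out=out)
    return out * m
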