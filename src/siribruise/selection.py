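"""Acquisition-parameter selection from line-profile contrast.

The spatial frequency and wavelength used for the full survey are chosen
by profiling pixel intensity along a line through the bruise in AC images
acquired at each candidate (f, lambda) pair: the peak-to-valley difference
between sound tissue and the bruise valley measures how separable the
bruise will be for thresholding, and the pair with the largest contrast
wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as bresenham_line

from . import demodulation
from .phantom import PhantomSample, PhantomSpec, render_phantom
from .utils import as_image

__all__ = [
    "LineProfile",
    "extract_line_profile",
    "peak_to_valley_contrast",
    "rank_parameters",
    "bruise_profile",
    "contrast_table_from_phantoms",
]

#: columns of a contrast table
CONTRAST_COLUMNS = ("frequency_cyc_per_mm", "wavelength_nm", "contrast")


@dataclass(frozen=True)
class LineProfile:
    """Intensities sampled along a straight segment of the image."""

    positions: np.ndarray  # index 0..len-1 along the segment
    intensities: np.ndarray
    endpoints: tuple[tuple[int, int], tuple[int, int]]  # ((r0,c0), (r1,c1))

    def __post_init__(self):
        if len(self.positions) < 2:
            raise ValueError("a profile needs at least two samples")
        if not np.isfinite(self.intensities).all():
            raise ValueError("profile intensities must be finite")

    def __len__(self) -> int:
        return len(self.positions)


def extract_line_profile(
    image: np.ndarray, endpoints: tuple[tuple[int, int], tuple[int, int]]
) -> LineProfile:
    """Sample the image along the Bresenham segment between two pixels.

    Nearest-pixel sampling (no interpolation): the profile visits exactly
    the rasterized pixels of the segment.
    """
    arr = as_image(image)
    (r0, c0), (r1, c1) = endpoints
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r < arr.shape[0] and 0 <= c < arr.shape[1]):
            raise ValueError(f"endpoint ({r}, {c}) outside image {arr.shape}")
    rr, cc = bresenham_line(int(r0), int(c0), int(r1), int(c1))
    return LineProfile(
        positions=np.arange(len(rr)),
        intensities=arr[rr, cc],
        endpoints=((int(r0), int(c0)), (int(r1), int(c1))),
    )


def peak_to_valley_contrast(
    profile: LineProfile,
    bruise_window: np.ndarray,
    normal_window: np.ndarray,
) -> float:
    """Peak-to-valley contrast between sound tissue and the bruise.

    ``max(intensity over normal window) - min(intensity over bruise
    window)``, floored at 0.  Windows are index arrays (or boolean masks)
    into the profile and must not overlap.
    """
    n = len(profile)

    def _as_index(wdw, name):
        w = np.asarray(wdw)
        if w.dtype == bool:
            if w.shape != (n,):
                raise ValueError(f"{name} boolean mask must match profile length")
            w = np.nonzero(w)[0]
        if w.size == 0:
            raise ValueError(f"{name} is empty")
        if w.min() < 0 or w.max() >= n:
            raise ValueError(f"{name} indices outside profile")
        return w

    bw = _as_index(bruise_window, "bruise_window")
    nw = _as_index(normal_window, "normal_window")
    if np.intersect1d(bw, nw).size:
        raise ValueError("bruise and normal windows overlap")
    contrast = float(profile.intensities[nw].max() - profile.intensities[bw].min())
    return max(contrast, 0.0)


def rank_parameters(table: pd.DataFrame) -> tuple[float, float]:
    """Pick the (frequency, wavelength) row with maximal contrast.

    Ties resolve towards lower frequency, then lower wavelength.  The
    result is independent of row order.
    """
    if table.empty:
        raise ValueError("contrast table is empty")
    missing = set(CONTRAST_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"contrast table lacks columns {sorted(missing)}")
    ordered = table.sort_values(
        ["contrast", "frequency_cyc_per_mm", "wavelength_nm"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    best = ordered.iloc[0]
    return float(best["frequency_cyc_per_mm"]), float(best["wavelength_nm"])


def bruise_profile(
    sample: PhantomSample, image: np.ndarray, margin: int = 5
) -> tuple[LineProfile, np.ndarray, np.ndarray]:
    """Profile a horizontal line through the bruise of a phantom.

    Returns the profile plus bruise/normal windows derived from the ground
    truth: the bruise window covers truth-bruise pixels on the line, the
    normal window sound-disc pixels at least ``margin`` px away from the
    bruise and clear of the shaded rim.
    """
    if not sample.truth_bruise.any():
        raise ValueError("sample has no bruise to profile")
    rows, cols = np.nonzero(sample.truth_bruise)
    row = int(round(rows.mean()))
    h, w = sample.truth_bruise.shape
    profile = extract_line_profile(image, ((row, 0), (row, w - 1)))
    dilated = ndimage.binary_dilation(sample.truth_bruise, iterations=margin)
    eroded_disc = ndimage.binary_erosion(sample.truth_disc, iterations=margin)
    bruise_window = np.nonzero(sample.truth_bruise[row])[0]
    normal_window = np.nonzero(eroded_disc[row] & ~dilated[row])[0]
    return profile, bruise_window, normal_window


def contrast_table_from_phantoms(
    spec: PhantomSpec,
    frequencies: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20),
    wavelengths: tuple[float, ...] = (700.0, 750.0, 800.0),
) -> pd.DataFrame:
    """Tabulate AC-image bruise contrast over a (frequency, wavelength) grid.

    For each pair, a phantom is rendered from ``spec`` (which must carry a
    bruise), demodulated after reference correction, and the peak-to-valley
    contrast of a line profile through the bruise is recorded.
    """
    if spec.bruise is None:
        raise ValueError("spec must define a bruise")
    rows = []
    for lam in wavelengths:
        for f in frequencies:
            sample = render_phantom(spec, f, lam)
            corrected = demodulation.correct_triplet(sample.triplet, sample.references)
            pair = demodulation.demodulate_three_phase(corrected)
            mask = demodulation.create_background_mask(pair)
            ac = demodulation.apply_mask(pair.ac, mask)
            profile, bruise_w, normal_w = bruise_profile(sample, ac)
            contrast = peak_to_valley_contrast(profile, bruise_w, normal_w)
            rows.append({"frequency_cyc_per_mm": f, "wavelength_nm": lam, "contrast": contrast})
    return pd.DataFrame(rows, columns=list(CONTRAST_COLUMNS))
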