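"""Reference calibration, three-phase demodulation, and foreground masking.

Structured-illumination reflectance imaging (SIRI) projects a sinusoidal
intensity pattern of spatial frequency ``f`` (cycle/mm) onto the sample and
records three pattern images at phase offsets -2*pi/3, 0 and 2*pi/3.  The
triplet is demodulated pixelwise into

* a DC image -- the phase-independent mean, equivalent to a reflectance
  image under uniform illumination, and
* an AC image -- the amplitude of the modulated component, which carries
  depth-resolved contrast tied to the illumination frequency.

Raw pattern images are first flat-field / dark-frame corrected against a
white reference (diffuse plate) and a black reference (capped lens), which
removes the source's spatial intensity profile and the sensor dark level.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np

from .utils import as_image, check_same_shape, to_levels

logger = logging.getLogger(__name__)

#: canonical phase offsets of the projected patterns, in radians
PHASE_OFFSETS: tuple[float, float, float] = (-2.0 * math.pi / 3.0, 0.0, 2.0 * math.pi / 3.0)

#: default 8-bit gray level separating fruit from background in DC images
DEFAULT_BACKGROUND_THRESHOLD = 15


def _check_phase(phase: float) -> float:
    for canonical in PHASE_OFFSETS:
        if abs(phase - canonical) < 1e-9:
            return canonical
    raise ValueError(
        f"phase_offset {phase!r} is not one of the canonical offsets "
        f"-2pi/3, 0, 2pi/3"
    )


@dataclass(frozen=True)
class RawPatternImage:
    """One pattern image plus its acquisition metadata.

    Parameters
    ----------
    pixels
        2-D reflectance image, real-valued, nominally in [0, 1].
    phase_offset
        Phase of the projected sinusoid, one of -2*pi/3, 0, 2*pi/3 (rad).
    spatial_frequency
        Illumination spatial frequency on the sample, cycle/mm, >= 0.
    wavelength
        Center wavelength of the acquisition band, nm.
    pixel_pitch
        Sample-plane size of one pixel, mm/pixel.
    """

    pixels: np.ndarray
    phase_offset: float
    spatial_frequency: float
    wavelength: float
    pixel_pitch: float

    def __post_init__(self):
        object.__setattr__(self, "pixels", as_image(self.pixels, "pixels"))
        if (self.pixels < 0).any():
            raise ValueError("pixel values must be >= 0")
        object.__setattr__(self, "phase_offset", _check_phase(self.phase_offset))
        if self.spatial_frequency < 0:
            raise ValueError("spatial_frequency must be >= 0")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ReferencePair:
    """White (diffuse plate) and black (capped lens) reference images."""

    white: np.ndarray
    black: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "white", as_image(self.white, "white"))
        object.__setattr__(self, "black", as_image(self.black, "black"))
        check_same_shape(self.white, self.black)

    @property
    def valid(self) -> np.ndarray:
        """Boolean map of pixels where white > black (calibration defined)."""
        return self.white > self.black


@dataclass(frozen=True)
class PhaseTriplet:
    """Three co-registered pattern images at the three canonical phases."""

    images: tuple[RawPatternImage, RawPatternImage, RawPatternImage]

    def __post_init__(self):
        images = tuple(self.images)
        if len(images) != 3:
            raise ValueError("a PhaseTriplet needs exactly three images")
        object.__setattr__(self, "images", images)
        check_same_shape(*(im.pixels for im in images))
        phases = tuple(im.phase_offset for im in images)
        if phases != PHASE_OFFSETS:
            raise ValueError(
                f"phase offsets must be (-2pi/3, 0, 2pi/3) in order, got {phases}"
            )
        for attr in ("spatial_frequency", "wavelength", "pixel_pitch"):
            vals = {getattr(im, attr) for im in images}
            if len(vals) > 1:
                raise ValueError(f"images disagree on {attr}: {sorted(vals)}")

    @property
    def spatial_frequency(self) -> float:
        return self.images[0].spatial_frequency

    @property
    def wavelength(self) -> float:
        return self.images[0].wavelength

    @property
    def pixel_pitch(self) -> float:
        return self.images[0].pixel_pitch

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape


@dataclass(frozen=True)
class DemodulatedPair:
    """AC (modulation amplitude) and DC (mean) images with metadata."""

    ac: np.ndarray
    dc: np.ndarray
    spatial_frequency: float
    wavelength: float
    pixel_pitch: float

    def __post_init__(self):
        object.__setattr__(self, "ac", as_image(self.ac, "ac"))
        object.__setattr__(self, "dc", as_image(self.dc, "dc"))
        check_same_shape(self.ac, self.dc)
        if (self.ac < 0).any():
            raise ValueError("ac must be >= 0")


@dataclass(frozen=True)
class ForegroundMask:
    """Boolean fruit-foreground mask plus the 8-bit threshold that built it."""

    mask: np.ndarray
    threshold_used: int

    def __post_init__(self):
        mask = np.asarray(self.mask)
        if mask.dtype != bool or mask.ndim != 2:
            raise ValueError("mask must be a 2-D boolean array")
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


def correct_reference(raw: RawPatternImage, refs: ReferencePair) -> RawPatternImage:
    """Flat-field / dark-frame calibrate one raw pattern image.

    Computes ``(raw - black) / (white - black)`` elementwise, clipped to
    [0, 1].  Pixels where ``white <= black`` have no defined calibration;
    they are set to 0 and counted in the log rather than propagating
    infinities.
    """
    check_same_shape(raw.pixels, refs.white, refs.black)
    valid = refs.valid
    n_invalid = int((~valid).sum())
    if n_invalid == valid.size:
        raise ValueError("reference pair has no valid pixels (white <= black everywhere)")
    if n_invalid:
        logger.warning("correct_reference: %d invalid reference pixels set to 0", n_invalid)
    out = np.zeros_like(raw.pixels)
    denom = refs.white - refs.black
    np.divide(raw.pixels - refs.black, denom, out=out, where=valid)
    np.clip(out, 0.0, 1.0, out=out)
    out[~valid] = 0.0
    return dataclasses.replace(raw, pixels=out)


def correct_triplet(triplet: PhaseTriplet, refs: ReferencePair) -> PhaseTriplet:
    """Apply :func:`correct_reference` to all three images of a triplet."""
    return PhaseTriplet(tuple(correct_reference(im, refs) for im in triplet.images))


def demodulate_three_phase(triplet: PhaseTriplet) -> DemodulatedPair:
    """Demodulate a three-phase triplet into AC and DC images.

    With I1, I2, I3 the images at phases -2*pi/3, 0, 2*pi/3::

        AC = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I1-I3)^2 + (I2-I3)^2)
        DC = (I1 + I2 + I3) / 3

    For an ideal sinusoid ``I_k = C + A*cos(phi + theta_k)`` this recovers
    AC = A and DC = C exactly, for any global phase ``phi``.
    """
    i1, i2, i3 = (im.pixels for im in triplet.images)
    ac = (math.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i1 - i3) ** 2 + (i2 - i3) ** 2
    )
    dc = (i1 + i2 + i3) / 3.0
    return DemodulatedPair(
        ac=ac,
        dc=dc,
        spatial_frequency=triplet.spatial_frequency,
        wavelength=triplet.wavelength,
        pixel_pitch=triplet.pixel_pitch,
    )


def create_background_mask(
    dc: DemodulatedPair | np.ndarray,
    threshold: int = DEFAULT_BACKGROUND_THRESHOLD,
) -> ForegroundMask:
    """Build the fruit-foreground mask from a DC image.

    The DC image (unit range) is quantized to 8-bit levels and pixels
    strictly above ``threshold`` are foreground.  The fixed default of 15
    separates the dark background from the fruit disc in DC images.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be within [0, 255]")
    dc_image = dc.dc if isinstance(dc, DemodulatedPair) else as_image(dc, "dc")
    mask = to_levels(dc_image) > threshold
    return ForegroundMask(mask=mask, threshold_used=int(threshold))


def apply_mask(image: np.ndarray, mask: ForegroundMask | np.ndarray) -> np.ndarray:
    """Zero out background pixels: ``image * mask`` elementwise."""
    arr = as_image(image)
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)
    check_same_shape(arr, m)
    return arr * m
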