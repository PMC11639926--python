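"""Synthetic SIRI phantoms: seeded fruit discs with optional bruises.

The generator renders what the imaging system would record for a roughly
spherical fruit on a dark stage: a bright disc with radial shading from
surface curvature, a projected sinusoid along image columns whose
modulation depth decays with spatial frequency and varies with wavelength,
an optional subsurface bruise (an elliptical region with strongly reduced
AC modulation and slightly reduced mean reflectance), small dark surface
pits, an optional stem/suture streak, additive Gaussian sensor noise, a
sensor dark level, and matching white/black reference frames.  Every
sample carries its ground-truth disc and bruise masks.

Image formation for phase offset theta_k::

    raw_k = dark + gain(x, y) * (Rdc + Rac * cos(2*pi*f*x_mm + theta_k)) + noise

quantized to 8-bit.  ``gain`` is the curvature shading (not removable by
flat-field calibration, since the white plate is flat), ``Rdc`` the local
mean reflectance and ``Rac = Rdc * depth`` the modulation amplitude.

The bruise's AC contrast is frequency-tuned: a subsurface defect is probed
best at an intermediate spatial frequency -- too low and most photons pass
beneath it, too high and they never reach it.  The default configuration
peaks the measurable bruise contrast at 0.10 cycle/mm and 700 nm.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .demodulation import PHASE_OFFSETS, PhaseTriplet, RawPatternImage, ReferencePair

__all__ = [
    "BruiseSpec",
    "StreakSpec",
    "PhantomSpec",
    "PhantomSample",
    "impact_energy",
    "modulation_depth",
    "bruise_frequency_response",
    "render_phantom",
    "generate_dataset",
    "DEFAULT_WAVELENGTH_GAIN",
]

#: relative AC brightness of the default acquisition bands (photon
#: efficiency and tissue reflectivity drop towards the NIR)
DEFAULT_WAVELENGTH_GAIN = {700.0: 1.0, 750.0: 0.85, 800.0: 0.70}


def impact_energy(mass: float, height: float, g: float = 9.8) -> float:
    """Impact energy E = m*g*h (J) of a ball dropped onto the fruit.

    A 100 g ball dropped from about 400 mm delivers ~0.4 J, the energy
    used to induce slight, visually inconspicuous bruises.
    """
    if mass < 0 or height < 0 or g < 0:
        raise ValueError("mass, height and g must be >= 0")
    return mass * g * height


@dataclass(frozen=True)
class BruiseSpec:
    """Elliptical subsurface bruise.

    ``ac_contrast`` is the fractional reduction of modulation amplitude at
    the most sensitive spatial frequency; ``dc_contrast`` the (much
    smaller) reduction of mean reflectance -- slight bruises are nearly
    invisible under uniform illumination.
    """

    center: tuple[float, float]  # (row, col), px
    semi_axes: tuple[float, float]  # (along rotated axis 1, axis 2), px
    ac_contrast: float = 0.55
    dc_contrast: float = 0.05
    angle: float = 0.0  # radians, rotation of the ellipse
    peak_frequency: float = 0.10  # cycle/mm of maximal AC contrast

    def __post_init__(self):
        if not 0 <= self.ac_contrast <= 1 or not 0 <= self.dc_contrast <= 1:
            raise ValueError("contrasts must lie in [0, 1]")


@dataclass(frozen=True)
class StreakSpec:
    """Dark linear streak emulating a stem or ventral suture."""

    p0: tuple[float, float]  # (row, col) endpoint, px
    p1: tuple[float, float]
    width: float = 3.0  # px
    depth: float = 0.3  # fractional reflectance drop
    ac_extra: float = 0.2  # additional fractional modulation drop


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic SIRI sample."""

    image_size: tuple[int, int] = (128, 128)
    pixel_pitch: float = 0.5  # mm/px
    disc_center: tuple[float, float] = (64.0, 64.0)
    disc_radius: float = 45.0  # px
    dc_reflectance: float = 0.60
    background_reflectance: float = 0.02
    vignette_strength: float = 0.35
    modulation_depth0: float = 0.60
    freq_decay: float = 3.0  # mm/cycle, exponential decay of depth with f
    wavelength_gain: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_WAVELENGTH_GAIN)
    )
    bruise: BruiseSpec | None = None
    n_dark_spots: int = 3
    spot_radius: float = 2.5  # px
    spot_depth: float = 0.30  # fractional DC reflectance drop in pits
    spot_ac_extra: float = 0.25  # additional fractional modulation drop
    stem: StreakSpec | None = None
    noise_sigma: float = 0.004  # additive Gaussian, unit intensity scale
    dark_level: float = 0.02  # sensor dark offset, unit intensity scale
    white_reflectance: float = 0.98  # diffuse calibration plate
    ball_mass: float = 0.1  # kg, impact ball
    drop_height: float = 0.4  # m
    g: float = 9.8  # m/s^2
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        cr, cc = self.disc_center
        r = self.disc_radius
        if cr - r < 0 or cc - r < 0 or cr + r > h or cc + r > w:
            raise ValueError("disc must lie inside the image")
        if self.bruise is not None:
            br, bc = self.bruise.center
            a = max(self.bruise.semi_axes)
            if math.hypot(br - cr, bc - cc) + a > r:
                raise ValueError("bruise must lie inside the disc")
        for name in (
            "dc_reflectance",
            "background_reflectance",
            "modulation_depth0",
            "spot_depth",
            "spot_ac_extra",
            "white_reflectance",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.vignette_strength < 1:
            raise ValueError("vignette_strength must lie in [0, 1)")
        if self.freq_decay <= 0:
            raise ValueError("freq_decay must be > 0")

    @property
    def impact_energy_joules(self) -> float:
        return impact_energy(self.ball_mass, self.drop_height, self.g)


@dataclass(frozen=True)
class PhantomSample:
    """A rendered phantom: triplet, references, ground truth, label."""

    triplet: PhaseTriplet
    references: ReferencePair
    truth_disc: np.ndarray
    truth_bruise: np.ndarray
    label: str
    spec: PhantomSpec

    def __post_init__(self):
        has_bruise = bool(np.asarray(self.truth_bruise).any())
        if (self.label == "bruised") != has_bruise:
            raise ValueError("label must be 'bruised' iff truth_bruise is non-empty")


def modulation_depth(spec: PhantomSpec, f: float, wavelength: float) -> float:
    """Modulation depth of sound tissue at frequency f and wavelength.

    ``depth = modulation_depth0 * wavelength_gain(lambda) * exp(-f * freq_decay)``
    -- a phenomenological single-exponential stand-in for the diffusion-
    theory attenuation of structured light in turbid tissue, where higher
    spatial frequencies are damped faster.
    """
    if f < 0:
        raise ValueError("spatial frequency must be >= 0")
    try:
        gain = spec.wavelength_gain[float(wavelength)]
    except KeyError:
        raise ValueError(
            f"unknown wavelength {wavelength}; configured: {sorted(spec.wavelength_gain)}"
        ) from None
    return spec.modulation_depth0 * gain * math.exp(-f * spec.freq_decay)


def bruise_frequency_response(f: float, peak_frequency: float) -> float:
    """Relative AC contrast of a subsurface bruise at frequency f.

    A band-pass shape ``(f/f0)^2 * exp(2*(1 - f/f0))``, equal to 1 at the
    peak frequency ``f0`` and to 0 at f = 0: uniform illumination probes
    past the bruise, very high frequencies never reach it.
    """
    if peak_frequency <= 0:
        raise ValueError("peak_frequency must be > 0")
    x = f / peak_frequency
    return x * x * math.exp(2.0 * (1.0 - x))


def _ellipse_mask(shape, center, semi_axes, angle) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _streak_mask(shape, streak: StreakSpec) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    p0 = np.asarray(streak.p0)
    p1 = np.asarray(streak.p1)
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0:
        dist = np.hypot(rr - p0[0], cc - p0[1])
    else:
        t = np.clip(((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / len2, 0.0, 1.0)
        dist = np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))
    return dist <= streak.width / 2.0


def _quantize8(image: np.ndarray) -> np.ndarray:
    return np.floor(np.clip(image, 0.0, 1.0) * 255.0 + 0.5) / 255.0


def render_phantom(
    spec: PhantomSpec,
    f: float,
    wavelength: float,
    rng: np.random.Generator | None = None,
) -> PhantomSample:
    """Render one phantom at spatial frequency f (cycle/mm) and wavelength (nm).

    All randomness (sensor noise, dark-spot placement) is drawn from
    ``rng`` or, if omitted, from a generator seeded with ``spec.seed`` --
    the same spec and seed always render bit-identical images.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    cr, ccen = spec.disc_center
    radius = np.hypot(rr - cr, cc - ccen)
    disc = radius <= spec.disc_radius

    # curvature shading; clipped so the rim never goes fully dark
    gain = np.clip(1.0 - spec.vignette_strength * (radius / spec.disc_radius) ** 2, 0.1, 1.0)

    rdc = np.where(disc, spec.dc_reflectance, spec.background_reflectance)
    depth = np.full((h, w), modulation_depth(spec, f, wavelength))

    truth_bruise = np.zeros((h, w), dtype=bool)
    if spec.bruise is not None:
        b = spec.bruise
        truth_bruise = _ellipse_mask((h, w), b.center, b.semi_axes, b.angle) & disc
        rdc = np.where(truth_bruise, rdc * (1.0 - b.dc_contrast), rdc)
        c_eff = b.ac_contrast * bruise_frequency_response(f, b.peak_frequency)
        depth = np.where(truth_bruise, depth * (1.0 - c_eff), depth)

    # surface pits: darker reflectance and disproportionately damped modulation
    for _ in range(spec.n_dark_spots):
        ang = rng.uniform(0.0, 2.0 * math.pi)
        rad = spec.disc_radius * math.sqrt(rng.uniform(0.0, 0.85))
        center = (cr + rad * math.sin(ang), ccen + rad * math.cos(ang))
        spot = _ellipse_mask((h, w), center, (spec.spot_radius, spec.spot_radius), 0.0) & disc
        rdc = np.where(spot, rdc * (1.0 - spec.spot_depth), rdc)
        depth = np.where(spot, depth * (1.0 - spec.spot_ac_extra), depth)

    if spec.stem is not None:
        streak = _streak_mask((h, w), spec.stem) & disc
        rdc = np.where(streak, rdc * (1.0 - spec.stem.depth), rdc)
        depth = np.where(streak, depth * (1.0 - spec.stem.ac_extra), depth)

    rac = rdc * depth
    x_mm = cc * spec.pixel_pitch  # sinusoid runs along image columns
    images = []
    for theta in PHASE_OFFSETS:
        pattern = np.cos(2.0 * math.pi * f * x_mm + theta)
        raw = spec.dark_level + gain * (rdc + rac * pattern)
        if spec.noise_sigma > 0:
            raw = raw + rng.normal(0.0, spec.noise_sigma, size=raw.shape)
        images.append(
            RawPatternImage(
                pixels=_quantize8(raw),
                phase_offset=theta,
                spatial_frequency=f,
                wavelength=wavelength,
                pixel_pitch=spec.pixel_pitch,
            )
        )

    white = spec.dark_level + np.full((h, w), spec.white_reflectance)
    black = np.full((h, w), spec.dark_level)
    if spec.noise_sigma > 0:
        white = white + rng.normal(0.0, spec.noise_sigma, size=white.shape)
        black = black + rng.normal(0.0, spec.noise_sigma, size=black.shape)
    references = ReferencePair(white=_quantize8(white), black=_quantize8(black))

    return PhantomSample(
        triplet=PhaseTriplet(tuple(images)),
        references=references,
        truth_disc=disc,
        truth_bruise=truth_bruise,
        label="bruised" if truth_bruise.any() else "normal",
        spec=spec,
    )


def _random_bruise(spec: PhantomSpec, rng: np.random.Generator) -> BruiseSpec:
    """Randomize bruise geometry: impacts land anywhere on the fruit face."""
    a = rng.uniform(15.0, 19.0)
    b = rng.uniform(18.0, 24.0)
    scale = spec.disc_radius / 45.0  # keep proportions if the disc is resized
    a *= scale
    b *= scale
    max_off = max(spec.disc_radius - max(a, b) - 2.0, 0.0)
    ang = rng.uniform(0.0, 2.0 * math.pi)
    rad = max_off * math.sqrt(rng.uniform(0.0, 1.0))
    center = (
        spec.disc_center[0] + rad * math.sin(ang),
        spec.disc_center[1] + rad * math.cos(ang),
    )
    return BruiseSpec(center=center, semi_axes=(a, b), angle=rng.uniform(0.0, math.pi))


def generate_dataset(
    n_normal: int,
    n_bruised: int,
    base_spec: PhantomSpec | None = None,
    f: float = 0.10,
    wavelength: float = 700.0,
    seed: int = 0,
) -> list[PhantomSample]:
    """Render a seeded, reproducible dataset of normal and bruised phantoms.

    Bruise location, size and orientation, pit count and placement, and a
    mild per-fruit variation of reflectance and shading are randomized;
    every per-sample generator derives deterministically from ``seed``.
    Returns ``n_normal`` normal samples followed by ``n_bruised`` bruised
    ones.
    """
    if n_normal < 0 or n_bruised < 0:
        raise ValueError("sample counts must be >= 0")
    if base_spec is None:
        base_spec = PhantomSpec()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_normal + n_bruised)
    samples: list[PhantomSample] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        bruised = i >= n_normal
        spec = dataclasses.replace(
            base_spec,
            dc_reflectance=float(
                np.clip(base_spec.dc_reflectance + rng.uniform(-0.05, 0.05), 0.0, 1.0)
            ),
            vignette_strength=float(
                np.clip(base_spec.vignette_strength + rng.uniform(-0.05, 0.05), 0.0, 0.95)
            ),
            n_dark_spots=int(rng.integers(0, base_spec.n_dark_spots + 1)),
            spot_radius=float(rng.uniform(2.0, 5.5)),
            bruise=_random_bruise(base_spec, rng) if bruised else None,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        samples.append(render_phantom(spec, f, wavelength, rng=rng))
    return samples
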