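"""Small shared helpers: 8-bit quantization and validation."""

from __future__ import annotations

import numpy as np

#: number of gray levels used wherever the pipeline quantizes to a histogram
N_LEVELS = 256


def as_image(a, name: str = "image") -> np.ndarray:
    """Coerce to a 2-D float64 array and validate finiteness."""
    arr = np.asarray(a, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def check_same_shape(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch: {sorted(shapes)}")


def to_levels(image: np.ndarray) -> np.ndarray:
    """Quantize a unit-range image to integer gray levels 0..255.

    Uses round-half-up so that level boundaries match classic 8-bit
    acquisition conventions rather than banker's rounding.
    """
    scaled = np.clip(image, 0.0, 1.0) * (N_LEVELS - 1)
    return np.floor(scaled + 0.5).astype(np.int64)


def from_levels(levels: np.ndarray) -> np.ndarray:
    """Map integer gray levels 0..255 back to the unit range."""
    return np.asarray(levels, dtype=np.float64) / (N_LEVELS - 1)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (towards +inf for positive inputs)."""
    factor = 10.0**decimals
    return float(np.floor(x * factor + 0.5) / factor)
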