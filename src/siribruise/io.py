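"""Reading and writing images, triplet manifests, and dataset exports."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .demodulation import PhaseTriplet, RawPatternImage, ReferencePair
from .phantom import PhantomSample

__all__ = [
    "load_image",
    "save_image",
    "load_triplet",
    "save_triplet_manifest",
    "export_dataset",
]


def load_image(path: str | Path) -> np.ndarray:
    """Read a single-channel 8/16-bit PNG or TIFF into the unit range."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-channel image (shape {arr.shape})")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def save_image(path: str | Path, image: np.ndarray, bit_depth: int = 8) -> None:
    """Write a unit-range image as 8- or 16-bit PNG/TIFF (round-half-up)."""
    path = Path(path)
    if bit_depth == 8:
        scaled = np.floor(np.clip(image, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    elif bit_depth == 16:
        scaled = np.floor(np.clip(image, 0.0, 1.0) * 65535.0 + 0.5).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, scaled)
    else:
        iio.imwrite(path, scaled)


def save_triplet_manifest(
    path: str | Path, triplet: PhaseTriplet, image_paths: list[str]
) -> None:
    """Write a YAML sidecar describing a stored triplet."""
    doc = {
        "spatial_frequency_cyc_per_mm": triplet.spatial_frequency,
        "wavelength_nm": triplet.wavelength,
        "pixel_pitch_mm": triplet.pixel_pitch,
        "images": [
            {"path": p, "phase_offset_rad": im.phase_offset}
            for p, im in zip(image_paths, triplet.images)
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_triplet(manifest_path: str | Path) -> PhaseTriplet:
    """Load a triplet from a YAML manifest (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    doc = yaml.safe_load(manifest_path.read_text())
    images = []
    for entry in doc["images"]:
        img_path = Path(entry["path"])
        if not img_path.is_absolute():
            img_path = manifest_path.parent / img_path
        images.append(
            RawPatternImage(
                pixels=load_image(img_path),
                phase_offset=float(entry["phase_offset_rad"]),
                spatial_frequency=float(doc["spatial_frequency_cyc_per_mm"]),
                wavelength=float(doc["wavelength_nm"]),
                pixel_pitch=float(doc["pixel_pitch_mm"]),
            )
        )
    return PhaseTriplet(tuple(images))


def export_dataset(samples: list[PhantomSample], out_dir: str | Path) -> Path:
    """Write rendered phantoms as PNGs plus a manifest CSV.

    Each sample gets three pattern images, white/black references and its
    ground-truth masks; the returned manifest lists one row per sample.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        sid = f"sample_{i:04d}"
        sdir = out_dir / sid
        sdir.mkdir(exist_ok=True)
        paths = []
        for k, im in enumerate(s.triplet.images, start=1):
            p = sdir / f"pattern_{k}.png"
            save_image(p, im.pixels)
            paths.append(p.name)
        save_image(sdir / "white.png", s.references.white)
        save_image(sdir / "black.png", s.references.black)
        save_image(sdir / "truth_disc.png", s.truth_disc.astype(float))
        save_image(sdir / "truth_bruise.png", s.truth_bruise.astype(float))
        save_triplet_manifest(sdir / "triplet.yaml", s.triplet, paths)
        rows.append(
            {
                "sample_id": sid,
                "label": s.label,
                "manifest": f"{sid}/triplet.yaml",
                "white": f"{sid}/white.png",
                "black": f"{sid}/black.png",
                "frequency_cyc_per_mm": s.triplet.spatial_frequency,
                "wavelength_nm": s.triplet.wavelength,
                "seed": s.spec.seed,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
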