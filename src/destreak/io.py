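"""Serialization: images, sinograms, configs, sidecar metadata.

Images travel as 16-bit TIFF or PNG (values affinely scaled into the
integer range, with the scale recorded in metadata so the round trip is
lossless up to quantization) or as plain numeric text grids (lossless).
Sinograms use 32-bit float TIFF or text grids.  Every artifact written
by the experiment driver gets a JSON sidecar recording the seed, the
config hash and the package version, sufficient to regenerate it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from . import __version__
from .geometry import ScanGeometry, Sinogram
from .image import AttenuationImage

__all__ = [
    "read_image",
    "write_image",
    "read_sinogram",
    "write_sinogram",
    "write_sidecar",
    "config_hash",
]

_TEXT_SUFFIXES = {".txt", ".dat", ".csv"}


def write_image(path: str | Path, image: AttenuationImage) -> None:
    """Write an attenuation image as text grid, 16-bit TIFF or 16-bit PNG."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _TEXT_SUFFIXES:
        header = json.dumps({"pixel_size": image.pixel_size})
        np.savetxt(path, image.values, fmt="%.17e", header=header)
    elif suffix in (".tif", ".tiff"):
        scaled, meta = _quantize(image)
        tifffile.imwrite(path, scaled, description=json.dumps(meta))
    elif suffix == ".png":
        scaled, meta = _quantize(image)
        iio.imwrite(path, scaled)
        path.with_suffix(".png.json").write_text(json.dumps(meta))
    else:
        raise ValueError(f"unsupported image format {suffix!r} (use .txt, .tif/.tiff or .png)")


def _quantize(image: AttenuationImage) -> tuple[np.ndarray, dict]:
    vmin = float(image.values.min())
    vmax = float(image.values.max())
    span = vmax - vmin if vmax > vmin else 1.0
    scaled = np.round((image.values - vmin) / span * 65535.0).astype(np.uint16)
    return scaled, {"pixel_size": image.pixel_size, "vmin": vmin, "vmax": vmax}


def _dequantize(raw: np.ndarray, meta: dict) -> AttenuationImage:
    span = meta["vmax"] - meta["vmin"] if meta["vmax"] > meta["vmin"] else 1.0
    values = raw.astype(np.float64) / 65535.0 * span + meta["vmin"]
    return AttenuationImage(values, meta["pixel_size"])


def read_image(path: str | Path) -> AttenuationImage:
    """Read an attenuation image written by :func:`write_image`."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _TEXT_SUFFIXES:
        with open(path) as fh:
            first = fh.readline()
        meta = json.loads(first.lstrip("# ")) if first.startswith("#") else {}
        values = np.loadtxt(path)
        return AttenuationImage(values, meta.get("pixel_size", 0.0))
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            raw = tf.asarray()
            desc = tf.pages[0].description
        meta = json.loads(desc) if desc else None
        if raw.ndim != 2:
            raise ValueError(f"expected a single-channel 2D image, got shape {raw.shape}")
        if raw.dtype.kind == "f":
            return AttenuationImage(raw, (meta or {}).get("pixel_size", 0.0))
        if meta is None:
            raise ValueError("integer TIFF lacks the scale metadata written by this package")
        return _dequantize(raw, meta)
    if suffix == ".png":
        raw = iio.imread(path)
        if raw.ndim != 2:
            raise ValueError(f"expected a single-channel grayscale PNG, got shape {raw.shape}")
        sidecar = path.with_suffix(".png.json")
        if not sidecar.exists():
            raise ValueError("PNG image lacks its .png.json scale sidecar")
        return _dequantize(raw, json.loads(sidecar.read_text()))
    raise ValueError(f"unsupported image format {suffix!r}")


def write_sinogram(path: str | Path, sinogram: Sinogram) -> None:
    """Write a sinogram as a text grid or 32-bit float TIFF, geometry in metadata."""
    path = Path(path)
    suffix = path.suffix.lower()
    meta = dataclasses.asdict(sinogram.geometry)
    if suffix in _TEXT_SUFFIXES:
        np.savetxt(path, sinogram.values, fmt="%.17e", header=json.dumps(meta))
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, sinogram.values.astype(np.float32), description=json.dumps(meta))
    else:
        raise ValueError(f"unsupported sinogram format {suffix!r}")


def read_sinogram(path: str | Path) -> Sinogram:
    """Read a sinogram written by :func:`write_sinogram`."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _TEXT_SUFFIXES:
        with open(path) as fh:
            first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("text sinogram lacks its geometry header")
        geom = ScanGeometry(**json.loads(first.lstrip("# ")))
        return Sinogram(np.loadtxt(path), geom)
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            raw = tf.asarray().astype(np.float64)
            desc = tf.pages[0].description
        if not desc:
            raise ValueError("sinogram TIFF lacks its geometry metadata")
        return Sinogram(raw, ScanGeometry(**json.loads(desc)))
    raise ValueError(f"unsupported sinogram format {suffix!r}")


def config_hash(config) -> str:
    """Stable short hash of a (nested) dataclass or dict configuration."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_sidecar(artifact_path: str | Path, config, seed: int) -> Path:
    """Write the reproducibility sidecar for an artifact on disk."""
    artifact_path = Path(artifact_path)
    sidecar = artifact_path.with_name(artifact_path.name + ".meta.json")
    payload = {
        "artifact": artifact_path.name,
        "seed": seed,
        "config_hash": config_hash(config),
        "package_version": __version__,
    }
    sidecar.write_text(json.dumps(payload, indent=2))
    return sidecar
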