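"""Image, contour and phantom I/O.

Intensities live in [0, 1] in memory and are converted to/from 8- or 16-bit
integer PNG/TIFF on disk. Contours are CSV files with header
``index,row,col`` (0-based, sub-pixel floats).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .phantom import SpecklePhantom

__all__ = [
    "load_image",
    "save_image",
    "load_contour",
    "save_contour",
    "write_phantom",
    "read_phantom",
]


def load_image(path) -> np.ndarray:
    """Read a grayscale image and scale it to float [0, 1] by its bit depth."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # RGB(A): average the colour channels
        arr = arr[..., :3].mean(axis=-1)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return arr.astype(float)


def save_image(image, path, bit_depth: int = 8) -> None:
    """Write a float image, clipped to [0, 1] and scaled to the bit depth."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    peak = 255 if bit_depth == 8 else 65535
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (arr * peak + 0.5).astype(dtype))


def save_mask(mask, path) -> None:
    """Write a binary mask as a 0/255 8-bit PNG."""
    iio.imwrite(path, ((np.asarray(mask) > 0) * 255).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    return (np.asarray(iio.imread(path)) > 0).astype(np.uint8)


def save_contour(contour, path) -> None:
    pts = np.asarray(contour, dtype=float)
    df = pd.DataFrame({"index": np.arange(len(pts)),
                       "row": pts[:, 0], "col": pts[:, 1]})
    df.to_csv(path, index=False)


def load_contour(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["row", "col"]].to_numpy(dtype=float)


def write_phantom(phantom: SpecklePhantom, out_dir) -> None:
    """Write noisy/clean PNGs, the 0/255 mask and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_image(phantom.noisy, out / "noisy.png")
    save_image(phantom.clean, out / "clean.png")
    save_mask(phantom.truth_mask, out / "mask.png")
    meta = {"shape": list(phantom.shape), "sigma": phantom.sigma,
            "seed": phantom.seed, "object_spec": phantom.object_spec}
    (out / "phantom.json").write_text(json.dumps(meta, indent=2))


def read_phantom(in_dir) -> SpecklePhantom:
    src = Path(in_dir)
    meta = json.loads((src / "phantom.json").read_text())
    return SpecklePhantom(clean=load_image(src / "clean.png"),
                          truth_mask=load_mask(src / "mask.png"),
                          noisy=load_image(src / "noisy.png"),
                          sigma=meta["sigma"], seed=meta["seed"],
                          object_spec=meta.get("object_spec", {}))
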