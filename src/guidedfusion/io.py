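"""Image and report I/O.

Grayscale PNG/TIFF in 8 or 16 bit; RGB inputs are converted to luminance
(ITU-R BT.709 weights).  Intensities are always rescaled to [0, 1] by the
container's bit depth on read and quantized back on write.
"""

from __future__ import annotations

import json
import os
from typing import Iterable

import imageio.v3 as iio
import numpy as np

__all__ = [
    "load_gray_image",
    "save_gray_image",
    "write_phantom_pair",
    "write_report",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])  # BT.709


def load_gray_image(path) -> np.ndarray:
    """Read an image file as a float image in [0, 1]."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    raw = iio.imread(path)
    if raw.size == 0:
        raise ValueError(f"zero-size image: {path}")
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            arr = arr[:, :, 0]
        else:
            arr = arr[:, :, :3].astype(float) @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"unsupported image layout {raw.shape} in {path}")
    if raw.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if raw.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(raw.dtype, np.floating):
        return np.clip(arr.astype(float), 0.0, 1.0)
    raise ValueError(f"unsupported image dtype {raw.dtype} in {path}")


def save_gray_image(path, img, bit_depth: int = 16) -> None:
    """Quantize a [0, 1] image to 8 or 16 bit and write PNG/TIFF."""
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    if bit_depth == 16:
        iio.imwrite(path, np.round(arr * 65535.0).astype(np.uint16))
    elif bit_depth == 8:
        iio.imwrite(path, np.round(arr * 255.0).astype(np.uint8))
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")


def write_phantom_pair(outdir, pair) -> dict[str, str]:
    """Write a phantom pair as 16-bit PNGs plus a JSON metadata sidecar."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, img in (
        ("ct", pair.ct),
        ("mr_clean", pair.mr_clean),
        ("mr_noisy", pair.mr_noisy),
        ("ideal_composite", pair.ideal_composite),
    ):
        paths[name] = os.path.join(outdir, f"{name}.png")
        save_gray_image(paths[name], img)
    meta_path = os.path.join(outdir, "phantom.json")
    with open(meta_path, "w") as fh:
        json.dump(
            {"seed": pair.seed, "sigma": pair.sigma, "size": list(pair.ct.shape)},
            fh,
            indent=2,
        )
    paths["metadata"] = meta_path
    return paths


def write_report(path, rows: Iterable[tuple[str, str, float]]) -> None:
    """Write a metric report as TSV with columns metric, scheme, value."""
    with open(path, "w") as fh:
        fh.write("metric\tscheme\tvalue\n")
        for metric, scheme, value in rows:
            fh.write(f"{metric}\t{scheme}\t{value:.6f}\n")
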