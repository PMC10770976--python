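"""Shared readers/writers: 8-bit images, 16-bit instance masks, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale or RGB image as a numpy array."""
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    return img


def write_image(path: str | Path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError(f"images are written as 8-bit; got dtype {image.dtype}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, image)


def read_mask(path: str | Path) -> np.ndarray:
    """Read an instance mask (16-bit single channel, 0 = background)."""
    mask = iio.imread(path)
    if mask.ndim != 2:
        raise ValueError("instance masks must be single-channel")
    return mask.astype(np.int32)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("instance masks must be integer-labeled")
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("mask labels must fit in uint16")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, mask.astype(np.uint16))


def write_report(path: str | Path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
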