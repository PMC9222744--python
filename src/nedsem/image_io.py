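"""Image and mask I/O.

Images are 8-bit RGB numpy arrays of shape ``(H, W, 3)``; channels are the
universal ``(H, W)`` float/uint8 planes the rest of the pipeline consumes.
Label masks are written as single-channel PNGs with one distinct gray level
per label so they survive a lossless round trip.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG image as an 8-bit RGB array of shape (H, W, 3).

    Grayscale inputs are replicated to three channels; an alpha channel is
    dropped with a warning.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode in ("RGBA", "LA", "PA"):
                logger.warning("dropping alpha channel of %s (mode %s)", path, im.mode)
            rgb = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (OSError, UnidentifiedImageError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise IOError(f"cannot read image {path}: unexpected shape {rgb.shape}")
    return rgb


def write_image(img: np.ndarray, path) -> None:
    """Write an (H, W, 3) uint8 array as PNG/JPEG."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got {img.shape}")
    try:
        Image.fromarray(img.astype(np.uint8), mode="RGB").save(Path(path))
    except OSError as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc


def split_channels(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an RGB image into its R, G, B channel matrices.

    Stacking the three planes along the last axis reconstructs the image
    bit-exactly.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {img.shape}")
    return img[:, :, 0].copy(), img[:, :, 1].copy(), img[:, :, 2].copy()


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("mask labels must be integers")
    present = np.unique(labels)
    k = int(present[-1]) + 1
    if present[0] != 0 or len(present) != k:
        raise ValueError(
            f"labels must be a contiguous range starting at 0, got {present.tolist()}"
        )
    return labels


def write_mask(labels: np.ndarray, path) -> None:
    """Write a label mask as a grayscale PNG, one distinct gray level per label.

    Labels must form a contiguous range 0..K-1.  Gray levels are spread over
    [0, 255] so the mask is human-viewable; :func:`read_mask` inverts the
    encoding exactly.
    """
    labels = _check_labels(labels)
    k = int(labels.max()) + 1
    levels = np.linspace(0, 255, k).round().astype(np.uint8) if k > 1 else np.array([0], np.uint8)
    try:
        Image.fromarray(levels[labels], mode="L").save(Path(path))
    except OSError as exc:
        raise IOError(f"cannot write mask {path}: {exc}") from exc


def read_mask(path) -> np.ndarray:
    """Read a grayscale label mask written by :func:`write_mask`.

    Distinct gray values are mapped, in increasing order, to labels 0..K-1.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            gray = np.asarray(im.convert("L"))
    except (OSError, UnidentifiedImageError) as exc:
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    values = np.unique(gray)
    lookup = {v: i for i, v in enumerate(values.tolist())}
    out = np.zeros(gray.shape, dtype=np.int64)
    for v, i in lookup.items():
        out[gray == v] = i
    return out
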