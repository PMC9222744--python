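"""Flat grayscale morphology: erosion, dilation, closing, morphological gradient.

All operators use a flat (binary-footprint) structuring element and reflect
padding at the image border, so a constant image is a fixed point of every
operator and no artificial edges are created at the frame.

Conventions
-----------
``erode(P, S)[i, j] = min { P[i + u - a0, j + v - a1] : S.footprint[u, v] }``
with ``(a0, a1)`` the anchor.  Dilation is the Minkowski dual: the maximum
over the *reflected* footprint, so that ``dilate(P, S) == -erode(-P,
reflect(S))`` holds exactly.  For the symmetric default footprints the two
conventions coincide with plain min/max filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk as _disk


@dataclass(frozen=True)
class StructuringElement:
    """Flat structuring element: binary footprint plus an anchor (origin).

    The default anchor is the central cell ``(h // 2, w // 2)``.
    """

    footprint: np.ndarray
    anchor: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        fp = np.asarray(self.footprint, dtype=bool)
        if fp.ndim != 2 or not fp.any():
            raise ValueError("footprint must be 2-D with at least one true cell")
        object.__setattr__(self, "footprint", fp)
        anchor = self.anchor
        if anchor is None:
            anchor = (fp.shape[0] // 2, fp.shape[1] // 2)
        a0, a1 = anchor
        if not (0 <= a0 < fp.shape[0] and 0 <= a1 < fp.shape[1]):
            raise ValueError(f"anchor {anchor} outside footprint {fp.shape}")
        object.__setattr__(self, "anchor", (int(a0), int(a1)))

    @property
    def contains_anchor(self) -> bool:
        return bool(self.footprint[self.anchor])

    def reflected(self) -> "StructuringElement":
        """Footprint rotated 180° about the anchor."""
        h, w = self.footprint.shape
        a0, a1 = self.anchor
        return StructuringElement(self.footprint[::-1, ::-1], (h - 1 - a0, w - 1 - a1))


def disk(radius: int) -> StructuringElement:
    """Disk footprint of the given pixel radius (side 2r+1)."""
    return StructuringElement(_disk(radius))


def square(radius: int) -> StructuringElement:
    side = 2 * radius + 1
    return StructuringElement(np.ones((side, side), dtype=bool))


def cross(radius: int) -> StructuringElement:
    side = 2 * radius + 1
    fp = np.zeros((side, side), dtype=bool)
    fp[radius, :] = True
    fp[:, radius] = True
    return StructuringElement(fp)


_SHAPES = {"disk": disk, "square": square, "cross": cross}


def from_config(shape: str = "disk", radius: int = 2) -> StructuringElement:
    """Build a structuring element from config keys ``se.shape`` / ``se.radius``."""
    try:
        factory = _SHAPES[shape]
    except KeyError:
        raise ValueError(f"unknown structuring-element shape {shape!r}") from None
    if radius < 0:
        raise ValueError("radius must be >= 0")
    return factory(radius)


def _filter(P: np.ndarray, se: StructuringElement, minimum: bool) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if not np.isfinite(P).all():
        raise ValueError("input matrix must be finite")
    c = (se.footprint.shape[0] // 2, se.footprint.shape[1] // 2)
    origin = (se.anchor[0] - c[0], se.anchor[1] - c[1])
    op = ndimage.minimum_filter if minimum else ndimage.maximum_filter
    return op(P, footprint=se.footprint, mode="reflect", origin=origin)


def erode(P: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Grayscale erosion: local minimum over the footprint."""
    return _filter(P, se, minimum=True)


def dilate(P: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Grayscale dilation: local maximum over the reflected footprint."""
    return _filter(P, se.reflected(), minimum=False)


def close(P: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Closing = dilation followed by erosion; fills dark holes smaller than S."""
    return erode(dilate(P, se), se)


def gradient(P: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Morphological gradient dilate − erode; non-negative, highlights edges."""
    return dilate(P, se) - erode(P, se)
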