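"""Neutrosophic-set conversion of color channels.

Each channel plane P' is mapped to a triple of membership maps:

* truth ``T``: the morphologically *closed* channel, min-max normalized over
  the whole plane — closing removes dark holes and thin artifacts (hairs)
  before the brightness is read off;
* falsity ``F = 1 − T``;
* indeterminacy ``I``: the absolute morphological gradient, min-max
  normalized — high values mark edge contours, where a pixel's membership is
  genuinely uncertain.

T, I, F are independent maps in [0, 1]; only T and F are tied by T + F = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import StructuringElement, close, gradient

_EPS = 1e-12


@dataclass(frozen=True)
class NSTriple:
    """Aligned (T, I, F) membership maps of one color channel."""

    T: np.ndarray
    I: np.ndarray
    F: np.ndarray
    channel: str = ""

    def __post_init__(self):
        if not (self.T.shape == self.I.shape == self.F.shape):
            raise ValueError("T, I, F must share one shape")
        for name, m in (("T", self.T), ("I", self.I), ("F", self.F)):
            if m.min() < -_EPS or m.max() > 1 + _EPS:
                raise ValueError(f"{name} outside [0, 1]")
        if not np.allclose(self.T + self.F, 1.0, atol=1e-9):
            raise ValueError("T + F must equal 1 element-wise")

    @property
    def shape(self) -> tuple[int, int]:
        return self.T.shape


def _rescale(M: np.ndarray, degenerate: float) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant matrix maps to `degenerate`."""
    lo, hi = float(M.min()), float(M.max())
    if hi - lo < _EPS:
        return np.full(M.shape, degenerate)
    return (M - lo) / (hi - lo)


def to_T(P: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Truth membership: min-max normalized closing of the channel.

    A constant channel (no dynamic range) maps to T = 0.5 everywhere: total
    indeterminacy between membership and non-membership.
    """
    return _rescale(close(np.asarray(P, dtype=float), se), degenerate=0.5)


def to_F(T: np.ndarray) -> np.ndarray:
    """Falsity membership F = 1 − T (involution)."""
    T = np.asarray(T, dtype=float)
    if T.min() < -_EPS or T.max() > 1 + _EPS:
        raise ValueError("T must lie in [0, 1]")
    return 1.0 - T


def to_I(P: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Indeterminacy: normalized absolute morphological gradient.

    A channel with no gradient anywhere (constant within every neighborhood)
    maps to I = 0: nothing is uncertain because there are no edges.
    """
    delta = np.abs(gradient(np.asarray(P, dtype=float), se))
    return _rescale(delta, degenerate=0.0)


def ns_channel(P: np.ndarray, se: StructuringElement, channel: str = "") -> NSTriple:
    """Full NS conversion of one channel plane."""
    T = to_T(P, se)
    return NSTriple(T=T, I=to_I(P, se), F=to_F(T), channel=channel)


def to_ns(img: np.ndarray, se: StructuringElement) -> tuple[NSTriple, NSTriple, NSTriple]:
    """Convert an (H, W, 3) RGB image into per-channel NS triples."""
    from .image_io import split_channels

    r, g, b = split_channels(img)
    return (
        ns_channel(r, se, "R"),
        ns_channel(g, se, "G"),
        ns_channel(b, se, "B"),
    )
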