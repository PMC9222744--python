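"""Single-valued neutrosophic entropy via the isentropic-cylinder model.

A neutrosophic point (t, i, f) lives in the unit cube.  Its uncertainty has
two ingredients: *fuzziness* |t − f| (how far membership and non-membership
are from balancing) and *intuitiveness* |i − 1/2| (how far the indeterminacy
is from its maximally uninformative value).  Both vanish on the axis
{t = f, i = 1/2}; points at equal Euclidean distance

    d = sqrt( (t − f)² / 2 + ((1 − 2i) / 2)² )

from that axis lie on one *isentropic cylinder* and share the entropy

    E = 1 − (2 / √3) · d,

normalized so that E = 1 on the axis and E = 0 at the crisp cube corners
(d = √3/2, e.g. (1, 0, 0)).  E is strictly decreasing in d, symmetric under
t ↔ f and under i ↔ 1 − i.

Applied per pixel to an NS triple this yields an entropy map that is high
exactly where the image is ambiguous — the gradually colored banded edge of
a melanoma lesion — and low in confidently dark or bright regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ns_domain import NSTriple

_COEF = 2.0 / math.sqrt(3.0)
_EPS = 1e-12


def _validate(*comps):
    out = []
    for c in comps:
        c = np.asarray(c, dtype=float)
        if c.size and (c.min() < -_EPS or c.max() > 1 + _EPS):
            raise ValueError("neutrosophic components must lie in [0, 1]")
        out.append(c)
    return out


def axis_distance(t, i, f):
    """Euclidean distance of (t, i, f) from the axis {t = f, i = 1/2}.

    Accepts scalars or aligned arrays; ranges over [0, √3/2] on the cube.
    """
    t, i, f = _validate(t, i, f)
    return np.sqrt((t - f) ** 2 / 2.0 + ((1.0 - 2.0 * i) / 2.0) ** 2)


def pixel_entropy(t, i, f):
    """Single-valued neutrosophic entropy E = 1 − (2/√3)·axis_distance."""
    return 1.0 - _COEF * axis_distance(t, i, f)


@dataclass(frozen=True)
class EntropyMatrix:
    """Per-pixel neutrosophic entropy map of one channel, values in [0, 1]."""

    values: np.ndarray
    channel: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.min() < -_EPS or v.max() > 1 + _EPS:
            raise ValueError("entropy values outside [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self):
        return self.values.shape

    @property
    def scalar(self) -> float:
        """Aggregate entropy: the plain mean of the per-pixel map."""
        return float(self.values.mean())


def entropy_map(ns: NSTriple) -> EntropyMatrix:
    """Element-wise entropy of an NS triple, preserving spatial structure."""
    return EntropyMatrix(pixel_entropy(ns.T, ns.I, ns.F), channel=ns.channel)
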