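"""Edge-feature construction: the R−B entropy difference and its dilation.

The red-channel entropy map picks out the inner rim of the lesion edge band,
the blue-channel map the outer rim and the bluish lesion interior.  Their
difference

    R_b = E_R − E_B

is positive on the reddish-brown edge band, negative where the blue
component dominates (blue-gray veil inside the lesion), and near zero on
background skin — a single scalar feature separating the three regions.
Dilating R_b (the "DI" stage) closes pinholes and thin dark artifacts before
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import StructuringElement, dilate
from .ne_domain import EntropyMatrix

RB = "Rb"
DI = "DI"


@dataclass(frozen=True)
class FeatureMatrix:
    """Scalar per-pixel feature plane with a processing-stage tag."""

    values: np.ndarray
    stage: str

    def __post_init__(self):
        if self.stage not in (RB, DI):
            raise ValueError(f"unknown feature stage {self.stage!r}")

    @property
    def shape(self):
        return self.values.shape


def augment(e_r: EntropyMatrix, e_b: EntropyMatrix) -> FeatureMatrix:
    """Build R_b = E_R − E_B from the red and blue entropy maps."""
    if e_r.channel != "R" or e_b.channel != "B":
        raise ValueError(
            f"augment expects channels R and B, got {e_r.channel!r}, {e_b.channel!r}"
        )
    if e_r.shape != e_b.shape:
        raise ValueError(f"shape mismatch {e_r.shape} vs {e_b.shape}")
    return FeatureMatrix(e_r.values - e_b.values, stage=RB)


def dilate_features(rb: FeatureMatrix, se: StructuringElement) -> FeatureMatrix:
    """Grayscale-dilate the R_b feature (stage Rb → DI); extensive."""
    if rb.stage != RB:
        raise ValueError(f"dilate_features expects stage {RB!r}, got {rb.stage!r}")
    return FeatureMatrix(dilate(np.asarray(rb.values, dtype=float), se), stage=DI)
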