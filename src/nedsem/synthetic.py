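"""Seeded generator of dermoscopy-like lesion phantoms with ground truth.

A phantom has three concentric regions around a wobbled (irregular) outline:

* **core** — the pigmented lesion interior.  Its default color has an
  elevated blue component relative to red, emulating the blue-gray veil of
  melanoma under dermoscopy.
* **banded edge** — the annulus between the inner and outer edge, colored a
  red-brown pigment rim distinct from both core and skin.  The radial color
  profile runs core → band → skin through two smoothstep ramps, so the
  transition is gradual and nonlinear, and — crucially — the red channel
  completes most of its change near the inner edge while the blue channel
  changes near the outer edge, as in real lesions.
* **background** — lighter healthy skin.

Additive Gaussian noise, dark hair strokes and bright bubble rings emulate
acquisition artifacts.  The ground-truth mask (0 background, 1 banded edge,
2 core) is derived from the same wobbled radii, so every pipeline stage can
be scored exactly.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class LesionSpec:
    height: int = 128
    width: int = 128
    center: tuple[float, float] | None = None     #: (row, col), default image center
    inner_radius: float = 25.0
    outer_radius: float = 40.0
    wobble_amplitude: float = 2.0                 #: px, boundary irregularity
    wobble_harmonics: int = 4
    core_rgb: tuple[float, float, float] = (70.0, 60.0, 95.0)
    band_rgb: tuple[float, float, float] = (150.0, 75.0, 60.0)
    skin_rgb: tuple[float, float, float] = (195.0, 150.0, 130.0)
    noise_sigma: float = 4.0
    hair_count: int = 0
    bubble_count: int = 0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.inner_radius < self.outer_radius < min(self.height, self.width) / 2):
            raise ValueError("need 0 < inner_radius < outer_radius < min(H, W)/2")
        for c in (self.core_rgb, self.band_rgb, self.skin_rgb):
            if min(c) < 0 or max(c) > 255:
                raise ValueError("colors must lie in [0, 255]")
        if self.wobble_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("amplitude and noise must be >= 0")
        if self.hair_count < 0 or self.bubble_count < 0:
            raise ValueError("artifact counts must be >= 0")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def generate(spec: LesionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the phantom; returns (uint8 RGB image, int truth mask).

    With zero wobble the truth annulus is exactly the set of pixels with
    ``inner_radius <= distance < outer_radius`` from the center.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    cy, cx = spec.center if spec.center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    wobble = np.zeros_like(dist)
    if spec.wobble_amplitude > 0 and spec.wobble_harmonics > 0:
        amps = rng.normal(size=spec.wobble_harmonics)
        phases = rng.uniform(0, 2 * np.pi, size=spec.wobble_harmonics)
        for k in range(spec.wobble_harmonics):
            wobble += amps[k] * np.cos((k + 1) * theta + phases[k])
        wobble *= spec.wobble_amplitude / max(np.abs(wobble).max(), 1e-12)

    r_in = spec.inner_radius + wobble
    r_out = spec.outer_radius + wobble
    truth = np.zeros((h, w), dtype=np.int64)
    truth[dist < r_out] = 1
    truth[dist < r_in] = 2

    # radial progress through the annulus: 0 at the inner edge, 1 at the outer
    s = np.clip((dist - r_in) / (r_out - r_in), 0.0, 1.0)
    core = np.asarray(spec.core_rgb)
    band = np.asarray(spec.band_rgb)
    skin = np.asarray(spec.skin_rgb)
    inner = _smoothstep(s / 0.5)[..., None]        # core -> band over s in [0, 0.5]
    outer = _smoothstep((s - 0.5) / 0.5)[..., None]  # band -> skin over s in [0.5, 1]
    img = core + (band - core) * inner + (skin - band) * outer

    if spec.noise_sigma > 0:
        img = img + rng.normal(scale=spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    if spec.hair_count:
        img = add_hairs(img, spec.hair_count, seed=int(rng.integers(2**31)))
    if spec.bubble_count:
        img = add_bubbles(img, spec.bubble_count, seed=int(rng.integers(2**31)))
    return img, truth


def _stamp(mask: np.ndarray, r: np.ndarray, c: np.ndarray, width: int) -> None:
    h, w = mask.shape
    pad = width // 2
    for dr in range(-pad, pad + 1):
        for dc in range(-pad, pad + 1):
            rr = np.clip(r + dr, 0, h - 1)
            cc = np.clip(c + dc, 0, w - 1)
            mask[rr, cc] = True


def add_hairs(img: np.ndarray, count: int, seed: int = 0,
              return_mask: bool = False):
    """Overlay `count` dark quadratic-Bézier hair strokes (1–3 px wide).

    ``count=0`` returns the image unchanged.  With ``return_mask=True`` the
    union of stroke footprints is returned alongside for bookkeeping.
    """
    img = np.asarray(img).copy()
    h, w = img.shape[:2]
    rng = np.random.default_rng(seed)
    stroke_mask = np.zeros((h, w), dtype=bool)
    for _ in range(count):
        p0, p1, p2 = rng.uniform([0, 0], [h - 1, w - 1], size=(3, 2))
        t = np.linspace(0, 1, 4 * max(h, w))[:, None]
        curve = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
        r = np.clip(curve[:, 0].round().astype(int), 0, h - 1)
        c = np.clip(curve[:, 1].round().astype(int), 0, w - 1)
        one = np.zeros((h, w), dtype=bool)
        _stamp(one, r, c, width=int(rng.integers(1, 4)))
        shade = rng.uniform(15, 45)
        img[one] = np.clip(img[one].astype(float) * 0.25 + shade, 0, 255).astype(np.uint8)
        stroke_mask |= one
    return (img, stroke_mask) if return_mask else img


def add_bubbles(img: np.ndarray, count: int, seed: int = 0) -> np.ndarray:
    """Overlay `count` bright immersion-fluid bubble rings."""
    img = np.asarray(img).copy()
    h, w = img.shape[:2]
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(count):
        cy, cx = rng.uniform([0, 0], [h - 1, w - 1])
        rad = rng.uniform(2, 6)
        d = np.hypot(yy - cy, xx - cx)
        ring = np.abs(d - rad) < 1.0
        img[ring] = np.clip(img[ring].astype(float) + 70, 0, 255).astype(np.uint8)
    return img
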