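"""End-to-end segmentation pipeline.

Six stages: channel split → neutrosophic conversion → entropy maps → R−B
feature → dilation → mixture clustering, plus the cluster→region mapping and
the ordering/comparator ablations.

Cluster indices carry no meaning, so the final mask is relabeled
semantically: the cluster with the highest mean feature value becomes the
*banded edge* (the feature is built to peak there), and among the remaining
clusters the one with the lowest mean red intensity becomes the *core*
(melanin absorbs red); everything else is background.  Output labels are
0 = background, 1 = banded edge, 2 = lesion core.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import image_io, morphology, ns_domain
from .features import augment, dilate_features, FeatureMatrix, RB, DI
from .hgmm import HGMMConfig, fit as hgmm_fit
from .metrics import binary_dice, confusion, scores
from .ne_domain import entropy_map

logger = logging.getLogger(__name__)

ORDERS = ("rb_then_dilate", "dilate_then_rb", "none")
COMPARATORS = ("hgmm", "kmeans", "fcm")

BACKGROUND, BANDED_EDGE, CORE = 0, 1, 2
LABEL_NAMES = {BACKGROUND: "background", BANDED_EDGE: "banded edge", CORE: "lesion core"}


@dataclass(frozen=True)
class PipelineConfig:
    se_shape: str = "disk"
    se_radius: int = 2
    se_feature_shape: str | None = None     #: defaults to the NS-conversion SE
    se_feature_radius: int | None = None
    morphology_order: str = "rb_then_dilate"
    hgmm: HGMMConfig = field(default_factory=HGMMConfig)
    comparator: str = "hgmm"
    emit_intermediates: bool = False

    def __post_init__(self):
        if self.morphology_order not in ORDERS:
            raise ValueError(f"morphology_order must be one of {ORDERS}")
        if self.comparator not in COMPARATORS:
            raise ValueError(f"comparator must be one of {COMPARATORS}")

    @property
    def se(self) -> morphology.StructuringElement:
        return morphology.from_config(self.se_shape, self.se_radius)

    @property
    def se_feature(self) -> morphology.StructuringElement:
        return morphology.from_config(
            self.se_feature_shape or self.se_shape,
            self.se_feature_radius if self.se_feature_radius is not None else self.se_radius,
        )


def _cluster(feature: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    k, seed = cfg.hgmm.k, cfg.hgmm.seed
    if cfg.comparator == "hgmm":
        _, labels = hgmm_fit(feature, cfg.hgmm)
        return labels
    flat = feature.reshape(-1, 1)
    if cfg.comparator == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(flat).reshape(feature.shape)
    return _fcm(feature, k, seed)


def _fcm(feature: np.ndarray, k: int, seed: int, m: float = 2.0,
         tol: float = 1e-5, max_iter: int = 300) -> np.ndarray:
    """Standard fuzzy c-means (fuzzifier m) on the scalar feature plane."""
    x = feature.ravel()[:, None]
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(k), size=x.shape[0])
    for _ in range(max_iter):
        um = u**m
        centers = (um.T @ x) / np.maximum(um.sum(axis=0)[:, None], 1e-300)
        d2 = np.maximum((x - centers.T) ** 2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        if np.abs(u_new - u).max() < tol:
            u = u_new
            break
        u = u_new
    return np.argmax(u, axis=1).reshape(feature.shape)


def _semantic_relabel(raw: np.ndarray, feature: np.ndarray,
                      red: np.ndarray) -> np.ndarray:
    """Map arbitrary cluster indices to {background, banded edge, core}."""
    clusters = np.unique(raw)
    if clusters.size == 1:
        return np.zeros_like(raw)
    feat_means = [feature[raw == c].mean() for c in clusters]
    edge = clusters[int(np.argmax(feat_means))]
    out = np.full(raw.shape, BACKGROUND, dtype=np.int64)
    out[raw == edge] = BANDED_EDGE
    if clusters.size >= 3:
        rest = [c for c in clusters if c != edge]
        red_means = [red[raw == c].mean() for c in rest]
        core = rest[int(np.argmin(red_means))]
        out[raw == core] = CORE
    return out


def build_feature(img: np.ndarray, cfg: PipelineConfig,
                  intermediates: dict | None = None) -> FeatureMatrix:
    """Stages 1–5: channels → NS triples → entropy maps → feature plane."""
    se = cfg.se
    ns_r, ns_g, ns_b = ns_domain.to_ns(img, se)
    e_r, e_g, e_b = (entropy_map(ns) for ns in (ns_r, ns_g, ns_b))

    if cfg.morphology_order == "rb_then_dilate":
        feat = dilate_features(augment(e_r, e_b), cfg.se_feature)
    elif cfg.morphology_order == "dilate_then_rb":
        d = lambda e: morphology.dilate(e.values, cfg.se_feature)
        feat = FeatureMatrix(d(e_r) - d(e_b), stage=DI)
    else:  # no feature-stage morphology
        feat = augment(e_r, e_b)

    if intermediates is not None:
        intermediates.update({
            "ns_R": ns_r, "ns_G": ns_g, "ns_B": ns_b,
            "E_R": e_r, "E_G": e_g, "E_B": e_b,
            "Rb": augment(e_r, e_b).values, "feature": feat.values,
        })
    return feat


def segment(img: np.ndarray, cfg: PipelineConfig | None = None):
    """Segment an RGB dermoscopy image into background / banded edge / core.

    Returns ``(mask, intermediates)``; intermediates is None unless
    ``cfg.emit_intermediates`` is set.  Deterministic given (image, config).
    """
    cfg = cfg or PipelineConfig()
    img = np.asarray(img)
    inter: dict | None = {} if cfg.emit_intermediates else None
    t0 = time.perf_counter()
    feat = build_feature(img, cfg, inter)
    logger.info("feature stage done in %.2fs", time.perf_counter() - t0)
    raw = _cluster(feat.values, cfg)
    mask = _semantic_relabel(raw, feat.values, img[:, :, 0].astype(float))
    logger.info("clustering (%s) done in %.2fs", cfg.comparator,
                time.perf_counter() - t0)
    if inter is not None:
        inter["raw_labels"] = raw
    return mask, inter


def evaluate(mask: np.ndarray, truth: np.ndarray) -> dict:
    """Lesion-vs-background scores plus the banded-edge overlap."""
    sc = scores(confusion(mask, truth)).as_dict()
    sc["band_Dice"] = binary_dice(mask, truth, {BANDED_EDGE})
    sc["lesion_Dice"] = sc["Dice"]
    return sc


def run_ablation(img: np.ndarray, truth: np.ndarray,
                 cfg: PipelineConfig | None = None) -> list[dict]:
    """Score the three morphology orderings and the comparator clusterers."""
    cfg = cfg or PipelineConfig()
    rows = []
    for order in ORDERS:
        mask, _ = segment(img, replace(cfg, morphology_order=order, comparator="hgmm"))
        rows.append({"variant": f"hgmm/{order}", **evaluate(mask, truth)})
    for comp in ("kmeans", "fcm"):
        mask, _ = segment(img, replace(cfg, comparator=comp))
        rows.append({"variant": f"{comp}/{cfg.morphology_order}", **evaluate(mask, truth)})
    return rows
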