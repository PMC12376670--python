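"""Thresholding, positive-pixel masks, pixel-ratio statistics and tension maps.

The fibronectin tension read-out is ratiometric: the FnBPA5 probe binds
untensed fibers only, while a polyclonal antibody stains all fibronectin, so
the fraction of FnBPA5-positive pixels among fibronectin-positive pixels
summarizes how much of the fiber network has lost tension. Positivity is
strict (``intensity > threshold``), with Otsu's method as the default
per-channel, per-field threshold policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_core import BinaryMask

__all__ = [
    "ThresholdPolicy",
    "PixelClassifier",
    "RatiometricMap",
    "otsu_threshold",
    "train_pixel_classifier",
    "make_mask",
    "pixel_ratio",
    "pixel_density",
    "ratiometric_map",
]

logger = logging.getLogger("fibertension")

OTSU_BINS = 256  # fixed histogram resolution regardless of bit depth


@dataclass
class ThresholdPolicy:
    """How a channel's positive pixels are defined.

    mode ``otsu`` recomputes Otsu's threshold over in-region pixels; ``fixed``
    uses ``fixed_value``; ``classifier`` scores each pixel with a trained
    :class:`PixelClassifier` and calls score > 0.5 positive.
    """

    mode: str = "otsu"
    fixed_value: float | None = None
    classifier: "PixelClassifier | None" = None

    def __post_init__(self) -> None:
        if self.mode not in ("otsu", "fixed", "classifier"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "fixed" and self.fixed_value is None:
            raise ValueError("fixed mode requires fixed_value")
        if self.mode == "classifier" and self.classifier is None:
            raise ValueError("classifier mode requires a trained classifier")


@dataclass
class PixelClassifier:
    """Linear per-pixel classifier over multi-scale smoothed-intensity features.

    Features per pixel are the Gaussian-smoothed intensity and the Gaussian
    gradient magnitude at each scale in ``feature_scales`` (scale 0 means the
    raw intensity with a centered-difference gradient), plus a constant.
    Weights are fitted by least squares against 0/1 labels; the decision
    threshold is fixed at 0.5.
    """

    feature_scales: list[float]
    weights: np.ndarray
    training_seed: int = 0

    def features(self, channel: np.ndarray) -> np.ndarray:
        """Per-pixel feature stack, shape (n_features, H, W)."""
        channel = np.asarray(channel, dtype=np.float64)
        feats = []
        for s in self.feature_scales:
            smoothed = ndimage.gaussian_filter(channel, s) if s > 0 else channel
            gr, gc = np.gradient(smoothed)
            feats.append(smoothed)
            feats.append(np.hypot(gr, gc))
        feats.append(np.ones_like(channel))
        return np.stack(feats)

    def score(self, channel: np.ndarray) -> np.ndarray:
        f = self.features(channel)
        return np.tensordot(self.weights, f, axes=1)


def train_pixel_classifier(
    patches: list[tuple[np.ndarray, np.ndarray]],
    scales: list[float] | None = None,
    seed: int = 0,
) -> PixelClassifier:
    """Fit the linear pixel classifier on (patch, boolean label mask) pairs.

    Closed-form least squares; deterministic given the patches and seed.
    Raises if the pooled labels contain a single class.
    """
    scales = [0.0, 1.0, 2.0] if scales is None else list(scales)
    clf = PixelClassifier(feature_scales=scales, weights=np.zeros(1), training_seed=seed)
    X_parts, y_parts = [], []
    for patch, labels in patches:
        f = clf.features(np.asarray(patch, dtype=np.float64))
        X_parts.append(f.reshape(f.shape[0], -1).T)
        y_parts.append(np.asarray(labels, dtype=np.float64).ravel())
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    if y.min() == y.max():
        raise ValueError("training labels contain a single class")
    weights, *_ = np.linalg.lstsq(X, y, rcond=None)
    clf.weights = weights
    return clf


def otsu_threshold(channel: np.ndarray, region: BinaryMask | None = None) -> float:
    """Otsu's threshold over a 256-bin histogram of in-region intensities.

    Returns the bin-edge intensity maximizing the between-class variance;
    ties break toward the smallest maximizing threshold. A constant region
    raises (degenerate histogram).
    """
    channel = np.asarray(channel, dtype=np.float64)
    values = channel[region.values] if region is not None else channel.ravel()
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("degenerate histogram: region is constant")
    hist, edges = np.histogram(values, bins=OTSU_BINS, range=(lo, hi))
    p = hist.astype(np.float64) / hist.sum()
    omega = np.cumsum(p)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    # threshold after bin k separates bins <=k from bins >k
    k = int(np.argmax(sigma_b[:-1]))
    return float(edges[k + 1])


def make_mask(
    channel: np.ndarray,
    policy: ThresholdPolicy,
    region: BinaryMask,
    source_channel: str = "",
) -> BinaryMask:
    """Positive-pixel mask: in-region pixels passing the threshold policy."""
    channel = np.asarray(channel, dtype=np.float64)
    if channel.shape != region.shape:
        raise ValueError("channel and region geometry mismatch")
    if policy.mode == "classifier":
        score = policy.classifier.score(channel)
        if score.shape != channel.shape:
            raise ValueError("classifier geometry mismatch")
        positive = score > 0.5
    else:
        thr = policy.fixed_value if policy.mode == "fixed" else otsu_threshold(channel, region)
        positive = channel > thr
    return BinaryMask(values=positive & region.values, source_channel=source_channel,
                      provenance=policy.mode if policy.mode != "fixed" else "fixed_threshold")


def pixel_ratio(numerator: BinaryMask, denominator: BinaryMask) -> float:
    """Percentage of denominator-positive pixels that are also numerator-positive.

    This is the FnBPA5/FN pixel ratio of the tension read-out: the
    intersection is used so numerator noise off the reference fibers does not
    inflate the ratio.
    """
    if numerator.shape != denominator.shape:
        raise ValueError("mask geometry mismatch")
    denom = denominator.positive_count
    if denom == 0:
        raise ValueError("no reference-positive pixels")
    joint = int(np.sum(numerator.values & denominator.values))
    return 100.0 * joint / denom


def pixel_density(mask: BinaryMask, region: BinaryMask) -> float:
    """Percentage of region pixels covered by the mask (e.g. TNC or CD34 density)."""
    if mask.shape != region.shape:
        raise ValueError("mask geometry mismatch")
    area = region.positive_count
    if area == 0:
        raise ValueError("empty analysis region")
    return 100.0 * int(np.sum(mask.values & region.values)) / area


@dataclass
class RatiometricMap:
    """Per-pixel FnBPA5/FN intensity ratio on the joint positive mask.

    ``values`` is NaN outside the joint mask — the ratio is undefined there,
    not zero. Ratios are relative (a.u.): two fluorophores do not permit
    absolute molecular ratios.
    """

    values: np.ndarray
    mask: BinaryMask

    def __post_init__(self) -> None:
        defined = np.isfinite(self.values)
        if not np.array_equal(defined, self.mask.values):
            raise ValueError("values must be defined exactly on the joint mask")
        if np.any(self.values[defined] < 0):
            raise ValueError("ratios must be >= 0")

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values)) if self.mask.positive_count else float("nan")


def ratiometric_map(
    fnbpa5: np.ndarray,
    fibronectin: np.ndarray,
    region: BinaryMask,
    policy: ThresholdPolicy | None = None,
) -> RatiometricMap:
    """Pixel-by-pixel FnBPA5/FN intensity ratio where both channels pass threshold."""
    policy = policy or ThresholdPolicy(mode="otsu")
    m_num = make_mask(fnbpa5, policy, region, "FnBPA5")
    m_den = make_mask(fibronectin, policy, region, "FN")
    joint = BinaryMask(values=m_num.values & m_den.values, source_channel="FnBPA5/FN",
                       provenance=m_num.provenance)
    if joint.positive_count == 0:
        logger.warning("ratiometric map: empty joint mask")
    values = np.full(joint.shape, np.nan)
    sel = joint.values
    values[sel] = np.asarray(fnbpa5, dtype=np.float64)[sel] / np.asarray(
        fibronectin, dtype=np.float64)[sel]
    return RatiometricMap(values=values, mask=joint)
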