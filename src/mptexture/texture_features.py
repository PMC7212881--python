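"""Per-FoV texture parameters for multiphoton channel images.

Each channel of each field of view is min–max normalized and reduced to 13
texture parameters: five first-order statistics of the intensity histogram
(mean, standard deviation, kurtosis, skewness, entropy) and, for each of two
pixel distances (6 µm and 40 µm by default), four gray-level co-occurrence
matrix (GLCM) properties — contrast, correlation, energy, homogeneity —
averaged over the four orientations 0°, 45°, 90° and 135°.  Vectors from
several channels of the same FoV are concatenated (26 values for
CARS + TPEF).

Conventions (frozen into the model manifest via :meth:`TextureConfig.config_hash`):

* sample standard deviation (N−1 denominator);
* population (biased, non-excess) skewness ``m3/m2^1.5`` and kurtosis
  ``m4/m2²`` (a normal distribution has kurtosis 3, a symmetric two-point
  distribution 1);
* base-2 entropy over a 256-bin histogram of [0, 1];
* GLCMs over 8 gray levels, asymmetric counting (each pair counted once in
  the stated offset direction), normalized to joint probabilities before
  property evaluation.

Degenerate (constant) FoVs — expected for the SHG channel in nontumor
tissue — yield defined values (sd, skewness, kurtosis, entropy 0;
correlation 1) plus a flag rather than NaNs, so they cannot crash the
classifier.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from functools import lru_cache
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .imaging_io import Channel, FieldOfView

log = logging.getLogger(__name__)

#: Pixel offsets (drow, dcol) per unit distance for each GLCM orientation.
ORIENTATION_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

FIRST_ORDER_NAMES = ("mean", "sd", "kurtosis", "skewness", "entropy_bits")
GLCM_PROPERTY_NAMES = ("contrast", "correlation", "energy", "homogeneity")


class TextureError(Exception):
    """Invalid input to texture extraction."""


class FirstOrderFeatures(NamedTuple):
    mean: float
    sd: float
    kurtosis: float
    skewness: float
    entropy_bits: float


class GLCMProperties(NamedTuple):
    contrast: float
    correlation: float
    energy: float
    homogeneity: float


@dataclass(frozen=True)
class TextureConfig:
    """Extraction configuration; its hash travels with every feature table/model."""

    levels: int = 8
    distances_um: tuple[float, ...] = (6.0, 40.0)
    orientations: tuple[int, ...] = (0, 45, 90, 135)
    entropy_bins: int = 256
    fov_rows: int = 104
    fov_cols: int = 208

    def __post_init__(self) -> None:
        object.__setattr__(self, "distances_um", tuple(float(d) for d in self.distances_um))
        object.__setattr__(self, "orientations", tuple(int(o) for o in self.orientations))
        if self.levels < 2:
            raise TextureError("levels must be ≥ 2")
        if not self.distances_um or any(d <= 0 for d in self.distances_um):
            raise TextureError("distances_um must be positive")
        bad = set(self.orientations) - set(ORIENTATION_OFFSETS)
        if bad or not self.orientations:
            raise TextureError(f"unsupported orientations: {sorted(bad)}")
        if self.entropy_bins < 2:
            raise TextureError("entropy_bins must be ≥ 2")

    @property
    def n_features(self) -> int:
        return len(FIRST_ORDER_NAMES) + len(GLCM_PROPERTY_NAMES) * len(self.distances_um)

    def feature_names(self) -> tuple[str, ...]:
        """The frozen per-channel feature order."""
        names = list(FIRST_ORDER_NAMES)
        for d in self.distances_um:
            names += [f"{p}_d{d:g}" for p in GLCM_PROPERTY_NAMES]
        return tuple(names)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class NormalizedFoV:
    """Min–max normalized FoV in [0, 1]; all-zero + flag when the source was constant."""

    pixels: np.ndarray
    degenerate: bool
    provenance: tuple[str, int, int, str]
    pixel_size_um: float = 1.0


@dataclass(frozen=True)
class GLCMatrix:
    """Gray-level co-occurrence matrix for one offset."""

    counts: np.ndarray
    levels: int
    distance_px: int
    orientation_deg: int
    normalized: bool


@dataclass(frozen=True)
class ChannelFeatureVector:
    """The 13 texture parameters of one channel of one FoV, in frozen order."""

    values: np.ndarray
    names: tuple[str, ...]
    channel: Channel
    provenance: tuple[str, int, int, str]
    degenerate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.names),):
            raise TextureError("feature values and names disagree in length")
        if not np.all(np.isfinite(self.values)):
            raise TextureError("feature vector contains NaN/Inf")


@dataclass(frozen=True)
class CombinedFeatureVector:
    """Concatenation of per-channel vectors of one FoV, in declared channel order."""

    values: np.ndarray
    names: tuple[str, ...]
    channel_set: tuple[Channel, ...]
    provenance: tuple[str, int, int]


def minmax_normalize(fov: FieldOfView) -> NormalizedFoV:
    """Rescale intensities to [0, 1] via (x − min) / (max − min).

    A constant FoV maps to all zeros with ``degenerate=True``.  The output
    is invariant under positive affine transforms of the input.
    """
    x = fov.pixels
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return NormalizedFoV(np.zeros_like(x), True, fov.provenance, fov.pixel_size_um)
    return NormalizedFoV((x - lo) / (hi - lo), False, fov.provenance, fov.pixel_size_um)


def first_order_features(norm: NormalizedFoV, entropy_bins: int = 256) -> FirstOrderFeatures:
    """Histogram statistics of a normalized FoV.

    Skewness and kurtosis use population central moments (``m3/m2^1.5``,
    ``m4/m2²``); entropy is −Σ p log2 p over an ``entropy_bins``-bin
    histogram of [0, 1], with 0·log 0 := 0.  A zero-variance FoV returns
    skewness = kurtosis = 0.
    """
    x = norm.pixels.ravel()
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    xc = x - mean
    m2 = float(np.mean(xc * xc))
    if m2 == 0.0:
        skew = kurt = 0.0
    else:
        m3 = float(np.mean(xc ** 3))
        m4 = float(np.mean(xc ** 4))
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2
    idx = np.minimum((x * entropy_bins).astype(np.int64), entropy_bins - 1)
    p = np.bincount(idx, minlength=entropy_bins).astype(float)
    p /= x.size
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return FirstOrderFeatures(mean, sd, kurt, skew, entropy)


def quantize(norm: NormalizedFoV, levels: int) -> np.ndarray:
    """Uniformly bin [0, 1] into ``levels`` integer gray levels.

    Value 1.0 maps to the top level (``levels − 1``).
    """
    if levels < 2:
        raise TextureError(f"levels must be ≥ 2, got {levels}")
    return np.minimum((norm.pixels * levels).astype(np.int64), levels - 1)


def glcm(levelimg: np.ndarray, distance_px: int, orientation_deg: int,
         levels: int | None = None, normalize: bool = True) -> GLCMatrix:
    """Gray-level co-occurrence matrix of an integer level image.

    Pairs (reference pixel, pixel at the orientation offset scaled by
    ``distance_px``) are counted once, in the stated direction (asymmetric
    counting); out-of-bounds pairs are skipped.  With ``normalize=True`` the
    counts are scaled to a joint probability matrix.
    """
    levelimg = np.asarray(levelimg)
    if levelimg.ndim != 2:
        raise TextureError("level image must be 2-D")
    if distance_px < 1:
        raise TextureError(f"distance must be ≥ 1 px, got {distance_px}")
    if orientation_deg not in ORIENTATION_OFFSETS:
        raise TextureError(f"unsupported orientation {orientation_deg}")
    L = int(levels) if levels is not None else int(levelimg.max()) + 1
    if L < 2:
        L = 2
    if levelimg.min() < 0 or levelimg.max() >= L:
        raise TextureError("level image values outside [0, levels)")
    dr0, dc0 = ORIENTATION_OFFSETS[orientation_deg]
    dr, dc = dr0 * distance_px, dc0 * distance_px
    R, C = levelimg.shape
    r0, r1 = max(0, -dr), R - max(0, dr)
    c0, c1 = max(0, -dc), C - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise TextureError(
            f"no co-occurring pairs at distance {distance_px}px, orientation "
            f"{orientation_deg}° for shape {levelimg.shape}")
    a = levelimg[r0:r1, c0:c1]
    b = levelimg[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    counts = np.bincount((a * L + b).ravel(), minlength=L * L).reshape(L, L).astype(float)
    if normalize:
        counts = counts / counts.sum()
    return GLCMatrix(counts=counts, levels=L, distance_px=distance_px,
                     orientation_deg=orientation_deg, normalized=normalize)


@lru_cache(maxsize=8)
def _property_weights(L: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    diff = i - j
    return (diff ** 2).astype(float), 1.0 / (1.0 + np.abs(diff))


def glcm_properties(g: GLCMatrix) -> GLCMProperties:
    """Contrast, correlation, energy, homogeneity of a normalized GLCM.

    correlation = Σ p(i,j)(i−μ_r)(j−μ_c)/(σ_r σ_c) with marginal
    means/SDs; a zero-variance matrix (all mass on one diagonal entry —
    perfectly predictable constant texture) returns correlation 1.
    """
    if not g.normalized:
        raise TextureError("glcm_properties requires a normalized GLCM")
    p = g.counts
    L = g.levels
    sq_diff, inv_diff = _property_weights(L)
    contrast = float((p * sq_diff).sum())
    energy = float((p * p).sum())
    homogeneity = float((p * inv_diff).sum())
    idx = np.arange(L, dtype=float)
    pr, pc = p.sum(axis=1), p.sum(axis=0)
    mu_r, mu_c = float(idx @ pr), float(idx @ pc)
    var_r = float(((idx - mu_r) ** 2) @ pr)
    var_c = float(((idx - mu_c) ** 2) @ pc)
    denom = np.sqrt(var_r * var_c)
    if denom == 0.0:
        log.debug("zero-variance GLCM (constant texture); correlation := 1")
        correlation = 1.0
    else:
        cov = float(((idx[:, None] - mu_r) * (idx[None, :] - mu_c) * p).sum())
        correlation = cov / denom
    return GLCMProperties(contrast, correlation, energy, homogeneity)


def distance_px_for(d_um: float, pixel_size_um: float) -> int:
    """Convert a distance in µm to pixels (nearest integer, at least 1)."""
    d_px = max(1, round(d_um / pixel_size_um))
    if abs(d_px - d_um / pixel_size_um) > 1e-9:
        log.info("distance %.3g µm at %.3g µm/px rounded to %d px",
                 d_um, pixel_size_um, d_px)
    return d_px


def channel_texture_vector(fov: FieldOfView,
                           config: TextureConfig = TextureConfig()) -> ChannelFeatureVector:
    """The 13 texture parameters of one channel of one FoV.

    Five first-order statistics plus, per configured distance, the four GLCM
    properties averaged over the configured orientations.  Distances are
    given in µm and converted via the FoV's pixel size.
    """
    rows, cols = fov.shape
    norm = minmax_normalize(fov)
    fo = first_order_features(norm, config.entropy_bins)
    lvl = quantize(norm, config.levels)
    values = list(fo)
    for d_um in config.distances_um:
        d_px = distance_px_for(d_um, fov.pixel_size_um)
        if d_px >= rows or d_px >= cols:
            raise TextureError(
                f"FoV of shape {fov.shape} is smaller than GLCM distance "
                f"{d_um} µm ({d_px} px)")
        props = np.array([glcm_properties(glcm(lvl, d_px, o, config.levels))
                          for o in config.orientations])
        values.extend(props.mean(axis=0))
    return ChannelFeatureVector(values=np.array(values), names=config.feature_names(),
                                channel=fov.channel, provenance=fov.provenance,
                                degenerate=norm.degenerate)


def combine_vectors(vectors: Sequence[ChannelFeatureVector]) -> CombinedFeatureVector:
    """Concatenate per-channel vectors of one FoV in the given channel order."""
    if not vectors:
        raise TextureError("no vectors to combine")
    positions = {v.provenance[:3] for v in vectors}
    if len(positions) != 1:
        raise TextureError(f"mixed FoV provenance: {sorted(positions)}")
    channels = tuple(v.channel for v in vectors)
    if len(set(channels)) != len(channels):
        raise TextureError(f"duplicate channels: {channels}")
    values = np.concatenate([v.values for v in vectors])
    names = tuple(f"{v.channel.value}_{n}" for v in vectors for n in v.names)
    return CombinedFeatureVector(values=values, names=names, channel_set=channels,
                                 provenance=vectors[0].provenance[:3])
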