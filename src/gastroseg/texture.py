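"""First-order and GLCM texture features over a region of interest.

CT texture analysis quantifies tumor heterogeneity from the pixel statistics
of a delineated ROI.  This module extracts the five classical parameters:

* first-order (gray-histogram): **mean**, **skewness** (m3 / m2^1.5),
  **kurtosis** (Pearson convention m4 / m2^2, so a normal field scores 3),
  and **entropy** in bits (−Σ p·log2 p over the quantized histogram);
* second-order: **GLCM correlation**, the Haralick correlation of the
  gray-level co-occurrence matrix.

The GLCM here is ROI-aware: a pixel pair contributes only when *both* pixels
lie inside the ROI, which standard rectangular-window implementations cannot
express.  Quantization is uniform between the ROI minimum and maximum
(64 levels by default), which makes every feature except the mean invariant
under a constant intensity shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from gastroseg.phantoms import CTSlice

__all__ = [
    "ROI",
    "TextureVector",
    "GLCM",
    "TextureConfig",
    "DEFAULT_OFFSETS",
    "quantize",
    "histogram_features",
    "glcm",
    "glcm_correlation",
    "wall_bbox_roi",
    "extract",
]

#: Distance-1 offsets for directions 0°, 45°, 90°, 135° in row-major image
#: coordinates (row delta, column delta).
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_MIN_ROI_PIXELS = 16


@dataclass(frozen=True)
class ROI:
    """Binary inclusion mask selecting the pixels under analysis."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("ROI mask must be binary")
        m = m.astype(bool)
        if int(m.sum()) < _MIN_ROI_PIXELS:
            raise ValueError(
                f"ROI must select at least {_MIN_ROI_PIXELS} pixels for stable moments"
            )
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class TextureVector:
    """The five texture parameters for one ROI/phase."""

    mean: float
    skewness: float
    kurtosis: float
    entropy: float
    glcm_correlation: float
    degenerate: bool = False  # constant ROI: higher moments undefined, reported as 0


@dataclass(frozen=True)
class GLCM:
    """Normalized gray-level co-occurrence matrix."""

    matrix: np.ndarray
    levels: int
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool


@dataclass(frozen=True)
class TextureConfig:
    """Quantization depth, GLCM offsets, and the correlation normalization."""

    levels: int = 64
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    normalized_correlation: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


def _roi_values(slc: CTSlice | np.ndarray, roi: ROI) -> np.ndarray:
    px = slc.pixels if isinstance(slc, CTSlice) else np.asarray(slc, dtype=float)
    if px.shape != roi.mask.shape:
        raise ValueError(f"ROI shape {roi.mask.shape} != slice shape {px.shape}")
    return px[roi.mask]


def quantize(slc: CTSlice | np.ndarray, roi: ROI, levels: int = 64) -> np.ndarray:
    """Quantize ROI intensities into ``levels`` uniform bins between ROI min/max.

    Returns an integer grid of the slice's shape with levels in
    [0, levels-1] inside the ROI and -1 outside.  A constant ROI maps to
    level 0 everywhere.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    px = slc.pixels if isinstance(slc, CTSlice) else np.asarray(slc, dtype=float)
    vals = _roi_values(px, roi)
    out = np.full(px.shape, -1, dtype=np.int64)
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-300:
        out[roi.mask] = 0
        return out
    q = np.floor((vals - lo) / (hi - lo) * levels).astype(np.int64)
    out[roi.mask] = np.clip(q, 0, levels - 1)
    return out


def histogram_features(
    slc: CTSlice | np.ndarray, roi: ROI, levels: int = 64
) -> tuple[float, float, float, float]:
    """(mean, skewness, kurtosis, entropy) of the ROI intensities.

    Population moments: skewness m3/m2^1.5, kurtosis m4/m2^2 (normal → 3);
    entropy −Σ p·log2 p over the ``levels``-bin quantized histogram with
    0·log 0 ≡ 0.  A constant ROI reports skewness = kurtosis = 0 (flagged
    degenerate by :func:`extract`) and entropy 0.
    """
    vals = _roi_values(slc, roi)
    mean = float(vals.mean())
    if float(vals.var()) == 0.0:
        return mean, 0.0, 0.0, 0.0
    skew = float(stats.skew(vals, bias=True))
    kurt = float(stats.kurtosis(vals, fisher=False, bias=True))
    q = quantize(slc, roi, levels)
    counts = np.bincount(q[roi.mask], minlength=levels).astype(float)
    p = counts / counts.sum()
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    return mean, skew, kurt, entropy


def glcm(
    quantized: np.ndarray,
    roi: ROI | np.ndarray,
    levels: int,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> GLCM:
    """ROI-restricted gray-level co-occurrence matrix.

    A pair (p, p+offset) is counted only when both pixels lie inside the ROI.
    Counts are accumulated over all offsets, optionally symmetrized (each pair
    counted in both directions), and normalized to sum to 1.  ``roi`` may be a
    raw boolean mask here — co-occurrence needs pairs, not the 16-pixel
    minimum that stabilizes the histogram moments.
    """
    q = np.asarray(quantized)
    mask = (roi.mask if isinstance(roi, ROI) else np.asarray(roi).astype(bool))
    if q.shape != mask.shape:
        raise ValueError("quantized grid and ROI shapes differ")
    mat = np.zeros((levels, levels), dtype=float)
    h, w = q.shape
    for dr, dc in offsets:
        rs = slice(max(0, -dr), min(h, h - dr))
        cs = slice(max(0, -dc), min(w, w - dc))
        rs2 = slice(max(0, dr), min(h, h + dr))
        cs2 = slice(max(0, dc), min(w, w + dc))
        valid = mask[rs, cs] & mask[rs2, cs2]
        i = q[rs, cs][valid]
        j = q[rs2, cs2][valid]
        np.add.at(mat, (i, j), 1.0)
    if symmetric:
        mat = mat + mat.T
    total = mat.sum()
    if total == 0:
        raise ValueError("ROI admits no valid pixel pairs for the given offsets")
    return GLCM(matrix=mat / total, levels=levels, offsets=tuple(offsets), symmetric=symmetric)


def glcm_correlation(P: GLCM | np.ndarray, normalized: bool = True) -> float:
    """Haralick correlation Σ (i−μi)(j−μj) P(i,j) / (σi σj), in [−1, 1].

    ``normalized=False`` returns the raw co-occurrence covariance
    Σ (i−μi)(j−μj) P(i,j) instead (some commercial texture packages report
    this unnormalized variant, which lives on an arbitrary scale).
    """
    mat = P.matrix if isinstance(P, GLCM) else np.asarray(P, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("GLCM must be a square matrix")
    if abs(mat.sum() - 1.0) > 1e-8:
        raise ValueError("GLCM must be normalized to sum to 1")
    n = mat.shape[0]
    idx = np.arange(n, dtype=float)
    pi = mat.sum(axis=1)
    pj = mat.sum(axis=0)
    mi, mj = float(idx @ pi), float(idx @ pj)
    cov = float(((idx[:, None] - mi) * (idx[None, :] - mj) * mat).sum())
    if not normalized:
        return cov
    si = float(np.sqrt(((idx - mi) ** 2 * pi).sum()))
    sj = float(np.sqrt(((idx - mj) ** 2 * pj).sum()))
    if si == 0.0 or sj == 0.0:
        raise ValueError("zero marginal variance; GLCM correlation undefined")
    return cov / (si * sj)


def wall_bbox_roi(mask: np.ndarray, margin: int = 4) -> ROI:
    """Rectangular ROI: the bounding box of a wall mask plus a margin.

    A rectangular patch covering the lesion and a rim of surrounding tissue is
    the common delineation in CT texture analysis.  Including the neighbouring
    tissue plateaus anchors the min–max quantization range, so the entropy of
    the ROI responds to within-wall heterogeneity rather than normalizing it
    away.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    out = np.zeros_like(m)
    out[
        max(0, rows[0] - margin) : min(m.shape[0], rows[-1] + margin + 1),
        max(0, cols[0] - margin) : min(m.shape[1], cols[-1] + margin + 1),
    ] = True
    return ROI(mask=out.astype(np.uint8))


def extract(
    slc: CTSlice | np.ndarray, roi: ROI, config: TextureConfig = TextureConfig()
) -> TextureVector:
    """Full texture vector (mean, skewness, kurtosis, entropy, GLCM correlation).

    Deterministic in its inputs.  A constant ROI yields a vector flagged
    ``degenerate`` with higher moments and correlation reported as 0.
    """
    mean, skew, kurt, entropy = histogram_features(slc, roi, config.levels)
    vals = _roi_values(slc, roi)
    if float(vals.var()) == 0.0:
        return TextureVector(mean, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    q = quantize(slc, roi, config.levels)
    P = glcm(q, roi, config.levels, config.offsets, config.symmetric)
    try:
        corr = glcm_correlation(P, normalized=config.normalized_correlation)
    except ValueError:
        return TextureVector(mean, skew, kurt, entropy, 0.0, degenerate=True)
    return TextureVector(mean, skew, kurt, entropy, corr)
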