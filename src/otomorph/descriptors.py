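"""Wavelet shape descriptors, mean shapes and the ICC variance profile.

The radial profile r(θ) of an otolith, sampled at 2^J equally spaced
angles, is decomposed with an orthonormal discrete wavelet transform using
periodic (circular) boundary handling — the radius function wraps around
the outline, so periodization is the natural mode and keeps the transform
energy-preserving and length-preserving.  Each coefficient is annotated
with the decomposition level it belongs to and the center angle of its
support, which is what allows variance decompositions to be plotted
*along the outline*.

The default filter is the least-asymmetric Daubechies wavelet with 10
vanishing moments (``sym10``); the family is configurable since nothing
about the analysis depends on a particular orthogonal filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .io_core import ValidationError
from .outline import Outline, RadiusVector

__all__ = [
    "WaveletCoefficients",
    "CoefficientMatrix",
    "ICCProfile",
    "dwt_radii",
    "idwt",
    "matrix_from_radii",
    "mean_shape",
    "icc_profile",
]


def _check_pow2(n: int) -> int:
    if n < 2 or (n & (n - 1)) != 0:
        raise ValidationError(f"wavelet input length must be a power of two, got {n}")
    return int(np.log2(n))


def _default_levels(n: int, family: str) -> int:
    return max(1, pywt.dwt_max_level(n, family))


def _structure(n: int, levels: int) -> list[int]:
    """Coefficient-array lengths in wavedec order [cA_L, cD_L, ..., cD_1]."""
    lens = [n >> levels]
    for j in range(levels, 0, -1):
        lens.append(n >> j)
    return lens


def _annotate(n: int, levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-coefficient (level, center angle).  Level 0 marks the smooth
    (approximation) band; detail levels count 1 = finest ... L = coarsest.
    A coefficient at position k in a band of m coefficients covers 1/m of
    the outline and is assigned center angle 360*(k + 0.5)/m."""
    lens = _structure(n, levels)
    level_of_band = [0] + list(range(levels, 0, -1))
    level = np.concatenate([np.full(m, lv) for m, lv in zip(lens, level_of_band)])
    angle = np.concatenate([360.0 * (np.arange(m) + 0.5) / m for m in lens])
    return level.astype(int), angle


@dataclass
class WaveletCoefficients:
    """One specimen's full orthonormal coefficient vector."""

    values: np.ndarray
    coef_angle: np.ndarray
    coef_level: np.ndarray
    family: str
    levels: int

    @property
    def n_angles(self) -> int:
        return int(self.values.size)


@dataclass
class CoefficientMatrix:
    """Specimens x coefficients, with per-coefficient angle/level labels.

    The transform is complete (``n_coef == n_angles``); any filtering of
    coefficients happens downstream and operates on column subsets.
    """

    values: np.ndarray
    coef_angle: np.ndarray
    coef_level: np.ndarray
    specimen_ids: list[str]
    family: str = "sym10"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coef_angle = np.asarray(self.coef_angle, dtype=float)
        self.coef_level = np.asarray(self.coef_level, dtype=int)
        n, m = self.values.shape
        if len(self.specimen_ids) != n:
            raise ValidationError("specimen_ids length does not match rows")
        if self.coef_angle.size != m or self.coef_level.size != m:
            raise ValidationError("coefficient annotations do not match columns")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("coefficient matrix contains non-finite values")

    @property
    def levels(self) -> int:
        return int(self.coef_level.max())

    @property
    def structure(self) -> list[int]:
        return _structure(self.values.shape[1], self.levels)


def dwt_radii(
    radii: RadiusVector | np.ndarray, family: str = "sym10", levels: int | None = None
) -> WaveletCoefficients:
    """Orthonormal dyadic wavelet decomposition of a radial profile.

    Output length equals input length; with an orthogonal family and
    periodization the transform conserves energy exactly, so Euclidean
    distances between coefficient vectors equal distances between the
    underlying radius vectors.
    """
    r = radii.radii if isinstance(radii, RadiusVector) else np.asarray(radii, dtype=float)
    J = _check_pow2(r.size)
    if levels is None:
        levels = _default_levels(r.size, family)
    if not (1 <= levels <= J):
        raise ValidationError(f"levels must be in [1, {J}], got {levels}")
    coeffs = pywt.wavedec(r, family, mode="periodization", level=levels)
    values = np.concatenate(coeffs)
    level, angle = _annotate(r.size, levels)
    return WaveletCoefficients(values, angle, level, family, levels)


def idwt(coefs: WaveletCoefficients, family: str | None = None) -> np.ndarray:
    """Invert :func:`dwt_radii`.  ``family`` must match the forward transform."""
    if family is not None and family != coefs.family:
        raise ValidationError(
            f"wavelet family mismatch: forward used {coefs.family!r}, got {family!r}"
        )
    return _invert(coefs.values, coefs.n_angles, coefs.levels, coefs.family)


def _invert(values: np.ndarray, n: int, levels: int, family: str) -> np.ndarray:
    lens = _structure(n, levels)
    parts, start = [], 0
    for m in lens:
        parts.append(np.asarray(values[start : start + m], dtype=float))
        start += m
    return pywt.waverec(parts, family, mode="periodization")[:n]


def matrix_from_radii(
    radius_vectors: dict[str, RadiusVector | np.ndarray],
    family: str = "sym10",
    levels: int | None = None,
) -> CoefficientMatrix:
    """Transform a set of radial profiles into one coefficient matrix."""
    ids = list(radius_vectors)
    rows = [
        rv.radii if isinstance(rv, RadiusVector) else np.asarray(rv, dtype=float)
        for rv in radius_vectors.values()
    ]
    X = np.vstack(rows)
    _check_pow2(X.shape[1])
    if levels is None:
        levels = _default_levels(X.shape[1], family)
    coeffs = pywt.wavedec(X, family, mode="periodization", level=levels, axis=1)
    values = np.concatenate(coeffs, axis=1)
    level, angle = _annotate(X.shape[1], levels)
    return CoefficientMatrix(values, angle, level, ids, family)


# ---------------------------------------------------------------------------
# mean shapes
# ---------------------------------------------------------------------------


def mean_shape(
    matrix: CoefficientMatrix,
    group: np.ndarray | list,
    normalize: bool = False,
) -> dict[str, Outline]:
    """Per-population mean shape, reconstructed through the inverse transform.

    The transform is linear, so averaging coefficients and inverting equals
    averaging the radial profiles directly; working in coefficient space
    keeps this consistent with any coefficient-level filtering applied
    elsewhere.  With ``normalize=True`` each mean shape is rescaled to unit
    mean radius for size-free display.
    """
    group = np.asarray(group)
    if group.size != matrix.values.shape[0]:
        raise ValidationError("group labels do not match specimen rows")
    n = matrix.values.shape[1]
    theta = 2.0 * np.pi * np.arange(n) / n
    shapes: dict[str, Outline] = {}
    for g in pd.unique(group):
        rows = matrix.values[group == g]
        if rows.shape[0] == 0:
            warnings.warn(f"population {g!r} has no specimens; skipped")
            continue
        radii = _invert(rows.mean(axis=0), n, matrix.levels, matrix.family)
        if np.any(radii <= 0):
            warnings.warn(f"population {g!r}: mean shape has non-positive radii; skipped")
            continue
        if normalize:
            radii = radii / radii.mean()
        shapes[str(g)] = Outline(
            np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
        )
    return shapes


# ---------------------------------------------------------------------------
# ICC profile
# ---------------------------------------------------------------------------


@dataclass
class ICCProfile:
    """Per-coefficient variance partition, ordered by outline angle.

    ``icc`` is the one-way random-effects intraclass correlation
    σ²_between / (σ²_between + σ²_within), clamped to [0, 1] for display.
    """

    coef_index: np.ndarray
    angle: np.ndarray
    icc: np.ndarray
    mean_coef: np.ndarray
    sd_coef: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef_index": self.coef_index,
                "angle_deg": self.angle,
                "icc": self.icc,
                "mean": self.mean_coef,
                "sd": self.sd_coef,
            }
        )


def icc_profile(matrix: CoefficientMatrix, group: np.ndarray | list) -> ICCProfile:
    """Between-population variance proportion per coefficient.

    Uses the one-way random-effects ANOVA estimator with the standard
    unbalanced-design coefficient n0 = (N - Σn_i²/N) / (k - 1):
    σ²_between = (MSB - MSW)/n0 (truncated at zero), σ²_within = MSW.
    Populations with a single specimen are dropped with a warning.
    """
    group = np.asarray(group)
    X = matrix.values
    if group.size != X.shape[0]:
        raise ValidationError("group labels do not match specimen rows")

    labels, counts = np.unique(group, return_counts=True)
    singletons = labels[counts < 2]
    if singletons.size:
        warnings.warn(f"dropping populations with a single specimen: {singletons.tolist()}")
        keep = ~np.isin(group, singletons)
        X, group = X[keep], group[keep]
        labels, counts = np.unique(group, return_counts=True)
    k = labels.size
    if k < 2:
        raise ValidationError("icc_profile needs at least two populations with n >= 2")

    N = X.shape[0]
    icc = _icc_oneway(X, group, labels, counts)
    order = np.argsort(matrix.coef_angle, kind="stable")
    return ICCProfile(
        coef_index=order.astype(int),
        angle=matrix.coef_angle[order],
        icc=icc[order],
        mean_coef=matrix.values.mean(axis=0)[order],
        sd_coef=matrix.values.std(axis=0, ddof=1)[order],
    )


def _icc_oneway(
    X: np.ndarray, group: np.ndarray, labels: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    """Vectorized one-way random-effects ICC per column of X."""
    N, k = X.shape[0], labels.size
    grand = X.mean(axis=0)
    means = np.vstack([X[group == g].mean(axis=0) for g in labels])  # (k, m)
    ssb = (counts[:, None] * (means - grand) ** 2).sum(axis=0)
    ssw = np.zeros(X.shape[1])
    for g, m_g in zip(labels, means):
        ssw += ((X[group == g] - m_g) ** 2).sum(axis=0)
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - (counts**2).sum() / N) / (k - 1)
    s2b = np.maximum((msb - msw) / n0, 0.0)
    denom = s2b + msw
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, s2b / denom, 0.0)
    return np.clip(icc, 0.0, 1.0)
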