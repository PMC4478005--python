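"""Statistical core: ANCOVA coefficient filter, CAP ordination, permutation
ANOVA, within-population variance and the dispersion-versus-age regression.

The ordination is Canonical Analysis of Principal coordinates (CAP):
a principal-coordinate (metric MDS) decomposition of the Euclidean
inter-specimen distance matrix, followed by a redundancy-style constrained
ordination of the coordinate scores on population membership.  An optional
covariate (age) is partialled out by linear residualization before
constraining, and permutation tests then act on the residualized rows
(reduced-model permutation).  With Euclidean distances on orthonormal
wavelet coefficients this is equivalent to redundancy analysis on the raw
coefficients, which is what makes Euclidean the natural metric here.

Significance uses a pseudo-F statistic,

    F = (constrained inertia / df_constraint) / (residual inertia / df_residual),

whose null distribution is built by permuting specimen rows.  Sampled
permutation p-values use the add-one convention p = (1 + b)/(1 + m), with
ties counted as extreme; the exhaustive mode enumerates every row ordering
and is exact.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ValidationError

__all__ = [
    "FilterReport",
    "OrdinationResult",
    "ancova_filter",
    "cap",
    "permutation_anova",
    "within_variance",
    "variance_age_regression",
]

#: PCoA axes with eigenvalue below this fraction of the largest are treated
#: as numerically null space and discarded before constraining.
_EIG_TOL = 1e-10


# ---------------------------------------------------------------------------
# ANCOVA length-by-population interaction filter
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Outcome of the per-coefficient length x population interaction test."""

    kept: list[int]
    dropped: list[tuple[int, float]]
    alpha: float
    p_values: np.ndarray = field(repr=False, default=None)

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def ancova_filter(
    values: np.ndarray,
    length_cm: np.ndarray,
    group: np.ndarray | list,
    alpha: float = 0.05,
) -> FilterReport:
    """Drop coefficients whose allometry differs between populations.

    For every coefficient the linear model
    ``coef ~ length + population + length:population`` is compared against
    the no-interaction model by an F-test on residual sums of squares; a
    coefficient with interaction p < ``alpha`` is excluded, because its
    population differences cannot be separated from population-specific
    length scaling.  P-values are per-coefficient with no multiplicity
    correction.  Populations too small to estimate their own slope and
    intercept (n < 3) are left out of the test with a warning.
    """
    X = np.asarray(values, dtype=float)
    length = np.asarray(length_cm, dtype=float)
    group = np.asarray(group)
    if not np.all(length > 0):
        raise ValidationError("lengths must be positive")
    if X.shape[0] != length.size or X.shape[0] != group.size:
        raise ValidationError("values, length_cm and group must align by row")

    labels, counts = np.unique(group, return_counts=True)
    small = labels[counts < 3]
    if small.size:
        warnings.warn(
            f"populations excluded from the ANCOVA filter (n < 3): {small.tolist()}"
        )
        keep = ~np.isin(group, small)
        X, length, group = X[keep], length[keep], group[keep]
        labels = np.unique(group)
    k = labels.size
    if k < 2:
        raise ValidationError("ancova_filter needs at least two populations")

    n = X.shape[0]
    dummies = (group[:, None] == labels[None, 1:]).astype(float)  # k-1 columns
    ones = np.ones((n, 1))
    Xr = np.hstack([ones, length[:, None], dummies])
    Xf = np.hstack([Xr, dummies * length[:, None]])
    df_int = k - 1
    df_resid = n - Xf.shape[1]
    if df_resid < 1:
        raise ValidationError("too few specimens for the interaction model")

    rss_r = _rss(Xr, X)
    rss_f = _rss(Xf, X)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_r - rss_f) / df_int) / (rss_f / df_resid)
    F = np.where(rss_f <= 1e-300 * np.maximum(rss_r, 1.0), np.inf, F)
    p = stats.f.sf(F, df_int, df_resid)
    p = np.where(np.isnan(p), 1.0, p)  # constant column: no evidence of interaction

    drop = p < alpha
    kept = np.flatnonzero(~drop).tolist()
    dropped = [(int(i), float(p[i])) for i in np.flatnonzero(drop)]
    return FilterReport(kept=kept, dropped=dropped, alpha=alpha, p_values=p)


def _rss(design: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    return (resid**2).sum(axis=0)


# ---------------------------------------------------------------------------
# CAP ordination
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """Constrained ordination summary.

    ``site_scores`` are specimen scores on the constrained axes (CAP1,
    CAP2, ...); ``group_centroids`` are per-population mean site scores, one
    row per entry of ``group_labels``.  Inertias are sums of squares of the
    principal-coordinate scores: total = conditional (covariate) +
    constrained (population) + residual.
    """

    site_scores: np.ndarray
    group_labels: list[str]
    group_centroids: np.ndarray
    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    conditional_inertia: float
    residual_inertia: float
    df_constraint: int
    df_residual: int
    pseudo_F: float
    p_value: float

    def centroid_frame(self) -> pd.DataFrame:
        cols = [f"CAP{i + 1}" for i in range(self.group_centroids.shape[1])]
        return pd.DataFrame(self.group_centroids, index=self.group_labels, columns=cols)


def _pcoa_scores(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Principal-coordinate scores of the Euclidean distance matrix.

    Implemented through the SVD of the column-centered data matrix, which is
    exact for Euclidean distances and keeps every axis with eigenvalue above
    ``_EIG_TOL`` times the largest.  Returns (scores, total inertia)."""
    X = np.asarray(values, dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    lam = s**2
    top = lam[0] if lam.size else 0.0
    keep = lam > _EIG_TOL * max(top, 1e-300)
    Y = U[:, keep] * s[keep]
    return Y, float(lam[keep].sum())


def _residualize(Y: np.ndarray, covariate: np.ndarray | None) -> tuple[np.ndarray, float]:
    """Partial a covariate out of the coordinate scores; returns
    (residual scores, conditional inertia)."""
    if covariate is None:
        return Y, 0.0
    z = np.asarray(covariate, dtype=float).reshape(-1, 1)
    if z.shape[0] != Y.shape[0]:
        raise ValidationError("covariate length does not match specimens")
    Z = np.hstack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    Yr = Y - Z @ beta
    return Yr, float((Y**2).sum() - (Yr**2).sum())


def _group_index(group: np.ndarray) -> tuple[list[str], list[np.ndarray]]:
    labels = pd.unique(group)
    return [str(g) for g in labels], [np.flatnonzero(group == g) for g in labels]


def _constrained_inertia(Yr: np.ndarray, idx: list[np.ndarray]) -> float:
    total = 0.0
    for rows in idx:
        m = Yr[rows].mean(axis=0)
        total += rows.size * float(m @ m)
    return total


def cap(
    values: np.ndarray,
    group: np.ndarray | list,
    covariate: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> OrdinationResult:
    """Canonical Analysis of Principal coordinates on Euclidean distances.

    ``values`` is the (filtered) specimens x coefficients matrix, ``group``
    the population labels, ``covariate`` an optional per-specimen value
    (age) partialled out before constraining.  ``n_perm`` permutations give
    the overall test of the population constraint; pass ``n_perm=0`` to
    skip the test (``p_value`` is then NaN).
    """
    group = np.asarray(group)
    X = np.asarray(values, dtype=float)
    if X.shape[0] != group.size:
        raise ValidationError("group labels do not match specimen rows")
    labels, idx = _group_index(group)
    k = len(labels)
    if k < 2:
        raise ValidationError("cap needs at least two populations")
    n = X.shape[0]
    if n < k + 2:
        raise ValidationError("cap needs at least populations + 2 specimens")

    Y, total = _pcoa_scores(X)
    Yr, conditional = _residualize(Y, covariate)

    fitted = np.zeros_like(Yr)
    for rows in idx:
        fitted[rows] = Yr[rows].mean(axis=0)
    constrained = float((fitted**2).sum())
    residual = float((Yr**2).sum()) - constrained

    df_c = k - 1
    df_cond = 1 if covariate is not None else 0
    df_r = n - 1 - df_c - df_cond
    if df_r < 1:
        raise ValidationError("no residual degrees of freedom")
    F_obs = _pseudo_F(constrained, residual, df_c, df_r)

    # canonical axes from the SVD of the fitted (group-mean) matrix
    Uf, sf, Vtf = np.linalg.svd(fitted, full_matrices=False)
    n_axes = min(df_c, int((sf**2 > _EIG_TOL * max(sf[0] ** 2, 1e-300)).sum())) if sf.size else 0
    V = Vtf[:n_axes].T
    site_scores = Yr @ V
    centroids = np.vstack([site_scores[rows].mean(axis=0) for rows in idx]) if n_axes else np.zeros((k, 0))

    if n_perm:
        p = _permutation_p(Yr, idx, df_c, df_r, F_obs, n_perm, seed)
    else:
        p = float("nan")

    return OrdinationResult(
        site_scores=site_scores,
        group_labels=labels,
        group_centroids=centroids,
        eigenvalues=sf[:n_axes] ** 2,
        total_inertia=total,
        constrained_inertia=constrained,
        conditional_inertia=conditional,
        residual_inertia=residual,
        df_constraint=df_c,
        df_residual=df_r,
        pseudo_F=F_obs,
        p_value=p,
    )


def _pseudo_F(constrained: float, residual: float, df_c: int, df_r: int) -> float:
    if residual <= 0:
        return float("inf") if constrained > 0 else 0.0
    return (constrained / df_c) / (residual / df_r)


def _perm_F_batch(
    Yr: np.ndarray,
    idx: list[np.ndarray],
    df_c: int,
    df_r: int,
    perms: np.ndarray,
) -> np.ndarray:
    """Pseudo-F for a (B, n) block of row permutations, vectorized."""
    total = float((Yr**2).sum())
    B = perms.shape[0]
    constrained = np.zeros(B)
    for rows in idx:
        sub = Yr[perms[:, rows]]  # (B, n_g, m)
        m = sub.mean(axis=1)
        constrained += rows.size * (m**2).sum(axis=1)
    residual = total - constrained
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (constrained / df_c) / (residual / df_r)
    return np.where(residual <= 0, np.inf, F)


def _permutation_p(
    Yr: np.ndarray,
    idx: list[np.ndarray],
    df_c: int,
    df_r: int,
    F_obs: float,
    n_perm: int,
    seed: int,
    exhaustive: bool = False,
) -> float:
    n = Yr.shape[0]
    if exhaustive:
        count, total = 0, 0
        block, block_size = [], 4096
        for perm in itertools.permutations(range(n)):
            block.append(perm)
            if len(block) == block_size:
                F = _perm_F_batch(Yr, idx, df_c, df_r, np.asarray(block))
                count += int((F >= F_obs - 1e-12).sum())
                total += len(block)
                block = []
        if block:
            F = _perm_F_batch(Yr, idx, df_c, df_r, np.asarray(block))
            count += int((F >= F_obs - 1e-12).sum())
            total += len(block)
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_perm, int(2e7 // (n * max(Yr.shape[1], 1)) + 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.array([rng.permutation(n) for _ in range(b)])
        F = _perm_F_batch(Yr, idx, df_c, df_r, perms)
        count += int((F >= F_obs - 1e-12).sum())
        done += b
    return (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# permutation ANOVA
# ---------------------------------------------------------------------------


def permutation_anova(
    values: np.ndarray,
    group: np.ndarray | list,
    covariate: np.ndarray | None = None,
    contrast: dict | None = None,
    n_perm: int = 2000,
    seed: int = 0,
    method: str = "sampled",
) -> dict:
    """ANOVA-like permutation test of the population constraint.

    ``contrast`` maps population labels to coarser contrast levels for
    a-priori comparisons (e.g. one fjord versus the pooled others);
    populations absent from the mapping are excluded from that test.  When
    a covariate is supplied the rows permuted are the residualized
    coordinate scores.  ``method="exhaustive"`` enumerates all n! row
    orderings (n <= 8) and returns the exact p; ``"sampled"`` draws
    ``n_perm`` random permutations and uses p = (1 + b)/(1 + n_perm).

    Returns a dict with pseudo_F, p_value, df, and the inertia
    decomposition (variance components).
    """
    if n_perm < 99 and method == "sampled":
        raise ValidationError("n_perm must be >= 99")
    group = np.asarray(group)
    X = np.asarray(values, dtype=float)
    cov = None if covariate is None else np.asarray(covariate, dtype=float)

    if contrast is not None:
        mapped = np.array([contrast.get(g, None) for g in group], dtype=object)
        keep = np.array([m is not None for m in mapped])
        if keep.sum() < 4:
            raise ValidationError("contrast leaves too few specimens")
        X, group = X[keep], mapped[keep]
        if cov is not None:
            cov = cov[keep]

    labels, idx = _group_index(group)
    k = len(labels)
    if k < 2:
        raise ValidationError("permutation test needs at least two groups")
    n = X.shape[0]

    Y, total = _pcoa_scores(X)
    Yr, conditional = _residualize(Y, cov)
    constrained = _constrained_inertia(Yr, idx)
    residual = float((Yr**2).sum()) - constrained
    df_c = k - 1
    df_r = n - 1 - df_c - (1 if cov is not None else 0)
    if df_r < 1:
        raise ValidationError("no residual degrees of freedom")
    F_obs = _pseudo_F(constrained, residual, df_c, df_r)

    if method == "exhaustive":
        if math.factorial(n) > 40320:
            raise ValidationError("exhaustive mode limited to n <= 8 specimens")
        p = _permutation_p(Yr, idx, df_c, df_r, F_obs, 0, seed, exhaustive=True)
        n_perm_used = math.factorial(n)
    elif method == "sampled":
        p = _permutation_p(Yr, idx, df_c, df_r, F_obs, n_perm, seed)
        n_perm_used = n_perm
    else:
        raise ValidationError(f"unknown method {method!r}")

    return {
        "pseudo_F": F_obs,
        "p_value": p,
        "df": (df_c, df_r),
        "n_perm": n_perm_used,
        "constrained_inertia": constrained,
        "conditional_inertia": conditional,
        "residual_inertia": residual,
        "total_inertia": total,
        "groups": labels,
    }


# ---------------------------------------------------------------------------
# within-population variance and its age trend
# ---------------------------------------------------------------------------


def within_variance(
    values: np.ndarray,
    population: np.ndarray | list,
    age_group: np.ndarray | list,
) -> pd.DataFrame:
    """Within-cell multivariate variance per (population, age group).

    Defined through pairwise squared Euclidean distances,
    Σ_{i<j} d²_ij / (n (n-1)), which equals the trace of the within-cell
    covariance matrix (sum of per-dimension sample variances).  Cells with
    fewer than two specimens are omitted, mirroring sparse survey designs.
    """
    X = np.asarray(values, dtype=float)
    population = np.asarray(population)
    age_group = np.asarray(age_group)
    if not (X.shape[0] == population.size == age_group.size):
        raise ValidationError("values, population and age_group must align by row")
    rows = []
    for pop in pd.unique(population):
        for ag in pd.unique(age_group[population == pop]):
            if pd.isna(ag):
                continue
            cell = X[(population == pop) & (age_group == ag)]
            if cell.shape[0] < 2:
                continue
            var = float(cell.var(axis=0, ddof=1).sum())
            rows.append({"population_id": str(pop), "age_group": str(ag), "variance": var, "n": cell.shape[0]})
    return pd.DataFrame(rows, columns=["population_id", "age_group", "variance", "n"])


def variance_age_regression(
    dispersion: np.ndarray, age: np.ndarray
) -> tuple[float, float]:
    """OLS slope of a dispersion measure on age, with its t-test p-value.

    ``dispersion`` may be per-cell variances (paired with cell mid-ages) or
    per-specimen distances to the group centroid (paired with specimen
    ages).  Two points give the exact interpolating slope with an undefined
    (NaN) p-value.
    """
    y = np.asarray(dispersion, dtype=float)
    x = np.asarray(age, dtype=float)
    if y.size != x.size or y.size < 2:
        raise ValidationError("need at least two (dispersion, age) pairs")
    if np.unique(x).size < 2:
        raise ValidationError("age is constant; the regression is undefined")
    if y.size == 2:
        slope = float((y[1] - y[0]) / (x[1] - x[0]))
        return slope, float("nan")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)
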