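"""Along-coast geographic distances, shape distances and Mantel tests.

Isolation by distance for coastal populations is judged against distance
*along the coastline*, not straight-line separation: two fjords on either
side of a peninsula are far apart for a herring.  Geographic distances are
therefore accumulated along an ordered waypoint path (southern anchor to
northern anchor), with great-circle segment lengths from the haversine
formula on a spherical Earth of radius 6371.0 km.  Morphological distances
are Euclidean distances between population centroids on the first two
canonical axes (CAP1, CAP2).  The association of the two distance matrices
is tested with a Mantel permutation test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ValidationError, ConfigurationError

__all__ = [
    "DistanceMatrix",
    "EARTH_RADIUS_KM",
    "haversine_km",
    "coastline_distances",
    "shape_distances",
    "mantel_test",
    "idb_report",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with labelled rows/columns."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("distance matrix labels must be unique")
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be exactly zero")
        if np.any(v < 0):
            raise ValidationError("distances must be nonnegative")
        self.values = 0.5 * (v + v.T)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def haversine_km(
    lat1: float, lon1: float, lat2: float, lon2: float, radius: float = EARTH_RADIUS_KM
) -> float:
    """Great-circle distance between two (lat, lon) points in km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2.0 * radius * math.asin(min(1.0, math.sqrt(a)))


def coastline_distances(
    waypoints: np.ndarray,
    populations: pd.DataFrame | None = None,
    anchors: dict[str, int] | None = None,
) -> DistanceMatrix:
    """Along-coast distances (km) between populations anchored on a path.

    ``waypoints`` is an ordered (W, 2) array of (lat, lon) tracing the
    coast.  Populations are pinned to the path either explicitly through
    ``anchors`` (population id -> waypoint index) or by nearest waypoint
    from a ``populations`` frame with columns population_id / latitude /
    longitude.  The distance between two populations is the absolute
    difference of their cumulative arc lengths along the path, which makes
    the metric additive for ordered anchors.
    """
    wp = np.asarray(waypoints, dtype=float)
    if wp.ndim != 2 or wp.shape[1] != 2 or wp.shape[0] < 2:
        raise ValidationError("waypoints must be an ordered (W, 2) lat/lon array, W >= 2")

    seg = np.array(
        [haversine_km(*wp[i], *wp[i + 1]) for i in range(wp.shape[0] - 1)]
    )
    cum = np.concatenate([[0.0], np.cumsum(seg)])

    if anchors is None:
        if populations is None:
            raise ConfigurationError("provide either anchors or a populations table")
        anchors = {}
        for _, row in populations.iterrows():
            d = [
                haversine_km(row["latitude"], row["longitude"], la, lo)
                for la, lo in wp
            ]
            anchors[str(row["population_id"])] = int(np.argmin(d))
    labels = list(anchors)
    missing = [p for p, i in anchors.items() if not (0 <= i < wp.shape[0])]
    if missing:
        raise ConfigurationError(f"populations anchored outside the waypoint range: {missing}")
    pos = np.array([cum[anchors[p]] for p in labels])
    values = np.abs(pos[:, None] - pos[None, :])
    return DistanceMatrix(labels=labels, values=values)


def shape_distances(centroids: pd.DataFrame | np.ndarray, labels=None) -> DistanceMatrix:
    """Pairwise Euclidean distances between population centroids on the
    first two canonical axes.

    ``centroids`` is either a DataFrame indexed by population with CAP
    columns, or an array paired with ``labels``.  Only CAP1 and CAP2 enter
    the distance, matching the convention of summarizing population shape
    by its position in the first two discriminating dimensions.
    """
    if isinstance(centroids, pd.DataFrame):
        labels = list(centroids.index.astype(str))
        arr = centroids.to_numpy(dtype=float)
    else:
        arr = np.asarray(centroids, dtype=float)
        if labels is None:
            raise ValidationError("labels are required with an array of centroids")
        labels = [str(l) for l in labels]
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValidationError(
            "need at least two canonical axes (CAP1, CAP2); run the ordination "
            "with at least three populations so two constrained axes exist"
        )
    if arr.shape[0] < 3:
        raise ValidationError("shape_distances needs at least three populations")
    xy = arr[:, :2]
    diff = xy[:, None, :] - xy[None, :, :]
    values = np.sqrt((diff**2).sum(axis=-1))
    return DistanceMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def _check_aligned(d1: DistanceMatrix, d2: DistanceMatrix) -> None:
    if d1.labels != d2.labels:
        only1 = [l for l in d1.labels if l not in d2.labels]
        only2 = [l for l in d2.labels if l not in d1.labels]
        raise ValidationError(
            "distance matrices are not aligned: "
            f"order1={d1.labels}, order2={d2.labels}, "
            f"only-in-first={only1}, only-in-second={only2}"
        )


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "greater",
    method: str = "auto",
) -> tuple[float, float]:
    """Mantel permutation test of association between two distance matrices.

    r is the Pearson correlation over the n(n-1)/2 upper-triangle pairs.
    The null distribution permutes the labels of one matrix (simultaneous
    row/column shuffles).  ``method="auto"`` enumerates all n! relabelings
    exactly when n! <= 40320 (n <= 8) and samples otherwise; exhaustive
    p-values count the identity, sampled ones use (1 + b)/(1 + n_perm).
    The default alternative is one-sided positive association — the
    isolation-by-distance hypothesis; ``"two-sided"`` compares |r|.
    """
    _check_aligned(d1, d2)
    n = d1.n
    if n < 4:
        raise ValidationError("mantel_test needs at least 4 populations")
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    v2 = d2.values[iu]
    if v1.std() == 0 or v2.std() == 0:
        raise ValidationError("a distance matrix is constant; r is undefined")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])

    if method == "auto":
        method = "exhaustive" if math.factorial(n) <= 40320 else "sampled"

    def perm_r(perm: np.ndarray) -> float:
        vp = d2.values[np.ix_(perm, perm)][iu]
        return float(np.corrcoef(v1, vp)[0, 1])

    def extreme(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs - 1e-12
        if alternative == "two-sided":
            return abs(r_perm) >= abs(r_obs) - 1e-12
        raise ValidationError(f"unknown alternative {alternative!r}")

    if method == "exhaustive":
        count = total = 0
        for perm in itertools.permutations(range(n)):
            count += extreme(perm_r(np.asarray(perm)))
            total += 1
        p = count / total
    elif method == "sampled":
        if n_perm < 99:
            raise ValidationError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            count += extreme(perm_r(rng.permutation(n)))
        p = (1 + count) / (1 + n_perm)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return r_obs, float(p)


def idb_report(
    d_shape: DistanceMatrix, d_geo: DistanceMatrix, regression: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Per-pair isolation-by-distance table with residual outlier flags.

    Regresses shape distance on geographic distance (OLS) and flags pairs
    whose residual exceeds two standard deviations of the residuals — the
    pairs that are more (or less) different than their separation predicts.
    """
    _check_aligned(d_shape, d_geo)
    n = d_shape.n
    iu = np.triu_indices(n, k=1)
    pairs = pd.DataFrame(
        {
            "pop_a": [d_shape.labels[i] for i in iu[0]],
            "pop_b": [d_shape.labels[j] for j in iu[1]],
            "geo_km": d_geo.values[iu],
            "shape_dist": d_shape.values[iu],
        }
    )
    if len(pairs) < 3:
        raise ValidationError("idb_report needs at least 3 population pairs")
    fit: dict = {}
    if regression:
        res = stats.linregress(pairs["geo_km"], pairs["shape_dist"])
        resid = pairs["shape_dist"] - (res.intercept + res.slope * pairs["geo_km"])
        sd = float(resid.std(ddof=1))
        pairs["residual"] = resid
        pairs["outlier"] = np.abs(resid) > 2.0 * sd
        fit = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r": float(res.rvalue),
            "residual_sd": sd,
        }
    return pairs, fit
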