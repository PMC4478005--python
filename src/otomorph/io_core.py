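"""Specimen metadata, coefficient-table and run-configuration I/O.

The interchange format throughout is plain CSV (comma-separated, UTF-8,
mandatory header row).  A specimen table carries one row per fish with its
population assignment, geographic position, total length in cm, scale-read
age in years and a reference to the otolith image.  Wavelet coefficient
matrices are written as a values CSV plus a ``*.meta.csv`` sidecar that
records, for every coefficient column, its decomposition level and the
center angle of its support on the outline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("otomorph")

__all__ = [
    "ValidationError",
    "ConfigurationError",
    "AgeGroup",
    "PAPER_AGE_GROUPS",
    "RunConfig",
    "read_specimen_table",
    "assign_age_groups",
    "write_coefficient_table",
    "read_coefficient_table",
]


class ValidationError(ValueError):
    """Input data violate a documented invariant."""


class ConfigurationError(ValueError):
    """A configuration file, column layout or parameter set is unusable."""


REQUIRED_COLUMNS: tuple[str, ...] = (
    "specimen_id",
    "population_id",
    "latitude",
    "longitude",
    "length_cm",
    "age_years",
    "year",
)
#: recognised but not required
OPTIONAL_COLUMNS: tuple[str, ...] = ("image_path", "rotation_deg")


@dataclass(frozen=True)
class AgeGroup:
    """Inclusive integer age band, e.g. ``AgeGroup("3-5", 3, 5)``."""

    label: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ConfigurationError(
                f"age group {self.label!r}: lo={self.lo} > hi={self.hi}"
            )

    def contains(self, age: int) -> bool:
        return self.lo <= age <= self.hi


#: The standard three-band stratification used for herring: shape differences
#: are confounded with age, so analyses run separately within these bands.
PAPER_AGE_GROUPS: tuple[AgeGroup, ...] = (
    AgeGroup("3-5", 3, 5),
    AgeGroup("6-8", 6, 8),
    AgeGroup("9-12", 9, 12),
)


@dataclass
class RunConfig:
    """Parameters shared by the extraction and analysis stages.

    ``n_angles`` must be a power of two because the dyadic wavelet transform
    operates on vectors of length 2^J.  ``mirror`` optionally flips images of
    one otolith side so left and right sagittae share an orientation; no
    claim is made about which side any particular study used.
    """

    n_angles: int = 512
    wavelet_family: str = "sym10"
    decomposition_levels: int | None = None
    ancova_alpha: float = 0.05
    n_perm_anova: int = 2000
    n_perm_mantel: int = 10000
    rng_seed: int = 0
    threshold_method: str = "otsu"
    mirror: str = "none"

    def __post_init__(self) -> None:
        n = self.n_angles
        if n < 16 or (n & (n - 1)) != 0:
            raise ConfigurationError(f"n_angles must be a power of two >= 16, got {n}")
        if not (0.0 < self.ancova_alpha < 1.0):
            raise ConfigurationError("ancova_alpha must lie in (0, 1)")
        if self.n_perm_anova < 99 or self.n_perm_mantel < 99:
            raise ConfigurationError("permutation counts must be >= 99")
        if self.mirror not in ("none", "left", "right"):
            raise ConfigurationError(f"mirror must be none|left|right, got {self.mirror!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# specimen tables
# ---------------------------------------------------------------------------

_NUMERIC_COLUMNS = ("latitude", "longitude", "length_cm", "age_years", "year")


def read_specimen_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a specimen metadata CSV.

    Raises :class:`ConfigurationError` if a required column is absent and
    :class:`ValidationError` for duplicate specimen ids or unparseable /
    out-of-range values (reported with their 1-based data row numbers).
    Rows with a *missing* length or age are dropped with a log message —
    they cannot enter any statistic — rather than failing the whole file.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ConfigurationError(f"specimen table is missing required column {col!r}")

    out = pd.DataFrame()
    out["specimen_id"] = df["specimen_id"].astype(str).str.strip()
    out["population_id"] = df["population_id"].astype(str).str.strip()

    bad_rows: list[str] = []
    for col in _NUMERIC_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        invalid = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
        for i in df.index[invalid]:
            bad_rows.append(f"row {i + 1}: column {col!r} has value {df.loc[i, col]!r}")
        out[col] = parsed

    # range checks count as type-check failures and name the offending row
    neg_len = out["length_cm"].notna() & (out["length_cm"] <= 0)
    for i in out.index[neg_len]:
        bad_rows.append(f"row {i + 1}: length_cm must be > 0, got {out.loc[i, 'length_cm']}")
    bad_age = out["age_years"].notna() & (
        (out["age_years"] < 1) | (out["age_years"] % 1 != 0)
    )
    for i in out.index[bad_age]:
        bad_rows.append(f"row {i + 1}: age_years must be a positive integer, got {out.loc[i, 'age_years']}")
    if bad_rows:
        raise ValidationError("invalid specimen rows:\n  " + "\n  ".join(bad_rows))

    dupes = out["specimen_id"][out["specimen_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate specimen_id values: {dupes}")

    missing = out["length_cm"].isna() | out["age_years"].isna()
    if missing.any():
        logger.warning(
            "dropping %d specimen(s) with missing length or age: %s",
            int(missing.sum()),
            out.loc[missing, "specimen_id"].tolist(),
        )
        out = out.loc[~missing].reset_index(drop=True)
    out["age_years"] = out["age_years"].astype(int)
    out["year"] = out["year"].astype("Int64")

    for col in OPTIONAL_COLUMNS:
        if col in df.columns:
            out[col] = df.loc[out.index, col]
    return out


def assign_age_groups(
    table: pd.DataFrame, groups: Sequence[AgeGroup] = PAPER_AGE_GROUPS
) -> pd.DataFrame:
    """Return a copy of ``table`` with an ``age_group`` label column.

    Specimens whose age falls outside every group get ``NA`` (excluded).
    Overlapping group definitions are a configuration error.
    """
    gs = list(groups)
    for i, a in enumerate(gs):
        for b in gs[i + 1 :]:
            if a.lo <= b.hi and b.lo <= a.hi:
                raise ConfigurationError(
                    f"age groups {a.label!r} and {b.label!r} overlap"
                )
    out = table.copy()
    labels = pd.array([pd.NA] * len(out), dtype="object")
    ages = out["age_years"].to_numpy()
    for g in gs:
        hit = (ages >= g.lo) & (ages <= g.hi)
        labels[hit] = g.label
    out["age_group"] = labels
    n_excl = int(pd.isna(labels).sum())
    if n_excl:
        logger.info("%d specimen(s) fall outside all age groups and are excluded", n_excl)
    return out


# ---------------------------------------------------------------------------
# coefficient tables
# ---------------------------------------------------------------------------


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.csv")


def write_coefficient_table(matrix, path: str | Path) -> None:
    """Write a :class:`~otomorph.descriptors.CoefficientMatrix` to CSV.

    Produces ``path`` (specimen_id + one column per coefficient, full double
    precision) and a ``*.meta.csv`` sidecar with each coefficient's
    decomposition level and outline center angle.  Non-finite values are
    rejected: coefficients must be computed before they are persisted.
    """
    path = Path(path)
    values = np.asarray(matrix.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("coefficient matrix contains non-finite values")
    cols = [f"c{i:04d}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=cols)
    df.insert(0, "specimen_id", list(matrix.specimen_ids))
    df.to_csv(path, index=False, float_format="%.17g")

    meta = pd.DataFrame(
        {
            "column": cols,
            "level": np.asarray(matrix.coef_level, dtype=int),
            "angle_deg": np.asarray(matrix.coef_angle, dtype=float),
        }
    )
    with open(_meta_path(path), "w", encoding="utf-8") as fh:
        fh.write(f"# family={matrix.family}\n")
        meta.to_csv(fh, index=False, float_format="%.17g")


def read_coefficient_table(path: str | Path):
    """Read back a coefficient table written by :func:`write_coefficient_table`."""
    from .descriptors import CoefficientMatrix  # local import: no cycle at module load

    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "specimen_id" not in df.columns:
        raise ValidationError("coefficient table lacks a specimen_id column")
    family = "sym10"
    mp = _meta_path(path)
    if not mp.exists():
        raise ConfigurationError(f"coefficient sidecar not found: {mp}")
    with open(mp, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# family="):
            family = first.split("=", 1)[1].strip()
        meta = pd.read_csv(fh)
    specimen_ids = df["specimen_id"].astype(str).tolist()
    values = df.drop(columns="specimen_id").to_numpy(dtype=float)
    return CoefficientMatrix(
        values=values,
        coef_angle=meta["angle_deg"].to_numpy(dtype=float),
        coef_level=meta["level"].to_numpy(dtype=int),
        specimen_ids=specimen_ids,
        family=family,
    )
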