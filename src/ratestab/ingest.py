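"""Input parsing, validation, and aggregation to region × age-group counts.

The smoothing engine works on a :class:`CountCube`: observed event counts
``y[i, j]`` and person-years of exposure ``n[i, j]`` for every region ``i``
and age group ``j``.  This module turns the three user-supplied tables
(record-level events, region × age-group populations, and a standard
population) into that cube, with hard validation at every step — silent
coercion of epidemiologic denominators is how wrong maps get published.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "AgeGroupScheme",
    "StandardPopulation",
    "CountCube",
    "parse_age_scheme",
    "bin_age",
    "aggregate",
    "normalize_standard",
    "read_events",
    "read_population",
    "read_standard",
]


class ValidationError(ValueError):
    """Raised when an input table or parameter violates its contract."""


@dataclass(frozen=True)
class AgeGroupScheme:
    """Ordered, contiguous closed-open age brackets ``[lower, upper)``.

    The last bin is open-ended (``upper is None``), matching demographic
    bracket notation: "35–44" means ages 35 through 44 inclusive, i.e. the
    half-open interval [35, 45); "85+" means [85, ∞).
    """

    bins: tuple[tuple[int, int | None], ...]

    def __post_init__(self) -> None:
        if len(self.bins) < 2:
            raise ValidationError(f"need at least 2 age bins, got {len(self.bins)}")
        for k, (lo, hi) in enumerate(self.bins):
            last = k == len(self.bins) - 1
            if lo < 0:
                raise ValidationError(f"bin {k}: negative lower bound {lo}")
            if last:
                if hi is not None:
                    raise ValidationError("last bin must be open-ended")
            else:
                if hi is None or hi <= lo:
                    raise ValidationError(f"bin {k}: empty or inverted interval ({lo}, {hi})")
                nxt = self.bins[k + 1][0]
                if nxt != hi:
                    raise ValidationError(f"bins not contiguous at index {k}: upper {hi} != next lower {nxt}")

    @property
    def n_groups(self) -> int:
        return len(self.bins)

    @property
    def lower_bounds(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.bins])

    @property
    def labels(self) -> tuple[str, ...]:
        """Bracket labels, e.g. ``('35-44', ..., '85+')``."""
        out = []
        for lo, hi in self.bins:
            out.append(f"{lo}+" if hi is None else f"{lo}-{hi - 1}")
        return tuple(out)

    def index_of(self, age: int) -> int:
        return bin_age(age, self)

    def index_of_label(self, label: str) -> int:
        try:
            return self.labels.index(label.strip())
        except ValueError:
            raise ValidationError(
                f"age-group label {label!r} not in scheme {list(self.labels)}"
            ) from None


def parse_age_scheme(boundaries: Sequence[int] | str) -> AgeGroupScheme:
    """Build an :class:`AgeGroupScheme` from strictly increasing boundaries.

    ``boundaries = (b0, b1, ..., bk)`` yields the bins
    ``[b0,b1), [b1,b2), ..., [bk, ∞)`` — one more bin than there are
    internal cut points, the last open-ended.  A comma-separated string
    (CLI form, e.g. ``"0,35,45,65"``) is also accepted.
    """
    if isinstance(boundaries, str):
        try:
            boundaries = [int(tok) for tok in boundaries.split(",") if tok.strip()]
        except ValueError as exc:
            raise ValidationError(f"malformed age boundaries: {exc}") from None
    bounds = [int(b) for b in boundaries]
    if len(bounds) < 2:
        raise ValidationError("need at least 2 boundaries to form 2 bins")
    for a, b in zip(bounds, bounds[1:]):
        if b <= a:
            raise ValidationError(f"boundaries must be strictly increasing: {a} then {b}")
    bins: list[tuple[int, int | None]] = [
        (lo, hi) for lo, hi in zip(bounds, bounds[1:])
    ]
    bins.append((bounds[-1], None))
    return AgeGroupScheme(tuple(bins))


def bin_age(age: int, scheme: AgeGroupScheme) -> int:
    """Return the index ``j`` of the bin with ``lower_j <= age < upper_j``."""
    age = int(age)
    lowers = scheme.lower_bounds
    if age < lowers[0]:
        raise ValidationError(f"age {age} below the scheme's lowest bound {lowers[0]}")
    return int(np.searchsorted(lowers, age, side="right") - 1)


@dataclass(frozen=True)
class StandardPopulation:
    """Normalized standard-population age weights ``w[j]`` (sum to 1)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size < 1:
            raise ValidationError("weights must be a 1-d vector")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValidationError("weights must be finite and non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(f"weights must sum to 1, got {w.sum():.6g}")


def normalize_standard(counts: Sequence[float] | np.ndarray) -> StandardPopulation:
    """Turn raw standard-population counts into weights ``w[j] = c_j / Σc``."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.size < 1:
        raise ValidationError("standard-population counts must be a 1-d vector")
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValidationError("standard-population counts must be finite and >= 0")
    total = c.sum()
    if total <= 0:
        raise ValidationError("standard-population counts are all zero")
    return StandardPopulation(c / total)


@dataclass(frozen=True)
class CountCube:
    """Events ``y[i, j]`` and person-years ``n[i, j]`` per region × age group."""

    region_ids: tuple[str, ...]
    scheme: AgeGroupScheme
    y: np.ndarray = field(repr=False)
    n: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        n = np.asarray(self.n, dtype=float)
        if y.shape != n.shape or y.ndim != 2:
            raise ValidationError(f"y {y.shape} and n {n.shape} must be identical 2-d shapes")
        if y.shape != (len(self.region_ids), self.scheme.n_groups):
            raise ValidationError(
                f"cube shape {y.shape} != (regions {len(self.region_ids)}, groups {self.scheme.n_groups})"
            )
        if not np.issubdtype(y.dtype, np.integer):
            yi = np.rint(y).astype(np.int64)
            if not np.allclose(y, yi):
                raise ValidationError("event counts must be integer-valued")
            y = yi
        if np.any(y < 0):
            raise ValidationError("event counts must be non-negative")
        if np.any(n <= 0) or not np.all(np.isfinite(n)):
            raise ValidationError("person-years must be strictly positive and finite")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValidationError("duplicate region ids")
        object.__setattr__(self, "region_ids", tuple(str(r) for r in self.region_ids))
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "n", n)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_groups(self) -> int:
        return self.scheme.n_groups

    def crude_rates(self) -> np.ndarray:
        """Cell-level crude rates ``y / n`` (events per person-year)."""
        return self.y / self.n


def aggregate(
    events: pd.DataFrame,
    population: pd.DataFrame,
    scheme: AgeGroupScheme,
    observation_years: float = 1.0,
) -> CountCube:
    """Aggregate record-level events onto the population table's grid.

    ``events`` needs columns ``region_id`` and ``age``; ``population`` needs
    ``region_id``, ``age_group`` (scheme labels) and ``population``.
    Person-years are ``population × observation_years``.  Regions present in
    the population table but with no events are kept with ``y = 0``; events
    in regions absent from the population table are an error.
    """
    if observation_years <= 0:
        raise ValidationError(f"observation_years must be > 0, got {observation_years}")
    for col in ("region_id", "age_group", "population"):
        if col not in population.columns:
            raise ValidationError(f"population table missing column {col!r}")

    pop = population.copy()
    pop["region_id"] = pop["region_id"].astype(str)
    region_ids = tuple(sorted(pop["region_id"].unique()))
    J = scheme.n_groups

    dup = pop.duplicated(subset=["region_id", "age_group"])
    if dup.any():
        pairs = pop.loc[dup, ["region_id", "age_group"]].itertuples(index=False)
        raise ValidationError(
            "duplicate population rows for: " + ", ".join(f"({r}, {g})" for r, g in pairs)
        )

    n = np.zeros((len(region_ids), J))
    seen = np.zeros((len(region_ids), J), dtype=bool)
    ridx = {r: i for i, r in enumerate(region_ids)}
    for row in pop.itertuples(index=False):
        j = scheme.index_of_label(str(row.age_group))
        p = float(row.population)
        if not np.isfinite(p) or p <= 0:
            raise ValidationError(f"non-positive population for ({row.region_id}, {row.age_group}): {p}")
        n[ridx[row.region_id], j] = p * observation_years
        seen[ridx[row.region_id], j] = True
    if not seen.all():
        i, j = np.argwhere(~seen)[0]
        raise ValidationError(
            f"population table not rectangular: missing ({region_ids[i]}, {scheme.labels[j]})"
        )

    for col in ("region_id", "age"):
        if col not in events.columns:
            raise ValidationError(f"event table missing column {col!r}")
    y = np.zeros((len(region_ids), J), dtype=np.int64)
    if len(events):
        ev_region = events["region_id"].astype(str)
        unknown = sorted(set(ev_region) - set(region_ids))
        if unknown:
            raise ValidationError(f"events reference regions not in the population table: {unknown}")
        ages = pd.to_numeric(events["age"], errors="coerce")
        bad = ages.isna() | (ages < scheme.lower_bounds[0])
        if bad.any():
            rows = list(events.index[bad][:5])
            raise ValidationError(f"event ages out of range at rows {rows}")
        i_idx = ev_region.map(ridx).to_numpy()
        j_idx = np.searchsorted(scheme.lower_bounds, ages.to_numpy(), side="right") - 1
        np.add.at(y, (i_idx, j_idx), 1)
    assert int(y.sum()) == len(events)
    return CountCube(region_ids=region_ids, scheme=scheme, y=y, n=n)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read the record-level events CSV (``region_id,age``; extras ignored)."""
    df = pd.read_csv(path, dtype={"region_id": str})
    for col in ("region_id", "age"):
        if col not in df.columns:
            raise ValidationError(f"events file {path}: missing column {col!r}")
    extra = [c for c in df.columns if c not in ("region_id", "age")]
    if extra:
        logger.warning("events file %s: ignoring extra columns %s", path, extra)
    if df["region_id"].isna().any() or (df["region_id"].astype(str).str.len() == 0).any():
        raise ValidationError(f"events file {path}: empty region_id values")
    return df[["region_id", "age"]]


def read_population(path: str | Path) -> pd.DataFrame:
    """Read the region × age-group population CSV."""
    df = pd.read_csv(path, dtype={"region_id": str, "age_group": str})
    for col in ("region_id", "age_group", "population"):
        if col not in df.columns:
            raise ValidationError(f"population file {path}: missing column {col!r}")
    return df


def read_standard(path: str | Path, scheme: AgeGroupScheme) -> StandardPopulation:
    """Read the standard-population CSV and normalize to weights.

    Rows must cover every age group of ``scheme`` exactly once, in any order.
    """
    df = pd.read_csv(path, dtype={"age_group": str})
    for col in ("age_group", "population"):
        if col not in df.columns:
            raise ValidationError(f"standard-population file {path}: missing column {col!r}")
    counts = np.full(scheme.n_groups, np.nan)
    for row in df.itertuples(index=False):
        j = scheme.index_of_label(str(row.age_group))
        if not np.isnan(counts[j]):
            raise ValidationError(f"standard-population file {path}: duplicate group {row.age_group}")
        counts[j] = float(row.population)
    if np.isnan(counts).any():
        missing = [scheme.labels[j] for j in np.flatnonzero(np.isnan(counts))]
        raise ValidationError(f"standard-population file {path}: missing groups {missing}")
    return normalize_standard(counts)
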