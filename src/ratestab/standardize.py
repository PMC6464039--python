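"""Age-standardized rates with Monte-Carlo credible intervals and alerts.

A region's directly age-standardized rate is the weighted average of its
age-specific rates, ``R_i = Σ_j w_j θ_ij``, with weights from a standard
population's age distribution.  Rather than approximating the variance of
this weighted average analytically, uncertainty is propagated by sampling:
``θ_ij`` is drawn from each age group's gamma posterior (the posteriors
factorize across age groups) and the weighted sums form the Monte-Carlo
posterior of ``R_i``, summarized by its mean and the empirical 2.5/97.5
percentiles.

Two screens are applied to each region:

* reliability — an estimate is *unreliable* when its 95% credible interval
  is wider than the estimate itself;
* significance — a region is *higher*/*lower* than a reference rate when
  its interval lies entirely above/below that reference (an interval too
  wide to be reliable can still sit entirely below the reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .adjacency import NeighborhoodDictionary
from .ingest import CountCube, StandardPopulation, ValidationError
from .smoothing import EmpiricalBayesSmoother, GammaPosterior

__all__ = [
    "StandardizedPosterior",
    "RegionEstimate",
    "crude_standardized",
    "standardized_posterior",
    "classify_reliability",
    "combine_alerts",
    "classify_vs_reference",
    "RateStabilizer",
]

ALERT_NONE = "none"
ALERT_NONSPATIAL = "unreliable_nonspatial"
ALERT_SPATIAL = "unreliable_spatial"
ALERT_BOTH = "unreliable_both"


@dataclass(frozen=True)
class StandardizedPosterior:
    """Monte-Carlo posterior of one region's age-standardized rate."""

    draws: np.ndarray
    point_estimate: float
    ci: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo <= self.point_estimate <= hi):
            raise ValidationError(
                f"inconsistent standardized posterior: mean {self.point_estimate} outside CI ({lo}, {hi})"
            )
        if np.any(np.asarray(self.draws) < 0):
            raise ValidationError("standardized-rate draws must be non-negative")


@dataclass(frozen=True)
class RegionEstimate:
    """One output record: rates on the display scale, alert, significance."""

    region_id: str
    crude_std_rate: float
    ns_rate: float | None
    ns_lo: float | None
    ns_hi: float | None
    sp_rate: float | None
    sp_lo: float | None
    sp_hi: float | None
    alert: str
    ns_vs_ref: str | None
    sp_vs_ref: str | None


def crude_standardized(cube: CountCube, std: StandardPopulation) -> np.ndarray:
    """Unsmoothed directly standardized rates, ``R_i = Σ_j w_j (y_ij / n_ij)``."""
    if std.weights.shape != (cube.n_groups,):
        raise ValidationError(
            f"standard weights length {std.weights.size} != {cube.n_groups} age groups"
        )
    return cube.crude_rates() @ std.weights


def standardized_posterior(
    posteriors: Sequence[GammaPosterior] | GammaPosterior,
    std: StandardPopulation,
    n_draws: int = 10_000,
    random_state: int | np.random.Generator | None = None,
) -> StandardizedPosterior:
    """Monte-Carlo age-standardized posterior for a single region.

    ``posteriors`` holds one scalar gamma posterior per age group (either a
    sequence of scalar :class:`GammaPosterior` objects or one vector-valued
    posterior of length ``n_groups``).  Draws are
    ``r_s = Σ_j w_j θ_j^(s)`` with the ``θ_j`` sampled independently.
    """
    if isinstance(posteriors, GammaPosterior):
        shapes = np.atleast_1d(posteriors.shape)
        rates = np.atleast_1d(posteriors.rate)
    else:
        shapes = np.array([float(np.asarray(p.shape)) for p in posteriors])
        rates = np.array([float(np.asarray(p.rate)) for p in posteriors])
    if shapes.size != std.weights.size:
        raise ValidationError(
            f"got {shapes.size} age-group posteriors for {std.weights.size} weights"
        )
    if n_draws < 1000:
        raise ValidationError(f"n_draws must be >= 1000 for stable tail percentiles, got {n_draws}")
    rng = np.random.default_rng(random_state)
    theta = rng.gamma(shapes, 1.0 / rates, size=(n_draws, shapes.size))
    draws = theta @ std.weights
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return StandardizedPosterior(draws=draws, point_estimate=float(draws.mean()), ci=(float(lo), float(hi)))


def _standardized_draws(
    post: GammaPosterior, weights: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized standardized-rate draws for all regions, shape (n_draws, R).

    Accumulates one age group at a time to keep memory at
    O(n_draws × n_regions) regardless of the number of age groups.
    """
    R, J = post.shape.shape
    acc = np.zeros((n_draws, R))
    for j in range(J):
        acc += weights[j] * rng.gamma(post.shape[:, j], 1.0 / post.rate[:, j], size=(n_draws, R))
    return acc


def classify_reliability(estimate: float, ci: tuple[float, float]) -> bool:
    """True (unreliable) iff the interval width exceeds the estimate."""
    lo, hi = ci
    if hi < lo:
        raise ValidationError(f"invalid interval ({lo}, {hi})")
    return (hi - lo) > estimate


def combine_alerts(ns_unreliable: bool, sp_unreliable: bool) -> str:
    """Map the two per-method reliability flags to the output alert code."""
    if ns_unreliable and sp_unreliable:
        return ALERT_BOTH
    if ns_unreliable:
        return ALERT_NONSPATIAL
    if sp_unreliable:
        return ALERT_SPATIAL
    return ALERT_NONE


def classify_vs_reference(ci: tuple[float, float], reference: float) -> str:
    """'higher' / 'lower' / 'not_different' by whether the CI excludes the reference."""
    lo, hi = ci
    if hi < lo:
        raise ValidationError(f"invalid interval ({lo}, {hi})")
    if reference <= 0:
        raise ValidationError(f"reference rate must be positive, got {reference}")
    if lo > reference:
        return "higher"
    if hi < reference:
        return "lower"
    return "not_different"


class RateStabilizer(BaseEstimator):
    """Smoothed, age-standardized rates with credible intervals and alerts.

    The full pipeline in estimator form: fit empirical-Bayes posteriors for
    the requested smoothing method(s), propagate them to age-standardized
    rates by Monte Carlo, and classify each region's reliability and its
    position relative to the domain reference rate.

    Parameters
    ----------
    standard : StandardPopulation or 1-d array
        Standard-population age weights (raw counts are normalized).
    method : {"both", "nonspatial", "spatial"}
    adjacency : NeighborhoodDictionary, optional
        Required when the spatial method runs.
    prior_weight : float, array, or None
        Prior strength in person-years; None = median regional exposure per
        age group.
    n_draws : int
        Monte-Carlo sample size per region (>= 1000).
    random_state : int
        Seed for the draws; fixed seed gives bit-identical output.
    scale : float
        Display scale for rates (default per 100,000 person-years).
    level : float
        Credible level (default 0.95).

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per region: crude/nonspatial/spatial standardized rates,
        interval bounds (display scale), alert and significance classes.
    estimates_ : list of RegionEstimate
    reference_rate_ : float
        Domain crude age-standardized rate (display scale) used for the
        significance classification.
    smoothers_ : dict mapping method name to fitted EmpiricalBayesSmoother
    """

    _METHODS = ("nonspatial", "spatial", "both")

    def __init__(
        self,
        standard: StandardPopulation | np.ndarray | None = None,
        method: str = "both",
        adjacency: NeighborhoodDictionary | None = None,
        prior_weight: float | np.ndarray | None = None,
        n_draws: int = 10_000,
        random_state: int = 42,
        scale: float = 100_000.0,
        level: float = 0.95,
    ) -> None:
        self.standard = standard
        self.method = method
        self.adjacency = adjacency
        self.prior_weight = prior_weight
        self.n_draws = n_draws
        self.random_state = random_state
        self.scale = scale
        self.level = level

    def _resolve_standard(self, cube: CountCube) -> StandardPopulation:
        if self.standard is None:
            raise ValidationError("standard population weights are required")
        if isinstance(self.standard, StandardPopulation):
            std = self.standard
        else:
            w = np.asarray(self.standard, dtype=float)
            std = StandardPopulation(w / w.sum())
        if std.weights.size != cube.n_groups:
            raise ValidationError(
                f"standard weights length {std.weights.size} != {cube.n_groups} age groups"
            )
        return std

    def fit(self, X: CountCube, y=None) -> "RateStabilizer":
        if not isinstance(X, CountCube):
            raise ValidationError("RateStabilizer.fit expects a CountCube")
        if self.method not in self._METHODS:
            raise ValidationError(f"method must be one of {self._METHODS}, got {self.method!r}")
        if self.scale <= 0:
            raise ValidationError(f"scale must be positive, got {self.scale}")
        std = self._resolve_standard(X)
        run_ns = self.method in ("nonspatial", "both")
        run_sp = self.method in ("spatial", "both")

        crude = crude_standardized(X, std) * self.scale
        # reference = crude age-standardized rate of the pooled domain
        pooled = X.y.sum(axis=0) / X.n.sum(axis=0)
        self.reference_rate_ = float(pooled @ std.weights * self.scale)

        self.smoothers_ = {}
        per_method: dict[str, dict[str, np.ndarray]] = {}
        tail = 100.0 * (1.0 - self.level) / 2.0
        rng = np.random.default_rng(self.random_state)
        for name, strategy, run in (
            ("nonspatial", "global", run_ns),
            ("spatial", "neighborhood", run_sp),
        ):
            if not run:
                continue
            sm = EmpiricalBayesSmoother(
                strategy=strategy, adjacency=self.adjacency, prior_weight=self.prior_weight
            ).fit(X)
            self.smoothers_[name] = sm
            draws = _standardized_draws(sm.posterior_, std.weights, int(self.n_draws), rng)
            lo, hi = np.percentile(draws, [tail, 100.0 - tail], axis=0)
            per_method[name] = {
                "rate": draws.mean(axis=0) * self.scale,
                "lo": lo * self.scale,
                "hi": hi * self.scale,
            }

        estimates: list[RegionEstimate] = []
        for i, rid in enumerate(X.region_ids):
            fields: dict[str, float | None] = {
                "ns_rate": None, "ns_lo": None, "ns_hi": None,
                "sp_rate": None, "sp_lo": None, "sp_hi": None,
            }
            flags: dict[str, bool] = {}
            classes: dict[str, str | None] = {"ns_vs_ref": None, "sp_vs_ref": None}
            for name, pre in (("nonspatial", "ns"), ("spatial", "sp")):
                if name not in per_method:
                    continue
                r = float(per_method[name]["rate"][i])
                lo = float(per_method[name]["lo"][i])
                hi = float(per_method[name]["hi"][i])
                fields[f"{pre}_rate"], fields[f"{pre}_lo"], fields[f"{pre}_hi"] = r, lo, hi
                flags[name] = classify_reliability(r, (lo, hi))
                classes[f"{pre}_vs_ref"] = classify_vs_reference((lo, hi), self.reference_rate_)
            alert = combine_alerts(flags.get("nonspatial", False), flags.get("spatial", False))
            estimates.append(
                RegionEstimate(
                    region_id=rid,
                    crude_std_rate=float(crude[i]),
                    alert=alert,
                    ns_vs_ref=classes["ns_vs_ref"],
                    sp_vs_ref=classes["sp_vs_ref"],
                    **fields,  # type: ignore[arg-type]
                )
            )
        self.estimates_ = estimates
        self.results_ = pd.DataFrame([vars(e) for e in estimates])
        return self
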