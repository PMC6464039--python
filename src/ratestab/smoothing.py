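"""Conjugate Poisson-gamma empirical-Bayes smoothing of age-specific rates.

Model, per region ``i`` and age group ``j``::

    y_ij | theta_ij ~ Poisson(n_ij * theta_ij)
    theta_ij        ~ Gamma(alpha_ij, beta_ij)      (rate parameterization)

with the prior centered on a smoothing target ``t_ij`` and carrying the
information of ``m_j`` person-years: ``alpha_ij = t_ij * m_j``,
``beta_ij = m_j``.  Conjugacy gives the closed-form posterior
``Gamma(y_ij + alpha_ij, n_ij + beta_ij)`` whose mean is the familiar
shrinkage-weighted average of the crude rate ``y/n`` and the target ``t``.

Two target choices are offered:

* ``"global"`` (nonspatial): every region is shrunk toward the pooled rate
  of the whole spatial domain, per age group.
* ``"neighborhood"`` (spatial): each region is shrunk toward the crude rate
  of its combined contiguity neighbors (the focal region excluded), with a
  fallback to the global rate for islands or event-free neighborhoods.

The degree of smoothing is predetermined, not estimated: ``m_j`` defaults to
the median regional person-years in age group ``j``, so the prior counts as
much as one typical region's worth of exposure and its strength scales
appropriately with each age group's denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .adjacency import NeighborhoodDictionary
from .ingest import CountCube, ValidationError

__all__ = [
    "GammaPrior",
    "GammaPosterior",
    "global_rates",
    "neighborhood_rates",
    "make_prior",
    "posterior_update",
    "posterior_interval",
    "EmpiricalBayesSmoother",
]


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior on rates; mean = shape/rate = smoothing target."""

    shape: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.shape, dtype=float)
        b = np.asarray(self.rate, dtype=float)
        if a.shape != b.shape:
            raise ValidationError("prior shape and rate arrays must have identical shapes")
        if np.any(a <= 0) or np.any(b <= 0) or not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValidationError("prior shape and rate must be strictly positive and finite")
        object.__setattr__(self, "shape", a)
        object.__setattr__(self, "rate", b)

    @property
    def mean(self) -> np.ndarray:
        return self.shape / self.rate


@dataclass(frozen=True)
class GammaPosterior:
    """Gamma(shape, rate) posterior: shape = y + alpha, rate = n + beta."""

    shape: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.shape, dtype=float)
        b = np.asarray(self.rate, dtype=float)
        if a.shape != b.shape:
            raise ValidationError("posterior shape and rate arrays must have identical shapes")
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValidationError("posterior shape and rate must be strictly positive")
        object.__setattr__(self, "shape", a)
        object.__setattr__(self, "rate", b)

    @property
    def mean(self) -> np.ndarray:
        return self.shape / self.rate

    def interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        return posterior_interval(self, level)

    def sample(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Draws of shape ``(n_draws, *self.shape.shape)``."""
        return rng.gamma(self.shape, 1.0 / self.rate, size=(n_draws, *np.shape(self.shape)))


def global_rates(cube: CountCube) -> np.ndarray:
    """Pooled per-age-group rate of the whole domain, ``r_j = Σ_i y_ij / Σ_i n_ij``."""
    return cube.y.sum(axis=0) / cube.n.sum(axis=0)


def _zero_fallback_rates(cube: CountCube) -> np.ndarray:
    """Global rates with zero entries replaced by a half-event pseudo-rate.

    A gamma prior cannot have mean 0, so an age group with no events anywhere
    gets the continuity-corrected target ``0.5 / Σ_i n_ij``.
    """
    r = global_rates(cube)
    total_n = cube.n.sum(axis=0)
    return np.where(r > 0, r, 0.5 / total_n)


def neighborhood_rates(cube: CountCube, nd: NeighborhoodDictionary) -> np.ndarray:
    """Spatial smoothing targets: pooled crude rate of each region's neighbors.

    ``t_ij = Σ_{k in N(i)} y_kj / Σ_{k in N(i)} n_kj``, the focal region
    excluded from its own target.  Islands (empty neighbor sets) and
    neighborhoods whose pooled events are zero in an age group fall back to
    the domain's global rate for that group (itself continuity-corrected if
    zero).
    """
    missing = [rid for rid in cube.region_ids if rid not in nd]
    if missing:
        raise ValidationError(f"regions missing from the neighborhood dictionary: {missing}")
    fallback = _zero_fallback_rates(cube)
    ridx = {rid: i for i, rid in enumerate(cube.region_ids)}
    t = np.empty((cube.n_regions, cube.n_groups))
    for i, rid in enumerate(cube.region_ids):
        kk = [ridx[k] for k in nd[rid] if k in ridx]
        if not kk:
            t[i] = fallback
            continue
        y_nbr = cube.y[kk].sum(axis=0)
        n_nbr = cube.n[kk].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(n_nbr > 0, y_nbr / np.where(n_nbr > 0, n_nbr, 1.0), 0.0)
        t[i] = np.where((n_nbr > 0) & (y_nbr > 0), rate, fallback)
    return t


def make_prior(target: np.ndarray, prior_weight: np.ndarray | float) -> GammaPrior:
    """Prior centered at ``target`` with the strength of ``prior_weight`` person-years.

    ``alpha = target * m`` and ``beta = m``, so the prior mean equals the
    target exactly and the posterior treats the prior as ``m`` person-years
    of exposure observed at the target rate.
    """
    t = np.asarray(target, dtype=float)
    m = np.broadcast_to(np.asarray(prior_weight, dtype=float), t.shape)
    if np.any(t <= 0):
        raise ValidationError("smoothing target must be strictly positive (apply zero fallback first)")
    if np.any(m <= 0):
        raise ValidationError("prior weight must be strictly positive")
    return GammaPrior(shape=t * m, rate=m.copy())


def posterior_update(y: np.ndarray, n: np.ndarray, prior: GammaPrior) -> GammaPosterior:
    """Conjugate update: ``Gamma(y + alpha, n + beta)``."""
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(y < 0):
        raise ValidationError("event counts must be non-negative")
    if np.any(n <= 0):
        raise ValidationError("person-years must be strictly positive")
    return GammaPosterior(shape=y + prior.shape, rate=n + prior.rate)


def posterior_interval(post: GammaPosterior, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Equal-tailed credible interval of the gamma posterior, in rate units."""
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0
    lo = stats.gamma.ppf(tail, post.shape, scale=1.0 / post.rate)
    hi = stats.gamma.ppf(1.0 - tail, post.shape, scale=1.0 / post.rate)
    return lo, hi


class EmpiricalBayesSmoother(BaseEstimator):
    """Empirical-Bayes smoother for region × age-group event rates.

    Parameters
    ----------
    strategy : {"global", "neighborhood"}
        Smoothing target: the domain's pooled rate per age group
        (nonspatial) or the pooled crude rate of each region's contiguity
        neighbors (spatial).
    adjacency : NeighborhoodDictionary, optional
        Required when ``strategy="neighborhood"``.
    prior_weight : float, array of shape (n_groups,), or None
        Prior strength in person-years.  ``None`` (default) uses the median
        over regions of ``n[i, j]`` per age group, so the prior carries one
        typical region's worth of information.

    Attributes
    ----------
    target_rate_ : ndarray of shape (n_regions, n_groups)
        The smoothing target each cell is shrunk toward.
    prior_weight_ : ndarray of shape (n_groups,)
        Resolved prior strength per age group.
    prior_ : GammaPrior
    posterior_ : GammaPosterior
    region_ids_ : tuple of str

    Examples
    --------
    >>> sm = EmpiricalBayesSmoother().fit(cube)          # doctest: +SKIP
    >>> sm.posterior_.mean                               # doctest: +SKIP
    """

    def __init__(
        self,
        strategy: str = "global",
        adjacency: NeighborhoodDictionary | None = None,
        prior_weight: float | np.ndarray | None = None,
    ) -> None:
        self.strategy = strategy
        self.adjacency = adjacency
        self.prior_weight = prior_weight

    def fit(self, X: CountCube, y=None) -> "EmpiricalBayesSmoother":
        """Compute priors and conjugate posteriors from a :class:`CountCube`."""
        if not isinstance(X, CountCube):
            raise ValidationError("EmpiricalBayesSmoother.fit expects a CountCube")
        if self.strategy not in ("global", "neighborhood"):
            raise ValidationError(f"unknown strategy {self.strategy!r}")

        if self.strategy == "neighborhood":
            if self.adjacency is None:
                raise ValidationError("strategy='neighborhood' requires an adjacency dictionary")
            target = neighborhood_rates(X, self.adjacency)
        else:
            target = np.broadcast_to(_zero_fallback_rates(X), X.y.shape).copy()

        if self.prior_weight is None:
            m = np.median(X.n, axis=0)
        else:
            m = np.broadcast_to(np.asarray(self.prior_weight, dtype=float), (X.n_groups,)).copy()
        if np.any(m <= 0):
            raise ValidationError("prior_weight must be strictly positive")

        self.region_ids_ = X.region_ids
        self.target_rate_ = target
        self.prior_weight_ = m
        self.prior_ = make_prior(target, m[np.newaxis, :])
        self.posterior_ = posterior_update(X.y, X.n, self.prior_)
        return self

    def posterior_mean(self) -> np.ndarray:
        """Smoothed rate estimates, events per person-year, shape (R, J)."""
        self._check_fitted()
        return self.posterior_.mean

    def posterior_interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        self._check_fitted()
        return posterior_interval(self.posterior_, level)

    def sample(self, n_draws: int, random_state: int | np.random.Generator | None = None) -> np.ndarray:
        """Posterior draws of shape ``(n_draws, n_regions, n_groups)``."""
        self._check_fitted()
        rng = np.random.default_rng(random_state)
        return self.posterior_.sample(n_draws, rng)

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise ValidationError("this EmpiricalBayesSmoother instance is not fitted yet")
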