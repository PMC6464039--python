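"""Simulation harness: rMSE and coverage of smoothed standardized rates.

The study design: fix a lattice of regions with known ("true") age-specific
rates and exposures, repeatedly simulate Poisson event counts, run the three
estimators of the age-standardized rate (unsmoothed, nonspatially smoothed,
spatially smoothed) on every replicate, and score them by

* per-region root mean square error against the true standardized rate
  ``T_i = Σ_j w_j λ_ij``, and
* pooled coverage of the 95% credible intervals over region × replicate
  pairs (plus per-region coverage for diagnostics).

The synthetic truth emulates chronic-disease mortality: age-specific base
rates rising two orders of magnitude across six age brackets (35–44 up to
85+), modulated per region by a smooth spatial gradient — so the spatial
smoother has genuine neighborhood signal — plus independent lognormal
region effects, with heterogeneous exposures drawn log-uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adjacency import NeighborhoodDictionary, build_adjacency, grid_geometries
from .ingest import AgeGroupScheme, CountCube, StandardPopulation, ValidationError, parse_age_scheme
from .smoothing import EmpiricalBayesSmoother
from .standardize import _standardized_draws

__all__ = [
    "SimulationScenario",
    "SimulationResult",
    "make_scenario",
    "simulate_counts",
    "run_study",
    "DEFAULT_AGE_BOUNDARIES",
    "DEFAULT_BASE_RATES",
    "DEFAULT_STANDARD_COUNTS",
]

#: six-bracket adult age structure: 35-44, 45-54, 55-64, 65-74, 75-84, 85+
DEFAULT_AGE_BOUNDARIES = (35, 45, 55, 65, 75, 85)

#: heart-disease-like age-specific death rates, events per person-year
DEFAULT_BASE_RATES = (1e-4, 4e-4, 1.2e-3, 3.5e-3, 9e-3, 2e-2)

#: US 2000 standard million, brackets 35-44 ... 85+
DEFAULT_STANDARD_COUNTS = (162613.0, 134834.0, 87247.0, 66037.0, 44842.0, 15508.0)

_SCN_STREAM, _COUNT_STREAM, _DRAW_STREAM = 0, 1, 2


@dataclass(frozen=True)
class SimulationScenario:
    """Fixed synthetic truth for one simulation study."""

    rows: int
    cols: int
    region_ids: tuple[str, ...]
    true_rates: np.ndarray = field(repr=False)   # λ[i, j], events per person-year
    person_years: np.ndarray = field(repr=False)  # n[i, j]
    scheme: AgeGroupScheme
    standard: StandardPopulation
    adjacency: NeighborhoodDictionary
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError(f"need at least 2 replicates, got {self.n_replicates}")
        if np.any(self.true_rates < 0):
            raise ValidationError("true rates must be non-negative")
        if np.any(self.person_years <= 0):
            raise ValidationError("person-years must be positive")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def true_standardized(self) -> np.ndarray:
        """``T_i = Σ_j w_j λ_ij`` per region."""
        return self.true_rates @ self.standard.weights


@dataclass(frozen=True)
class SimulationResult:
    """Scores of the three estimators over one study."""

    region_ids: tuple[str, ...]
    rmse: dict[str, np.ndarray]             # per-region, by method
    coverage: dict[str, float]              # pooled over regions × replicates
    coverage_by_region: dict[str, np.ndarray]
    n_replicates: int

    def mean_rmse(self) -> dict[str, float]:
        return {m: float(v.mean()) for m, v in self.rmse.items()}

    def summary(self) -> dict[str, dict[str, float]]:
        return {"mean_rmse": self.mean_rmse(), "coverage": dict(self.coverage)}


def make_scenario(
    rows: int = 10,
    cols: int = 10,
    population_range: tuple[float, float] = (500.0, 50_000.0),
    n_replicates: int = 100,
    seed: int = 42,
    base_rates: tuple[float, ...] = DEFAULT_BASE_RATES,
    age_boundaries: tuple[int, ...] = DEFAULT_AGE_BOUNDARIES,
    standard_counts: tuple[float, ...] = DEFAULT_STANDARD_COUNTS,
    gradient: float = 0.3,
    noise_sd: float = 0.05,
) -> SimulationScenario:
    """Build the default synthetic study scenario.

    True rates are ``λ_ij = base_j · exp(gradient · (u_i − ½) + ε_i)`` where
    ``u_i ∈ [0, 1]`` runs along the grid diagonal (the smooth spatial trend,
    ±gradient/2 on the log scale) and ``ε_i ~ N(0, noise_sd²)`` is an
    unstructured region effect shared across age groups — so within every
    region the age gradient of the base rates is preserved.  Person-years
    are log-uniform over ``population_range`` independently per cell.
    """
    if rows < 2 or cols < 2:
        raise ValidationError(f"grid must be at least 2x2, got {rows}x{cols}")
    lo, hi = population_range
    if lo <= 0 or hi < lo:
        raise ValidationError(f"invalid population range {population_range}")
    base = np.asarray(base_rates, dtype=float)
    scheme = parse_age_scheme(age_boundaries)
    if base.size != scheme.n_groups:
        raise ValidationError(
            f"{base.size} base rates for {scheme.n_groups} age groups"
        )
    std = StandardPopulation(np.asarray(standard_counts) / np.sum(standard_counts))
    if std.weights.size != scheme.n_groups:
        raise ValidationError("standard counts must match the age scheme")

    geoms = grid_geometries(rows, cols)
    region_ids = tuple(sorted(geoms))
    nd = build_adjacency(geoms, rule="queen")

    rng = np.random.default_rng(np.random.SeedSequence((seed, _SCN_STREAM)))
    R = rows * cols
    rr = np.array([int(rid[1:3]) for rid in region_ids])
    cc = np.array([int(rid[4:6]) for rid in region_ids])
    u = (rr / (rows - 1) + cc / (cols - 1)) / 2.0
    eps = rng.normal(0.0, noise_sd, size=R)
    region_effect = np.exp(gradient * (u - 0.5) + eps)
    lam = region_effect[:, None] * base[None, :]

    n = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(R, scheme.n_groups)))

    return SimulationScenario(
        rows=rows,
        cols=cols,
        region_ids=region_ids,
        true_rates=lam,
        person_years=n,
        scheme=scheme,
        standard=std,
        adjacency=nd,
        n_replicates=n_replicates,
        seed=seed,
    )


def simulate_counts(scn: SimulationScenario, replicate: int) -> CountCube:
    """One replicate dataset: ``y_ij ~ Poisson(n_ij · λ_ij)`` independently."""
    rng = np.random.default_rng(np.random.SeedSequence((scn.seed, _COUNT_STREAM, replicate)))
    y = rng.poisson(scn.person_years * scn.true_rates)
    return CountCube(region_ids=scn.region_ids, scheme=scn.scheme, y=y, n=scn.person_years)


def run_study(
    scn: SimulationScenario,
    n_draws: int = 10_000,
    prior_weight: float | np.ndarray | None = None,
    level: float = 0.95,
) -> SimulationResult:
    """Run the full replicate study and score the three estimators.

    For every replicate: the unsmoothed estimate is the crude directly
    standardized rate; the two smoothed estimates and their credible
    intervals come from ``n_draws`` Monte-Carlo draws of the standardized
    rate under each method's gamma posteriors.
    """
    truth = scn.true_standardized()
    w = scn.standard.weights
    tail = 100.0 * (1.0 - level) / 2.0
    methods = ("unsmoothed", "nonspatial", "spatial")
    sq_err = {m: np.zeros(scn.n_regions) for m in methods}
    hits = {m: np.zeros(scn.n_regions) for m in ("nonspatial", "spatial")}

    for rep in range(scn.n_replicates):
        cube = simulate_counts(scn, rep)
        crude = cube.crude_rates() @ w
        sq_err["unsmoothed"] += (crude - truth) ** 2

        rng = np.random.default_rng(np.random.SeedSequence((scn.seed, _DRAW_STREAM, rep)))
        for method, strategy in (("nonspatial", "global"), ("spatial", "neighborhood")):
            sm = EmpiricalBayesSmoother(
                strategy=strategy,
                adjacency=scn.adjacency if strategy == "neighborhood" else None,
                prior_weight=prior_weight,
            ).fit(cube)
            draws = _standardized_draws(sm.posterior_, w, n_draws, rng)
            est = draws.mean(axis=0)
            lo, hi = np.percentile(draws, [tail, 100.0 - tail], axis=0)
            sq_err[method] += (est - truth) ** 2
            hits[method] += (lo <= truth) & (truth <= hi)

    rmse = {m: np.sqrt(v / scn.n_replicates) for m, v in sq_err.items()}
    cov_region = {m: v / scn.n_replicates for m, v in hits.items()}
    coverage = {m: float(v.mean()) for m, v in cov_region.items()}
    return SimulationResult(
        region_ids=scn.region_ids,
        rmse=rmse,
        coverage=coverage,
        coverage_by_region=cov_region,
        n_replicates=scn.n_replicates,
    )
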