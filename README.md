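# ratestab

Stable small-area event rates. `ratestab` takes record-level health events
(e.g. deaths), region × age-group populations, a standard population, and
region boundaries, and produces **age-standardized rates with 95% credible
intervals** for every region — stabilized by empirical-Bayes smoothing so
that census tracts, rural counties, or any other geography with few events
get usable estimates instead of noise. It is written for epidemiologists
and public-health analysts doing chronic-disease surveillance at
sub-county scales.

## The model

Events in region *i* and age group *j* are Poisson counts over exposure
*n<sub>ij</sub>* person-years:

```
y_ij | θ_ij ~ Poisson(n_ij · θ_ij)
θ_ij        ~ Gamma(α_ij, β_ij)        α_ij = t_ij · m_j ,  β_ij = m_j
```

The conjugate gamma prior is centered on a smoothing target *t<sub>ij</sub>*
and carries the information of *m<sub>j</sub>* person-years. Two targets are
offered:

- **nonspatial** — the pooled rate of the whole domain per age group,
  *t<sub>ij</sub> = Σ<sub>i</sub> y<sub>ij</sub> / Σ<sub>i</sub> n<sub>ij</sub>*;
- **spatial** — the pooled crude rate of region *i*'s contiguity neighbors
  (queen or rook adjacency, built from polygons), the focal region excluded.

Conjugacy gives the closed-form posterior Gamma(y<sub>ij</sub> + α<sub>ij</sub>,
n<sub>ij</sub> + β<sub>ij</sub>), whose mean is the shrinkage-weighted average

```
E[θ_ij | y] = (n_ij · (y_ij/n_ij) + m_j · t_ij) / (n_ij + m_j).
```

The age-standardized rate *R<sub>i</sub> = Σ<sub>j</sub> w<sub>j</sub> θ<sub>ij</sub>*
(weights *w<sub>j</sub>* from a standard population) is summarized by Monte
Carlo: sample each θ<sub>ij</sub> from its posterior, form the weighted sums,
and take the mean and the empirical 2.5/97.5 percentiles. Each region is
then screened twice: an estimate is flagged **unreliable** when its 95%
interval is wider than the estimate itself, and classified
**higher/lower/not different** than the domain's crude standardized rate by
whether the interval excludes it.

## Worked example

Generate a synthetic 4×4-region dataset and smooth it:

```sh
rst fixture --seed 1 --size 4x4 --out demo
rst smooth --events demo/events.csv --population demo/population.csv \
    --standard demo/standard.csv --geometry demo/grid.geojson \
    --ages 35,45,55,65,75,85 --method both --seed 42 --out demo/results.csv
```

The run logs `reference rate: 224.5 (per 100000)` — the domain's crude
age-standardized rate — and writes one record per region:

```
region_id,crude_std_rate,ns_rate,ns_lo,ns_hi,sp_rate,sp_lo,sp_hi,alert,ns_vs_ref,sp_vs_ref
r00c00,155.2,200,170.3,234.5,192.2,164.2,225.4,none,not_different,not_different
r00c01,200.2,209.6,186.9,233.4,208.9,186,233,none,not_different,not_different
```

Region `r00c00`'s crude standardized rate (155.2 per 100,000) is based on
few events; the nonspatial smoother pulls it toward the domain rate (200.0,
CI 170.3–234.5) and the spatial smoother toward its neighbors (192.2, CI
164.2–225.4). The interval widths (≈ 64 and 61) are well below the
estimates, so no reliability alert fires, and every interval here contains
the reference rate. Data-poor configurations produce
`unreliable_nonspatial` / `unreliable_spatial` / `unreliable_both` alerts
and `higher` / `lower` significance calls instead.

The simulation study that quantifies the benefit of smoothing runs as:

```sh
rst simulate --grid 6x6 --replicates 25 --draws 2000 --seed 7 --out demo/study
```

which printed (units: events per person-year):

```
mean_rmse: unsmoothed 2.67e-4, nonspatial 1.15e-4, spatial 1.01e-4
coverage:  nonspatial 0.968, spatial 0.993
```

— the smoothed estimators cut the root mean square error against the known
true standardized rates by more than half, while their credible intervals
cover the truth at or slightly above the nominal 95%.

As a library the same pipeline is a scikit-learn-style estimator:

```python
from ratestab import RateStabilizer
model = RateStabilizer(standard=std, adjacency=nbrs, method="both").fit(cube)
model.results_          # DataFrame: rates, CIs, alerts per region
model.reference_rate_   # domain crude standardized rate
```

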