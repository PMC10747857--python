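# soilrisk

Monte Carlo uncertainty propagation for soil heavy-metal(loid) pollution
assessment, probabilistic human-health risk, and geographic-detector
driving-factor analysis.

Regional soil surveys report point concentrations of Cr, Cd, As, Pb and
Hg; regulators grade them with the Nemerow index, assess human exposure
with USEPA dose models, and attribute spatial patterns to environmental
drivers with the geographic detector. Each of those steps inherits
uncertainty — from sampling-point positions and concentrations, from
exposure-variable variability, and from the arbitrary category
boundaries imposed on continuous covariates. `soilrisk` implements the
whole chain with the uncertainty propagated explicitly, and ships a
synthetic-data generator with known statistical structure so every stage
is testable without restricted survey data.

## Models

**Pollution indexing.** Single-factor index `Pi = Ci / Si` (measured
concentration over the pH-banded screening value) and the Nemerow
composite `Pn = sqrt((Pave² + Pmax²)/2)`, graded into five classes
(unpolluted / warning / low / medium / high). Positions are perturbed
`N(x, 10 m)` and concentrations redrawn from lognormals specified by
their (50th, 95th) percentiles; each iteration is re-interpolated by IDW
and re-graded, and per-cell uncertainty is the Shannon entropy
`H = −Σ Pi ln Pi` of the grade distribution. Crossing risk with entropy
yields a four-way control-zoning map (LR-LU … HR-HU).

**Health risk.** Ingestion and dermal doses
`ADD = CS·IR·EF·ED/(BW·AT)·10⁻⁶` (dermal with `AF·SA·ABS` replacing
`IR`), hazard quotients `HQ = Σ ADD/RfD`, hazard index `HI = Σ HQ`,
carcinogenic risks `CR = Σ ADD·SF`, `TCR = Σ CR`. The probabilistic
driver redraws CS, IRing, ED, AF, SA and BW per iteration (5000
iterations, last 3000 kept by default) and reports cumulative
distributions and exceedance probabilities against the HQ/HI > 1 and
CR/TCR > 10⁻⁶, 10⁻⁴ thresholds.

**Geographic detector.** Factor detector
`q = 1 − SSW/SST = 1 − Σ Nh·σh² / (N·σ²)` with population variances;
permutation significance; interaction detector on the overlay of two
factors with the five-way enhancement/weakening taxonomy; and optimal
discretization (equal-interval / quantile / natural-breaks × class
count) maximizing q. Category-boundary uncertainty is propagated by
stochastically re-assigning each raster cell from inverse-distance
category weights in its 5×5 neighborhood and re-running the detectors
(100 runs by default), summarized as per-factor and per-pair q standard
deviations.

## Worked example

```python
from soilrisk import SamplePoint, StrataData, factor_q, pollution_at_points
from soilrisk.config import (load_grade_scheme, load_screening_standard,
                             load_toxicity_table, load_exposure_parameters)
from soilrisk.health_risk import run_probabilistic_risk
from soilrisk.synthetic import (StudyRegion, default_concentration_specs,
                                generate_factor_raster,
                                generate_response_with_known_q)

std = load_screening_standard()
pt = SamplePoint(x=1000.0, y=2000.0,
                 conc={"Cr": 90.0, "Cd": 0.45, "As": 30.0, "Pb": 60.0, "Hg": 0.2},
                 ph=6.0)
(res,) = pollution_at_points([pt], std, load_grade_scheme())
print("Pi:", {k: round(v, 3) for k, v in res.pi.items()})
print(f"Pn = {res.pn:.3f}  grade = {res.grade}")

region = StudyRegion()                     # 100 x 100 km at 1 km cells
strata = generate_factor_raster(region, 8, "voronoi", seed=1)
y = generate_response_with_known_q(strata, 0.6, seed=2)
print(f"factor q = {factor_q(StrataData(y, strata.values.ravel())).q:.3f}")

s = run_probabilistic_risk(default_concentration_specs(),
                           load_exposure_parameters("child"),
                           load_toxicity_table(),
                           n_iter=5000, n_keep=3000, seed=7)
print(f"child mean HI = {s.means['HI']:.2f}   P(HI > 1) = {s.exceedance[('HI', 1.0)]:.2f}")
```

prints

```
Pi: {'As': 0.75, 'Cd': 1.5, 'Cr': 0.6, 'Hg': 0.111, 'Pb': 0.667}
Pn = 1.178  grade = low
factor q = 0.597
child mean HI = 2.27   P(HI > 1) = 0.74
```

The sample's Cd exceeds its screening value (Pi = 1.5), pulling the
Nemerow composite to 1.18 — the "low pollution" grade. The synthetic
response built to have 60 % of its variance explained by the factor map
recovers q ≈ 0.6, and the child cohort's simulated hazard index exceeds
the safety threshold in 74 % of Monte Carlo iterations.

A full synthetic pipeline (points → pollution → risk → detectors →
uncertainty maps) runs from the command line:

```sh
soilrisk all --seed 1 --out-dir out/
```

writing points/pollution CSVs, Pn/entropy/zoning ASCII grids, factor and
interaction q tables, and detector-uncertainty samples. Screening
values, grade breakpoints, toxicity data and exposure distributions are
editable YAML (see `src/soilrisk/data/`).

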