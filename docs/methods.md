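# Methods

## Scope and data model

`soilrisk` propagates three sources of uncertainty through a regional
soil heavy-metal(loid) assessment: (i) measurement error in sampling
positions and concentrations, through Nemerow pollution mapping;
(ii) exposure-variable variability, through USEPA health-risk indices;
(iii) category-boundary ambiguity of discretized covariates, through the
geographic detector. Inputs are point samples (projected meters,
mg/kg concentrations, pH) and categorical/continuous rasters; all grids
are upper-left-origin, row-major, cell-center evaluated, read and
written as ESRI ASCII grids (a plain-text format that round-trips values,
georeferencing and nodata exactly).

## Distributions

Concentration distributions are lognormals specified by their (50th,
95th) percentiles, the form these parameters are usually tabulated in:
the underlying normal has `mu = ln(p50)` and
`sigma = (ln p95 − ln p50)/z`, `z = 1.6449` (the standard-normal 95th
deviate). `p50 = p95` degenerates to a point mass. Defaults (mg/kg):
Cr (9.7, 67.6), Cd (9.9, 78.0), As (12.6, 82.7), Pb (10.1, 71.0),
Hg (10.8, 72.3). The pH default (1.9, 4.6) is implemented exactly as
tabled in the same form even though the (50th, 95th) reading implies a
lower median than typical field soil pH (≈5.8); it is overridable
wherever a realistic pH matters, and the screening-standard pH bands
make the effect explicit. Positional error is Normal(coordinate, 10 m)
per axis. Elements are sampled independently — only marginals are
specified, no copula.

## Pollution indexing and its Monte Carlo chain

`Pi = Ci/Si` with Si from a pH-banded screening table (GB 15618-2018
style defaults for non-paddy agricultural land; every value editable
YAML since regulatory tables vary by land use). `Pn = sqrt((Pave² +
Pmax²)/2)`; grading uses half-open intervals `[b_k, b_{k+1})` on breaks
0.7 / 1 / 2 / 3 (canonical five-level Nemerow breakpoints) — a Pn
exactly at a break belongs to the higher class.

The mapping chain per iteration: perturb positions and redraw
concentrations, IDW-interpolate each element and pH onto the analysis
grid (power 2, 12 neighbors by default — conventional choices, both
exposed), form per-cell Pi/Pn, grade. IDW uses cell centers, a
`k`-nearest query via a KD-tree, and an exact-hit rule at 10⁻⁹ m to
avoid division by zero. Iterations are seeded independently from
`(seed, iteration)`, so the keep-last-K convention (default keep 3000
of 5000) is implemented by evaluating only the kept iterations —
bit-identical to computing and discarding the rest, since this is plain
Monte Carlo with no chain state.

Per-cell uncertainty is Shannon entropy over the M grade counts,
`H = −Σ p_i ln p_i` (natural log; base-2 flag for bits), `0·ln 0 = 0`;
H = 0 iff one grade always wins, maximum ln M at uniformity. Entropy is
computed over the grade classes, not finer Pn bins, because the decision
variable downstream (zoning) is the grade. Control zoning crosses a risk
threshold (default: modal grade at least "low pollution", i.e. Pn ≥ 1)
with an entropy threshold (default: median over valid cells) into
LR-LU / LR-HU / HR-LU / HR-HU.

## Health risk

Ingestion and dermal pathways only. `ADD_ing = CS·IRing·EF·ED/(BW·AT)·
10⁻⁶`; `ADD_dermal` substitutes `AF·SA·ABS` for `IRing`. AT couples to
the endpoint: `ED·365` days for non-carcinogenic, `70·365` for
carcinogenic — standard USEPA convention, stated explicitly because the
dose formulas alone leave it open. HQ sums dose/RfD over pathways; a
nonzero dose with a missing RfD is an error (silently dropping it would
understate hazard), whereas a missing slope factor contributes zero CR
(no carcinogenicity evidence is the usual reading of an absent SF).

The probabilistic driver treats CS, IRing, ED, AF, SA, BW as stochastic
and EF, ABS as fixed; defaults are triangular distributions bracketing
conventional USEPA central values (editable YAML; adult/child cohorts).
All variables are independent. Outputs per index: sorted kept samples
(cumulative curves), means, quantiles, and exceedance probabilities at
HQ, HI > 1 and CR, TCR > 10⁻⁶, 10⁻⁴.

With all-lognormal inputs the log-dose is a sum of normals, so the
geometric mean of ADD has a closed form (product/quotient of input
geometric means × 10⁻⁶); the test suite uses this as an independent
check of the simulation.

## Geographic detector

`q = 1 − Σ_h N_h σ_h² / (N σ²)` with population (divide-by-N) variances,
so the variance-sum and SSW/SST forms coincide exactly; q is clamped
only against negative round-off at the 10⁻¹⁶ level. Significance is a
label-permutation test, `p = (1 + #{q_perm ≥ q_obs})/(1 + n_perm)`
(default 999): assumption-free and directly testable for type-I error,
preferred over the noncentral-F derivation whose use cannot be verified
here. The interaction detector computes q on the ordered-pair overlay;
the taxonomy is the standard five-way rule set (nonlinear/univariate
weaken, bivariate/nonlinear enhance, independent within tolerance
10⁻⁶). An overlay that shatters into singletons returns q = 1 with a
warning — it is uninformative, not wrong.

Optimal discretization scans equal-interval, quantile and 1-D
variance-minimizing ("natural breaks", via k-means with fixed
`random_state`) binnings over a class-count range (default 2–8, capped
at 15) and returns the q-argmax; ties prefer fewer classes, then the
method order listed. Observations with nodata in response or factor are
dropped pairwise.

## Classification-boundary perturbation

For each cell, category weights over its 5×5 window:
`D = Euclidean distance in cell units + 1` (the +1 applies to every
pixel including the center, which therefore carries the largest single
weight), `W = (1/D)` normalized over all valid window pixels, and
`C_k = Σ W` over pixels of category k, so `Σ_k C_k = 1`. The cell's new
label is drawn once per cell per run: `[0,1)` is partitioned into
consecutive intervals of length `C_k` in ascending label order and a
uniform draw selects the interval — the reading under which the weights
form a probability distribution. Border cells truncate the window and
renormalize. Homogeneous rasters are fixed points; the label set never
grows. Detector uncertainty repeats perturb-and-detect (default 100
runs; factor seeds derived per run and factor) and reports q sample
vectors and standard deviations for factors and pairs.

## Synthetic data

Positions are uniform over the study polygon (field sampling patterns
are a collection protocol, not a spatial law worth emulating); the
default region is a 100 × 100 km rectangle at 1 km cells. Factor rasters
are Voronoi tessellations of random seed cells (or rectangular strips),
guaranteeing contiguous, nonempty categories. Known-q responses assign
each stratum a Normal effect rescaled so the realized between-stratum
population variance equals the target, plus `N(0, sqrt(1 − target))`
noise, making the expected variance ratio the target exactly; a
noise-free path yields q = 1. What the generator does **not** emulate:
spatial autocorrelation of concentrations, inter-element correlation,
multi-depth sampling, or realistic covariate geometry — so passing tests
demonstrate correctness of the estimators and propagation machinery, not
calibration to any real region's field statistics.

## Problem sizes and numerics

Default demo/pipeline scale is 1000 points on a 50 × 50 grid with 50
pollution-MC iterations and 20 detector runs — enough for every
invariant to be exercised while keeping a full run near interactive
speed; the statistical checks use 10⁵ draws (distribution percentiles,
positional SD), 10⁴ cells (q recovery within ±0.05) and 10⁴ random
instances (q bounds/oracle agreement at 10⁻¹²). Degenerate inputs are
errors, not silent results: constant responses (SST = 0), empty
polygons, all-nodata neighborhoods, malformed pH bands. All stochastic
code takes explicit seeds; per-stage and per-iteration seeds are derived
from a single global seed, and identical seeds give bit-identical
outputs.

## Known limitations

- No kriging or variogram-based interpolation; IDW only, one projected
  CRS assumed.
- Inhalation exposure, Bayesian estimation, and land-use-specific
  exposure scenarios are out of scope, as are the geo-accumulation and
  potential-ecological-risk indices and the risk/ecological detectors.
- Health-risk uncertainty is non-spatial (per-cohort distributions, not
  maps).
- Default screening, toxicity and exposure values are conventional
  stand-ins meant to be replaced with jurisdiction-specific tables.
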