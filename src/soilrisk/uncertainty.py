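"""Monte Carlo uncertainty propagation drivers.

Three propagation chains are covered:

1. *Pollution mapping* — sampling-point positions and concentrations are
   perturbed per iteration (positions Normal(original, sigma), sigma
   defaulting to 10 m; concentrations redrawn from their element
   distributions), the per-element surfaces re-interpolated by IDW, the
   Nemerow index recomputed per cell and graded; the per-cell spread of
   grades over iterations is summarised by Shannon information entropy
   H = -sum_i P_i ln P_i (0 for a certain outcome, ln M at the uniform
   maximum over M grades).

2. *Classification-boundary perturbation* — each cell of a categorical
   factor raster is stochastically re-assigned using inverse-distance
   category weights from its (default 5 x 5) neighborhood:
   D = Euclidean cell distance + 1 (the +1 also applies to the center,
   avoiding division by zero), W = (1/D) normalised over all valid
   neighborhood pixels, and C_k = the summed W of category k, so that
   sum_k C_k = 1.  A uniform draw against the cumulative C_k intervals
   (ascending label order) picks the new label.

3. *Geo-detector uncertainty* — the factor and interaction detectors are
   re-run on repeatedly perturbed factor rasters; per-factor and
   per-pair q standard deviations quantify how sensitive the detector is
   to the category boundaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, sample
from .geodetector import StrataData, factor_q, interaction_q
from .pollution import GradeScheme, ScreeningStandard, nemerow_index
from .spatial import RasterLayer, idw_interpolate
from .synthetic import SamplePoint, StudyRegion

__all__ = [
    "PerturbationConfig",
    "ClassDistribution",
    "NeighborhoodWeights",
    "perturb_points",
    "pollution_mcs",
    "information_entropy",
    "control_zoning",
    "neighborhood_weights",
    "perturb_classification",
    "gdm_uncertainty",
    "GdmUncertaintyResult",
]


@dataclass
class PerturbationConfig:
    """Settings for the position/concentration perturbation chain.

    ``position_sigma`` is the standard deviation (m) of the Normal
    positional error applied to each coordinate; concentrations are
    redrawn from ``concentration_specs`` (elements absent from the map
    keep their observed values).
    """

    n_iter: int = 5000
    n_keep: int = 3000
    position_sigma: float = 10.0
    concentration_specs: Mapping[str, DistributionSpec] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_keep <= self.n_iter):
            raise ValueError("require 0 < n_keep <= n_iter")
        if self.position_sigma < 0:
            raise ValueError("position_sigma must be >= 0")


def perturb_points(
    points: Sequence[SamplePoint], cfg: PerturbationConfig, iteration: int
) -> List[SamplePoint]:
    """One Monte Carlo realisation of the sampling points.

    Deterministic given ``(cfg.seed, iteration)``: each coordinate is
    drawn Normal(original, position_sigma) and each concentration with a
    spec is redrawn from it; pH is left untouched.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, iteration)))
    n = len(points)
    dx = rng.normal(0.0, cfg.position_sigma, n) if cfg.position_sigma > 0 else np.zeros(n)
    dy = rng.normal(0.0, cfg.position_sigma, n) if cfg.position_sigma > 0 else np.zeros(n)
    new_conc = {
        el: sample(spec, n, rng) for el, spec in cfg.concentration_specs.items()
    }
    out = []
    for i, p in enumerate(points):
        conc = {
            el: float(new_conc[el][i]) if el in new_conc else c
            for el, c in p.conc.items()
        }
        out.append(
            SamplePoint(x=p.x + float(dx[i]), y=p.y + float(dy[i]), conc=conc, ph=p.ph)
        )
    return out


@dataclass
class ClassDistribution:
    """Per-cell outcome-class counts across kept iterations.

    ``counts`` has shape (M, nrows, ncols); ``labels`` are the M class
    names in counting order.  Valid cells have counts summing to
    ``n_keep``; all-zero cells are treated as nodata downstream.
    """

    counts: np.ndarray
    labels: Tuple[str, ...]
    grid: RasterLayer
    n_keep: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape[0] != len(self.labels):
            raise ValueError("counts first axis must match labels")

    @property
    def modal_class_index(self) -> np.ndarray:
        return self.counts.argmax(axis=0)


def _screening_grid(
    standard: ScreeningStandard, element: str, ph: np.ndarray
) -> np.ndarray:
    """Vectorised screening value lookup over a pH array."""
    if element in standard.flat:
        return np.full(ph.shape, standard.flat[element])
    si = np.full(ph.shape, np.nan)
    for (lo, hi), v in standard.bands[element]:
        si[(ph > lo) & (ph <= hi)] = v
    return si


def pollution_mcs(
    points: Sequence[SamplePoint],
    region: StudyRegion,
    standard: ScreeningStandard,
    scheme: GradeScheme,
    cfg: PerturbationConfig,
    power: float = 2.0,
    k_neighbors: int = 12,
    pn_stack_every: int = 0,
) -> Tuple[ClassDistribution, List[RasterLayer]]:
    """Monte Carlo pollution mapping chain.

    Each kept iteration: perturb the points, IDW-interpolate every
    element (and pH, for the banded standard) onto the region grid,
    compute the per-cell Nemerow index, grade it, and accumulate the
    per-cell grade counts.  Iterations are independently seeded, so only
    the kept ones are evaluated; results are identical to computing and
    discarding the burn-in.  ``pn_stack_every`` > 0 additionally retains
    every k-th Pn raster.
    """
    grid = region.empty_raster()
    elements = standard.elements
    counts = np.zeros((len(scheme.labels), region.nrows, region.ncols), dtype=int)
    stack: List[RasterLayer] = []
    first_kept = cfg.n_iter - cfg.n_keep
    for it in range(first_kept, cfg.n_iter):
        try:
            pts = perturb_points(points, cfg, it)
            pi_layers = []
            ph_grid = idw_interpolate(
                [(p.x, p.y, p.ph) for p in pts], grid, power, k_neighbors
            ).values
            for el in elements:
                conc = idw_interpolate(
                    [(p.x, p.y, p.conc[el]) for p in pts], grid, power, k_neighbors
                ).values
                si = _screening_grid(standard, el, ph_grid)
                pi_layers.append(conc / si)
            pi_arr = np.stack(pi_layers)
            p_ave = pi_arr.mean(axis=0)
            p_max = pi_arr.max(axis=0)
            pn = np.sqrt((p_ave**2 + p_max**2) / 2.0)
            grade_idx = scheme.index_of(pn)
            rows, cols = np.indices(pn.shape)
            counts[grade_idx, rows, cols] += 1
            if pn_stack_every and (it - first_kept) % pn_stack_every == 0:
                stack.append(grid.copy_with(pn))
        except Exception as exc:
            raise RuntimeError(f"pollution MC iteration {it} failed") from exc
    dist = ClassDistribution(
        counts=counts, labels=scheme.labels, grid=grid, n_keep=cfg.n_keep
    )
    return dist, stack


def information_entropy(dist: ClassDistribution, base: str = "e") -> RasterLayer:
    """Shannon entropy of the per-cell grade distribution.

    H = -sum_i P_i log P_i with P_i = count_i / n_keep and 0 log 0 = 0;
    natural log by default, ``base="2"`` for bits.  Zero-count cells
    become nodata.
    """
    counts = dist.counts.astype(float)
    total = counts.sum(axis=0)
    valid = total > 0
    p = np.where(counts > 0, counts / np.maximum(total, 1), 1.0)
    log = np.log2 if base == "2" else np.log
    hval = -(np.where(counts > 0, p * log(p), 0.0)).sum(axis=0) + 0.0  # avoid -0.0
    nodata = -9999.0
    out = np.where(valid, hval, nodata)
    return RasterLayer(
        dist.grid.origin, dist.grid.cell_size, out, nodata=nodata, kind="continuous"
    )


ZONE_LABELS = {1: "LR-LU", 2: "LR-HU", 3: "HR-LU", 4: "HR-HU"}


def control_zoning(
    risk: RasterLayer,
    entropy: RasterLayer,
    risk_threshold: float,
    entropy_threshold: float,
) -> RasterLayer:
    """Four-way risk/uncertainty zoning.

    Cells at or above a threshold count as "high"; labels are
    1=LR-LU, 2=LR-HU, 3=HR-LU, 4=HR-HU; nodata where either input is.
    """
    if risk.values.shape != entropy.values.shape or risk.origin != entropy.origin:
        raise ValueError("risk and entropy rasters are not aligned")
    hr = risk.values >= risk_threshold
    hu = entropy.values >= entropy_threshold
    zones = 1 + hu.astype(int) + 2 * hr.astype(int)
    valid = risk.valid_mask & entropy.valid_mask
    zones = np.where(valid, zones, -1)
    return RasterLayer(
        risk.origin, risk.cell_size, zones.astype(int), nodata=-1, kind="categorical"
    )


@dataclass
class NeighborhoodWeights:
    """Inverse-distance category weights of one cell's neighborhood."""

    center: Tuple[int, int]
    ck: Dict[int, float]
    weights: np.ndarray
    distances: np.ndarray


def _window_bounds(i: int, j: int, nrows: int, ncols: int, half: int):
    return (
        max(0, i - half),
        min(nrows, i + half + 1),
        max(0, j - half),
        min(ncols, j + half + 1),
    )


def neighborhood_weights(
    raster: RasterLayer, i: int, j: int, window: int = 5
) -> NeighborhoodWeights:
    """Category weights C_k of cell (i, j)'s window (truncated at borders).

    D = Euclidean distance in cell units + 1 (center's own D = 1);
    W = (1/D) normalised over all valid pixels; C_k sums W by category.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be an odd positive count")
    if not (0 <= i < raster.nrows and 0 <= j < raster.ncols):
        raise ValueError("center cell outside raster")
    half = window // 2
    r0, r1, c0, c1 = _window_bounds(i, j, raster.nrows, raster.ncols, half)
    sub = raster.values[r0:r1, c0:c1]
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = np.sqrt((rr - i) ** 2 + (cc - j) ** 2) + 1.0
    valid = sub != raster.nodata
    if not valid.any():
        raise ValueError("all-nodata neighborhood")
    invd = np.where(valid, 1.0 / dist, 0.0)
    w = invd / invd.sum()
    ck = {
        int(k): float(w[(sub == k) & valid].sum())
        for k in np.unique(sub[valid])
    }
    return NeighborhoodWeights(center=(i, j), ck=ck, weights=w, distances=dist)


def _category_weight_maps(
    raster: RasterLayer, window: int
) -> Tuple[np.ndarray, np.ndarray]:
    """(labels, C) with C shaped (K, nrows, ncols): per-cell category weights.

    Vectorised equivalent of calling :func:`neighborhood_weights` on every
    cell: for each window offset, the inverse-distance contribution is
    shifted and accumulated into the numerator of its cell's category and
    a shared denominator, which handles border truncation exactly.
    """
    half = window // 2
    vals = raster.values
    nrows, ncols = vals.shape
    valid = vals != raster.nodata
    labels = np.unique(vals[valid])
    num = np.zeros((labels.size, nrows, ncols))
    den = np.zeros((nrows, ncols))
    label_idx = np.searchsorted(labels, np.where(valid, vals, labels[0]))
    for di in range(-half, half + 1):
        for dj in range(-half, half + 1):
            invd = 1.0 / (np.hypot(di, dj) + 1.0)
            # source block contributing to destination block at offset (di, dj)
            dst_r0, dst_r1 = max(0, -di), min(nrows, nrows - di)
            dst_c0, dst_c1 = max(0, -dj), min(ncols, ncols - dj)
            src_r0, src_r1 = dst_r0 + di, dst_r1 + di
            src_c0, src_c1 = dst_c0 + dj, dst_c1 + dj
            src_valid = valid[src_r0:src_r1, src_c0:src_c1]
            src_lab = label_idx[src_r0:src_r1, src_c0:src_c1]
            contrib = np.where(src_valid, invd, 0.0)
            den[dst_r0:dst_r1, dst_c0:dst_c1] += contrib
            flat = num[:, dst_r0:dst_r1, dst_c0:dst_c1]
            np.add.at(
                flat,
                (src_lab, *np.indices(src_lab.shape)),
                contrib,
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = num / den
    return labels, C


def perturb_classification(
    raster: RasterLayer, seed: int, window: int = 5
) -> RasterLayer:
    """Stochastically re-assign every cell from its neighborhood weights.

    [0, 1) is partitioned into consecutive intervals of length C_k in
    ascending label order; one uniform draw per cell picks the interval.
    Border cells use the truncated, renormalised window; nodata cells are
    unchanged.  Homogeneous rasters are fixed points.
    """
    if raster.kind != "categorical":
        raise ValueError("perturb_classification needs a categorical raster")
    labels, C = _category_weight_maps(raster, window)
    cum = np.cumsum(C, axis=0)
    cum[-1] = np.maximum(cum[-1], 1.0)  # guard rounding at the top interval
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=raster.values.shape)
    pick = (u[None, ...] < cum).argmax(axis=0)
    new_vals = labels[pick]
    valid = raster.values != raster.nodata
    new_vals = np.where(valid, new_vals, raster.values)
    return raster.copy_with(new_vals.astype(int))


@dataclass
class GdmUncertaintyResult:
    """q samples across perturbation runs, for factors and factor pairs."""

    factor_samples: pd.DataFrame  # runs x factor names
    interaction_samples: pd.DataFrame  # runs x "A*B" pair names

    @property
    def factor_sd(self) -> pd.Series:
        return self.factor_samples.std(ddof=1)

    @property
    def interaction_sd(self) -> pd.Series:
        return self.interaction_samples.std(ddof=1)


def gdm_uncertainty(
    y: np.ndarray,
    factors: Mapping[str, RasterLayer],
    n_runs: int = 100,
    seed: int = 0,
    window: int = 5,
) -> GdmUncertaintyResult:
    """Geo-detector uncertainty under classification-boundary perturbation.

    Each run perturbs every categorical factor raster independently
    (deterministically seeded per run and factor), then recomputes the
    factor q of each factor and the interaction q of each pair against
    the fixed response ``y`` (raveled, NaN = nodata).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    y = np.asarray(y, dtype=float).ravel()
    names = list(factors)
    fac_rows = []
    int_rows = []
    for r in range(n_runs):
        pert = {}
        for fi, name in enumerate(names):
            sub_seed = np.random.SeedSequence((seed, r, fi)).generate_state(1)[0]
            pert[name] = perturb_classification(factors[name], int(sub_seed), window)
        try:
            qrow = {
                name: factor_q(StrataData(y, pert[name].values.ravel())).q
                for name in names
            }
            irow = {
                f"{a}*{b}": interaction_q(
                    y, pert[a].values.ravel(), pert[b].values.ravel()
                ).q12
                for a, b in itertools.combinations(names, 2)
            }
        except Exception as exc:
            raise RuntimeError(f"geo-detector run {r} failed") from exc
        fac_rows.append(qrow)
        int_rows.append(irow)
    return GdmUncertaintyResult(
        factor_samples=pd.DataFrame(fac_rows),
        interaction_samples=pd.DataFrame(int_rows),
    )
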