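"""Synthetic study data with known statistical structure.

Real provincial soil-census data is access-restricted, so every pipeline
stage is exercised on synthetic inputs that emulate its published
statistical description: lognormal concentrations specified by their
(50th, 95th) percentiles, uniformly scattered sampling positions inside a
study polygon, categorical factor rasters with contiguous patches, and
responses whose explained-variance fraction against a stratification
(the geo-detector q) is set by construction.

Default concentration specs (mg/kg, as (p50, p95)): Cr (9.7, 67.6),
Cd (9.9, 78.0), As (12.6, 82.7), Pb (10.1, 71.0), Hg (10.8, 72.3);
pH spec (1.9, 4.6).  The pH row is tabulated in the same (p50, p95)
lognormal form as the metals and is implemented exactly as tabled even
though it implies a lower median than typical field pH; override via
``ph_spec`` where a realistic pH matters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon, box

from .distributions import DistributionSpec, sample
from .spatial import RasterLayer

__all__ = [
    "ELEMENTS",
    "SamplePoint",
    "StudyRegion",
    "default_concentration_specs",
    "default_ph_spec",
    "generate_sample_points",
    "generate_factor_raster",
    "generate_response_with_known_q",
    "points_to_frame",
    "write_points_csv",
    "read_points_csv",
    "write_points_geojson",
]

#: Canonical element order used throughout the package.
ELEMENTS = ("Cr", "Cd", "As", "Pb", "Hg")

_TABLE_SPECS = {
    "Cr": (9.7, 67.6),
    "Cd": (9.9, 78.0),
    "As": (12.6, 82.7),
    "Pb": (10.1, 71.0),
    "Hg": (10.8, 72.3),
}


def default_concentration_specs() -> Dict[str, DistributionSpec]:
    """Lognormal (p50, p95) specs for the five elements, mg/kg."""
    return {
        el: DistributionSpec("lognormal_p50p95", p) for el, p in _TABLE_SPECS.items()
    }


def default_ph_spec() -> DistributionSpec:
    return DistributionSpec("lognormal_p50p95", (1.9, 4.6))


@dataclass
class SamplePoint:
    """One surface-soil sample: position (projected m), concentrations, pH."""

    x: float
    y: float
    conc: Dict[str, float]
    ph: float

    def __post_init__(self) -> None:
        for el, c in self.conc.items():
            if c <= 0:
                raise ValueError(f"concentration of {el} must be > 0, got {c}")
        if not (0 < self.ph <= 14):
            raise ValueError(f"pH must be in (0, 14], got {self.ph}")


@dataclass
class StudyRegion:
    """Study polygon plus the analysis grid covering it.

    Defaults to a 100 km x 100 km rectangle gridded at 1 km resolution.
    """

    polygon: Polygon = field(default_factory=lambda: box(0.0, 0.0, 100_000.0, 100_000.0))
    cell_size: float = 1000.0
    nrows: int = 100
    ncols: int = 100

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")
        if self.polygon.is_empty or self.polygon.area == 0:
            raise ValueError("study polygon is empty")
        minx, miny, maxx, maxy = self.polygon.bounds
        if (self.ncols * self.cell_size < maxx - minx - 1e-9) or (
            self.nrows * self.cell_size < maxy - miny - 1e-9
        ):
            raise ValueError("grid does not cover the polygon bounding box")

    @property
    def origin(self) -> tuple:
        minx, _, _, maxy = self.polygon.bounds
        return (minx, maxy)

    def empty_raster(self, fill: float = np.nan, kind: str = "continuous") -> RasterLayer:
        values = np.full((self.nrows, self.ncols), fill)
        return RasterLayer(self.origin, self.cell_size, values, kind=kind)


def generate_sample_points(
    region: StudyRegion,
    n: int,
    conc_specs: Dict[str, DistributionSpec] | None = None,
    ph_spec: DistributionSpec | None = None,
    seed: int = 0,
) -> List[SamplePoint]:
    """Uniform positions inside the polygon; concentrations drawn per spec.

    Positions are rejection-sampled from the polygon's bounding box;
    concentration vectors are drawn independently per element.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    conc_specs = conc_specs or default_concentration_specs()
    ph_spec = ph_spec or default_ph_spec()
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = region.polygon.bounds

    xs = np.empty(0)
    ys = np.empty(0)
    while xs.size < n:
        m = max(2 * (n - xs.size), 64)
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        keep = contains_xy(region.polygon, cx, cy)
        xs = np.concatenate([xs, cx[keep]])
        ys = np.concatenate([ys, cy[keep]])
    xs, ys = xs[:n], ys[:n]

    conc = {el: sample(spec, n, rng) for el, spec in conc_specs.items()}
    ph = np.clip(sample(ph_spec, n, rng), 1e-6, 14.0)
    return [
        SamplePoint(
            x=float(xs[i]),
            y=float(ys[i]),
            conc={el: float(conc[el][i]) for el in conc},
            ph=float(ph[i]),
        )
        for i in range(n)
    ]


def generate_factor_raster(
    region: StudyRegion,
    n_categories: int,
    pattern: str = "voronoi",
    seed: int = 0,
) -> RasterLayer:
    """Categorical raster with ``n_categories`` contiguous patches.

    ``voronoi`` labels each cell by its nearest random seed cell;
    ``blocks`` slices the grid into parallel rectangular strips.
    Labels are 1..n_categories and every category is nonempty.
    """
    ncells = region.nrows * region.ncols
    if n_categories < 2:
        raise ValueError("n_categories must be >= 2")
    if n_categories > ncells:
        raise ValueError("n_categories exceeds cell count")
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0 : region.nrows, 0 : region.ncols]

    if pattern == "voronoi":
        # distinct seed cells guarantee every category owns at least one cell
        flat = rng.choice(ncells, size=n_categories, replace=False)
        sr, sc = np.unravel_index(flat, (region.nrows, region.ncols))
        d2 = (rows[..., None] - sr) ** 2 + (cols[..., None] - sc) ** 2
        labels = d2.argmin(axis=-1) + 1
    elif pattern == "blocks":
        axis_len = region.nrows if region.nrows >= region.ncols else region.ncols
        if n_categories > axis_len:
            raise ValueError("blocks pattern needs n_categories <= longer grid side")
        edges = np.linspace(0, axis_len, n_categories + 1)
        coord = rows if region.nrows >= region.ncols else cols
        labels = np.digitize(coord, edges[1:-1], right=False) + 1
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    return RasterLayer(
        region.origin,
        region.cell_size,
        labels.astype(int),
        nodata=-1,
        kind="categorical",
    )


def generate_response_with_known_q(
    strata: RasterLayer,
    target_q: float,
    seed: int = 0,
    noise: bool = True,
) -> np.ndarray:
    """Response vector (raveled, row-major) whose q against ``strata`` is known.

    Each stratum receives an effect drawn N(0,1) and rescaled so the
    population-weighted between-stratum variance is exactly ``target_q``;
    i.i.d. N(0, sqrt(1 - target_q)) noise is added per cell, so the
    expected variance ratio tau^2/(tau^2 + sw^2) equals ``target_q``.
    With ``noise=False`` the pure stratum means are returned (q = 1
    whenever at least two stratum means differ).  Nodata cells get NaN.
    """
    if not (0 <= target_q <= 1):
        raise ValueError("target_q must be in [0, 1]")
    if noise and target_q >= 1:
        raise ValueError("target_q = 1 unreachable with noise; use noise=False")
    rng = np.random.default_rng(seed)
    labels = strata.values.ravel()
    valid = strata.valid_mask.ravel()
    uniq = np.unique(labels[valid])
    if target_q > 0 and uniq.size < 2:
        raise ValueError("need >= 2 strata for target_q > 0")

    effects = rng.normal(size=uniq.size)
    idx = np.searchsorted(uniq, labels[valid])
    cell_eff = effects[idx]
    if target_q > 0:
        # rescale so the realized between-stratum population variance = target_q
        var_b = cell_eff.var()
        if var_b == 0:
            raise ValueError("degenerate stratum effects")
        cell_eff = (cell_eff - cell_eff.mean()) * np.sqrt(target_q / var_b)
    else:
        cell_eff = np.zeros_like(cell_eff)

    if noise:
        cell_eff = cell_eff + rng.normal(scale=np.sqrt(1.0 - target_q), size=cell_eff.size)

    out = np.full(labels.size, np.nan)
    out[valid] = cell_eff
    return out


def points_to_frame(points: Sequence[SamplePoint]) -> pd.DataFrame:
    """Tabulate points as columns x, y, Cr, Cd, As, Pb, Hg, pH."""
    elements = list(points[0].conc) if points else list(ELEMENTS)
    rows = [
        {"x": p.x, "y": p.y, **{el: p.conc[el] for el in elements}, "pH": p.ph}
        for p in points
    ]
    return pd.DataFrame(rows, columns=["x", "y", *elements, "pH"])


def write_points_csv(points: Sequence[SamplePoint], path: str | Path) -> None:
    points_to_frame(points).to_csv(path, index=False)


def read_points_csv(path: str | Path) -> List[SamplePoint]:
    df = pd.read_csv(path)
    elements = [c for c in df.columns if c not in ("x", "y", "pH")]
    return [
        SamplePoint(
            x=row["x"],
            y=row["y"],
            conc={el: row[el] for el in elements},
            ph=row["pH"],
        )
        for _, row in df.iterrows()
    ]


def write_points_geojson(points: Sequence[SamplePoint], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
            "properties": {**p.conc, "pH": p.ph},
        }
        for p in points
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
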