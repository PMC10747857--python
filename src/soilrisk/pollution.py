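"""Single-factor and Nemerow composite pollution indices.

The single-factor index of element i is ``Pi = Ci / Si`` — the measured
concentration over its regulatory risk-screening value.  The Nemerow
index combines mean and worst single-factor indices,

    Pn = sqrt((Pave^2 + Pmax^2) / 2),

emphasizing the most polluting element; Pave <= Pn <= Pmax always.
Screening values may be banded by soil pH (GB 15618-2018 style) and are
supplied as editable configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ScreeningStandard",
    "GradeScheme",
    "PollutionResult",
    "single_factor_index",
    "nemerow_index",
    "classify_pollution",
    "pollution_at_points",
    "results_to_frame",
]


class InvalidStandardError(ValueError):
    """Raised for nonpositive screening values or malformed pH bands."""


@dataclass(frozen=True)
class ScreeningStandard:
    """Per-element screening values Si (mg/kg), optionally banded by pH.

    ``bands``: element -> list of ((ph_lo, ph_hi], Si).  Bands must have
    Si > 0 and jointly cover (0, 14].  An element may instead appear in
    ``flat`` with a single pH-independent value.
    """

    bands: Mapping[str, Sequence[Tuple[Tuple[float, float], float]]] = None
    flat: Mapping[str, float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", dict(self.bands or {}))
        object.__setattr__(self, "flat", dict(self.flat or {}))
        for el, si in self.flat.items():
            if si <= 0:
                raise InvalidStandardError(f"screening value for {el} must be > 0")
        for el, entries in self.bands.items():
            entries = sorted(entries, key=lambda e: e[0][0])
            lo = 0.0
            for (b_lo, b_hi), si in entries:
                if si <= 0:
                    raise InvalidStandardError(f"screening value for {el} must be > 0")
                if abs(b_lo - lo) > 1e-9 or b_hi <= b_lo:
                    raise InvalidStandardError(
                        f"pH bands for {el} must partition (0, 14]"
                    )
                lo = b_hi
            if abs(lo - 14.0) > 1e-9:
                raise InvalidStandardError(f"pH bands for {el} must end at 14")

    @property
    def elements(self) -> List[str]:
        return sorted(set(self.flat) | set(self.bands))

    def value(self, element: str, ph: float = 7.0) -> float:
        """Screening value for ``element`` at soil pH ``ph`` (band (lo, hi])."""
        if element in self.flat:
            return self.flat[element]
        if element in self.bands:
            for (b_lo, b_hi), si in self.bands[element]:
                if b_lo < ph <= b_hi:
                    return si
            raise InvalidStandardError(f"pH {ph} outside bands for {element}")
        raise KeyError(f"no screening value for element {element!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreeningStandard":
        """Build from config: {element: Si} or {element: [[lo, hi, Si], ...]}."""
        flat, bands = {}, {}
        for el, v in d.items():
            if isinstance(v, (int, float)):
                flat[el] = float(v)
            else:
                bands[el] = [((float(b[0]), float(b[1])), float(b[2])) for b in v]
        return cls(bands=bands, flat=flat)


@dataclass(frozen=True)
class GradeScheme:
    """Ordered breakpoints on Pn and the class labels of the intervals.

    With breakpoints (b1..bk) the classes are [0,b1), [b1,b2), ...,
    [bk, inf): a Pn exactly at a breakpoint belongs to the higher class.
    """

    breaks: Tuple[float, ...] = (0.7, 1.0, 2.0, 3.0)
    labels: Tuple[str, ...] = ("unpolluted", "warning", "low", "medium", "high")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breaks) + 1:
            raise ValueError("need exactly one more label than breakpoints")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breakpoints must be strictly increasing")

    def index_of(self, pn) -> np.ndarray:
        """0-based class index; vectorized."""
        return np.searchsorted(np.asarray(self.breaks), np.asarray(pn), side="right")


@dataclass
class PollutionResult:
    pi: Dict[str, float]
    p_ave: float
    p_max: float
    pn: float
    grade: str


def single_factor_index(ci: float, si: float):
    """Pi = Ci / Si.  Accepts scalars or arrays; Si must be positive."""
    if np.any(np.asarray(si) <= 0):
        raise InvalidStandardError("screening value Si must be > 0")
    if np.any(np.asarray(ci) < 0):
        raise ValueError("concentration Ci must be >= 0")
    return ci / si


def nemerow_index(pi_values) -> float:
    """Pn = sqrt((Pave^2 + Pmax^2) / 2) over the single-factor indices."""
    pi = np.asarray(pi_values, dtype=float)
    if pi.size == 0:
        raise ValueError("need at least one single-factor index")
    if np.any(pi < 0):
        raise ValueError("single-factor indices must be >= 0")
    p_ave = pi.mean()
    p_max = pi.max()
    return float(np.sqrt((p_ave**2 + p_max**2) / 2.0))


def classify_pollution(pn: float, scheme: GradeScheme = GradeScheme()) -> str:
    """Grade label of the half-open interval containing ``pn``."""
    if pn < 0:
        raise ValueError("Pn must be >= 0")
    return scheme.labels[int(scheme.index_of(pn))]


def pollution_at_points(
    points,
    standard: ScreeningStandard,
    scheme: GradeScheme = GradeScheme(),
) -> List[PollutionResult]:
    """Apply the index chain to each sample, selecting pH-banded standards."""
    results = []
    for k, p in enumerate(points):
        missing = [el for el in standard.elements if el not in p.conc]
        if missing:
            raise KeyError(f"point {k}: missing element(s) {missing}")
        pi = {
            el: float(single_factor_index(p.conc[el], standard.value(el, p.ph)))
            for el in standard.elements
        }
        vals = np.array(list(pi.values()))
        pn = nemerow_index(vals)
        results.append(
            PollutionResult(
                pi=pi,
                p_ave=float(vals.mean()),
                p_max=float(vals.max()),
                pn=pn,
                grade=classify_pollution(pn, scheme),
            )
        )
    return results


def results_to_frame(results: Sequence[PollutionResult]) -> pd.DataFrame:
    """Per-point table: Pi per element, Pave, Pmax, Pn, grade."""
    rows = []
    for k, r in enumerate(results):
        rows.append(
            {
                "point_id": k,
                **{f"Pi_{el}": v for el, v in r.pi.items()},
                "Pave": r.p_ave,
                "Pmax": r.p_max,
                "Pn": r.pn,
                "grade": r.grade,
            }
        )
    return pd.DataFrame(rows)
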