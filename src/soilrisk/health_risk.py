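"""USEPA-style health risk assessment, deterministic and probabilistic.

Exposure doses per pathway (mg per kg body weight per day):

    ADD_ing    = CS * IRing * EF * ED / (BW * AT) * 1e-6
    ADD_dermal = CS * AF * SA * ABS * EF * ED / (BW * AT) * 1e-6

Non-carcinogenic hazard: HQ_i = sum_k ADD_k / RfD_k, HI = sum_i HQ_i.
Carcinogenic risk:       CR_i = sum_k ADD_k * SF_k,  TCR = sum_i CR_i.

Averaging time follows standard practice: AT = ED * 365 days for the
non-carcinogenic chain and 70 * 365 days for the carcinogenic chain.
The probabilistic driver redraws the stochastic exposure variables
(CS, IRing, ED, AF, SA, BW) each Monte Carlo iteration and summarises
the resulting index distributions as sorted samples, means, quantiles
and threshold-exceedance probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, sample

__all__ = [
    "ExposureParameters",
    "ToxicityTable",
    "RiskResult",
    "ProbabilisticRiskSummary",
    "add_ingestion",
    "add_dermal",
    "hazard_quotient",
    "hazard_index",
    "carcinogenic_risk",
    "total_carcinogenic_risk",
    "assess_risk",
    "run_probabilistic_risk",
]

PATHWAYS = ("ingestion", "dermal")

#: Default index thresholds for exceedance reporting: HQ/HI against the
#: safety threshold 1; CR/TCR against the conventional 1e-6 (negligible
#: below) and 1e-4 (unacceptable above) bounds.
DEFAULT_THRESHOLDS: Dict[str, Tuple[float, ...]] = {
    "HQ": (1.0,),
    "HI": (1.0,),
    "CR": (1e-6, 1e-4),
    "TCR": (1e-6, 1e-4),
}

ParamValue = Union[float, DistributionSpec]


@dataclass
class ExposureParameters:
    """Cohort exposure variables; each entry a fixed value or a spec.

    Units: IRing mg/day, EF days/yr, ED yr, BW kg, AF mg/cm^2, SA cm^2,
    ABS dimensionless (0, 1].  AT (days) is derived, not stored.
    """

    cohort: str
    IRing: ParamValue
    EF: ParamValue
    ED: ParamValue
    BW: ParamValue
    AF: ParamValue
    SA: ParamValue
    ABS: ParamValue
    lifetime_years: float = 70.0

    def __post_init__(self) -> None:
        if self.cohort not in ("adult", "child"):
            raise ValueError("cohort must be 'adult' or 'child'")

    def realize(self, n: int, rng: np.random.Generator) -> Dict[str, np.ndarray]:
        """Draw n values of each variable (fixed values are broadcast)."""
        out = {}
        for name in ("IRing", "EF", "ED", "BW", "AF", "SA", "ABS"):
            v = getattr(self, name)
            if isinstance(v, DistributionSpec):
                out[name] = sample(v, n, rng)
            else:
                out[name] = np.full(n, float(v))
            if np.any(out[name] <= 0):
                raise ValueError(f"exposure variable {name} realized non-positive")
        if np.any(out["ABS"] > 1):
            raise ValueError("ABS must be in (0, 1]")
        return out


@dataclass(frozen=True)
class ToxicityTable:
    """RfD (mg/(kg d)) and SF ((kg d)/mg) per element x pathway; None = absent."""

    rfd: Mapping[str, Mapping[str, Optional[float]]]
    sf: Mapping[str, Mapping[str, Optional[float]]]

    def __post_init__(self) -> None:
        for el, per_path in self.rfd.items():
            for path, v in per_path.items():
                if v is not None and v <= 0:
                    raise ValueError(f"RfD[{el}][{path}] must be > 0")
        for el, per_path in self.sf.items():
            for path, v in per_path.items():
                if v is not None and v < 0:
                    raise ValueError(f"SF[{el}][{path}] must be >= 0")

    @property
    def elements(self):
        return sorted(set(self.rfd) | set(self.sf))


@dataclass
class RiskResult:
    """Deterministic per-element doses and indices for one cohort."""

    cohort: str
    add_ing: Dict[str, float]
    add_dermal: Dict[str, float]
    hq: Dict[str, float]
    cr: Dict[str, float]
    hi: float
    tcr: float


def add_ingestion(cs, iring, ef, ed, bw, at):
    """ADD via incidental soil ingestion; all inputs positive."""
    bw, at = np.asarray(bw, dtype=float), np.asarray(at, dtype=float)
    if np.any(bw <= 0) or np.any(at <= 0):
        raise ValueError("BW and AT must be > 0")
    return cs * iring * ef * ed / (bw * at) * 1e-6


def add_dermal(cs, af, sa, abs_, ef, ed, bw, at):
    """ADD via dermal contact with adhered soil."""
    bw, at = np.asarray(bw, dtype=float), np.asarray(at, dtype=float)
    if np.any(bw <= 0) or np.any(at <= 0):
        raise ValueError("BW and AT must be > 0")
    return cs * af * sa * abs_ * ef * ed / (bw * at) * 1e-6


def hazard_quotient(
    doses: Mapping[str, float], rfds: Mapping[str, Optional[float]]
) -> float:
    """HQ = sum over pathways of ADD_k / RfD_k."""
    hq = 0.0
    for path, dose in doses.items():
        rfd = rfds.get(path)
        if rfd is None:
            if np.any(np.asarray(dose) > 0):
                raise ValueError(f"nonzero {path} dose but RfD missing")
            continue
        hq = hq + dose / rfd
    return hq


def hazard_index(hqs) -> float:
    """HI = sum of per-element hazard quotients (0 for the empty set)."""
    return float(np.sum(hqs)) if np.ndim(hqs) <= 1 else np.sum(hqs, axis=0)


def carcinogenic_risk(
    doses: Mapping[str, float], sfs: Mapping[str, Optional[float]]
) -> float:
    """CR = sum of ADD_k * SF_k; pathways without a slope factor add 0."""
    cr = 0.0
    for path, dose in doses.items():
        sf = sfs.get(path)
        if sf is None:
            continue
        if sf < 0:
            raise ValueError("slope factor must be >= 0")
        cr = cr + dose * sf
    return cr


def total_carcinogenic_risk(crs) -> float:
    """TCR = sum of per-element carcinogenic risks."""
    return float(np.sum(crs)) if np.ndim(crs) <= 1 else np.sum(crs, axis=0)


def assess_risk(
    conc: Mapping[str, float],
    exposure: ExposureParameters,
    tox: ToxicityTable,
) -> RiskResult:
    """Deterministic risk chain at fixed parameter values.

    Every exposure entry must be a fixed number (point specs allowed).
    """

    def _fixed(name):
        v = getattr(exposure, name)
        if isinstance(v, DistributionSpec):
            if v.family != "point":
                raise ValueError(f"{name} is stochastic; use run_probabilistic_risk")
            return v.params[0]
        return float(v)

    p = {n: _fixed(n) for n in ("IRing", "EF", "ED", "BW", "AF", "SA", "ABS")}
    at_nc = p["ED"] * 365.0
    at_ca = exposure.lifetime_years * 365.0

    add_ing_, add_derm, hq, cr = {}, {}, {}, {}
    for el in tox.elements:
        cs = conc[el]
        di_nc = add_ingestion(cs, p["IRing"], p["EF"], p["ED"], p["BW"], at_nc)
        dd_nc = add_dermal(cs, p["AF"], p["SA"], p["ABS"], p["EF"], p["ED"], p["BW"], at_nc)
        di_ca = add_ingestion(cs, p["IRing"], p["EF"], p["ED"], p["BW"], at_ca)
        dd_ca = add_dermal(cs, p["AF"], p["SA"], p["ABS"], p["EF"], p["ED"], p["BW"], at_ca)
        add_ing_[el] = float(di_nc)
        add_derm[el] = float(dd_nc)
        hq[el] = float(
            hazard_quotient(
                {"ingestion": di_nc, "dermal": dd_nc}, tox.rfd.get(el, {})
            )
        )
        cr[el] = float(
            carcinogenic_risk(
                {"ingestion": di_ca, "dermal": dd_ca}, tox.sf.get(el, {})
            )
        )
    return RiskResult(
        cohort=exposure.cohort,
        add_ing=add_ing_,
        add_dermal=add_derm,
        hq=hq,
        cr=cr,
        hi=hazard_index(list(hq.values())),
        tcr=total_carcinogenic_risk(list(cr.values())),
    )


@dataclass
class ProbabilisticRiskSummary:
    """Monte Carlo index distributions for one cohort.

    ``samples`` maps index name ("HQ_As", "CR_Cr", "HI", "TCR") to the
    sorted vector of kept iterations; ``exceedance`` maps
    (index name, threshold) to P(index > threshold).
    """

    cohort: str
    samples: Dict[str, np.ndarray]
    means: Dict[str, float]
    quantiles: Dict[str, Dict[float, float]]
    exceedance: Dict[Tuple[str, float], float]

    def to_frames(self) -> Tuple[pd.DataFrame, pd.DataFrame]:
        """(quantile table, exceedance table) for CSV export."""
        qrows = [
            {"index": name, "mean": self.means[name], **{f"q{int(q*100)}": v for q, v in qs.items()}}
            for name, qs in self.quantiles.items()
        ]
        erows = [
            {"index": name, "threshold": thr, "prob_exceed": p}
            for (name, thr), p in self.exceedance.items()
        ]
        return pd.DataFrame(qrows), pd.DataFrame(erows)


def run_probabilistic_risk(
    conc_specs: Mapping[str, DistributionSpec],
    exposure: ExposureParameters,
    tox: ToxicityTable,
    n_iter: int = 5000,
    n_keep: int = 3000,
    seed: int = 0,
    quantile_probs: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
    thresholds: Mapping[str, Tuple[float, ...]] = None,
) -> ProbabilisticRiskSummary:
    """Monte Carlo propagation of concentration and exposure uncertainty.

    Draws all stochastic variables independently per iteration, evaluates
    the full dose/HQ/HI/CR/TCR chain for every element, and retains the
    last ``n_keep`` of ``n_iter`` iterations for summaries.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if not (0 < n_keep <= n_iter):
        raise ValueError("require 0 < n_keep <= n_iter")
    for el, spec in conc_specs.items():
        if not isinstance(spec, DistributionSpec):
            raise ValueError(f"concentration spec for {el} is not a DistributionSpec")
    thresholds = dict(thresholds or DEFAULT_THRESHOLDS)

    rng = np.random.default_rng(seed)
    p = exposure.realize(n_iter, rng)
    cs = {el: sample(spec, n_iter, rng) for el, spec in conc_specs.items()}
    at_nc = p["ED"] * 365.0
    at_ca = exposure.lifetime_years * 365.0

    keep = slice(n_iter - n_keep, n_iter)
    samples: Dict[str, np.ndarray] = {}
    hi = np.zeros(n_keep)
    tcr = np.zeros(n_keep)
    for el in tox.elements:
        di_nc = add_ingestion(cs[el], p["IRing"], p["EF"], p["ED"], p["BW"], at_nc)
        dd_nc = add_dermal(
            cs[el], p["AF"], p["SA"], p["ABS"], p["EF"], p["ED"], p["BW"], at_nc
        )
        di_ca = add_ingestion(cs[el], p["IRing"], p["EF"], p["ED"], p["BW"], at_ca)
        dd_ca = add_dermal(
            cs[el], p["AF"], p["SA"], p["ABS"], p["EF"], p["ED"], p["BW"], at_ca
        )
        hq = hazard_quotient(
            {"ingestion": di_nc, "dermal": dd_nc}, tox.rfd.get(el, {})
        )
        cr = carcinogenic_risk(
            {"ingestion": di_ca, "dermal": dd_ca}, tox.sf.get(el, {})
        )
        hq = np.broadcast_to(np.asarray(hq, dtype=float), (n_iter,))[keep]
        cr = np.broadcast_to(np.asarray(cr, dtype=float), (n_iter,))[keep]
        hi += hq
        tcr += cr
        samples[f"HQ_{el}"] = np.sort(hq)
        samples[f"CR_{el}"] = np.sort(cr)
    samples["HI"] = np.sort(hi)
    samples["TCR"] = np.sort(tcr)

    means = {k: float(v.mean()) for k, v in samples.items()}
    quantiles = {
        k: {float(q): float(np.quantile(v, q)) for q in quantile_probs}
        for k, v in samples.items()
    }
    exceedance: Dict[Tuple[str, float], float] = {}
    for name, vec in samples.items():
        kind = name.split("_")[0]
        for thr in thresholds.get(kind, ()):
            exceedance[(name, float(thr))] = float((vec > thr).mean())
    return ProbabilisticRiskSummary(
        cohort=exposure.cohort,
        samples=samples,
        means=means,
        quantiles=quantiles,
        exceedance=exceedance,
    )
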