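"""Parametric distribution specifications for every stochastic input.

All Monte Carlo stages (sample synthesis, point perturbation, exposure
simulation) draw from :class:`DistributionSpec` objects so that a single
validated description covers concentrations, positions and exposure
variables alike.

The lognormal family is parameterised by its 50th and 95th percentiles,
the form in which soil-concentration distributions are usually tabulated:
the underlying normal has ``mu = ln(p50)`` and
``sigma = (ln(p95) - ln(p50)) / z95`` where ``z95 = 1.6449`` is the
standard-normal 95th-percentile deviate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = ["DistributionSpec", "Z95", "sample", "lognormal_from_percentiles"]

#: Standard-normal 95th-percentile deviate used to recover sigma from (p50, p95).
Z95 = 1.6449

_FAMILIES = ("lognormal_p50p95", "normal_meansd", "uniform", "triangular", "point")


class InvalidSpecError(ValueError):
    """Raised when a DistributionSpec violates its family's constraints."""


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric family plus its parameters.

    Parameters
    ----------
    family:
        One of ``lognormal_p50p95`` (params: 50th and 95th percentiles),
        ``normal_meansd`` (mean, standard deviation), ``uniform`` (lo, hi),
        ``triangular`` (lo, mode, hi) or ``point`` (the constant value).
    params:
        Tuple of real parameters, semantics per family.
    """

    family: str
    params: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise InvalidSpecError(f"unknown family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        p = self.params
        if self.family == "lognormal_p50p95":
            if len(p) != 2:
                raise InvalidSpecError("lognormal_p50p95 takes (p50, p95)")
            if not (0.0 < p[0] <= p[1]):
                raise InvalidSpecError(
                    f"lognormal_p50p95 requires 0 < p50 <= p95, got {p}"
                )
        elif self.family == "normal_meansd":
            if len(p) != 2 or p[1] < 0:
                raise InvalidSpecError(f"normal_meansd requires sd >= 0, got {p}")
        elif self.family == "uniform":
            if len(p) != 2 or p[0] > p[1]:
                raise InvalidSpecError(f"uniform requires lo <= hi, got {p}")
        elif self.family == "triangular":
            if len(p) != 3 or not (p[0] <= p[1] <= p[2]):
                raise InvalidSpecError(f"triangular requires lo <= mode <= hi, got {p}")
        elif self.family == "point":
            if len(p) != 1:
                raise InvalidSpecError("point takes a single value")

    @property
    def mu_sigma(self) -> Tuple[float, float]:
        """(mu, sigma) of the underlying normal for the lognormal family."""
        if self.family != "lognormal_p50p95":
            raise InvalidSpecError("mu_sigma only defined for lognormal_p50p95")
        p50, p95 = self.params
        mu = np.log(p50)
        sigma = (np.log(p95) - np.log(p50)) / Z95
        return float(mu), float(sigma)


def sample(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` values from ``spec`` using ``rng``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    p = spec.params
    if spec.family == "lognormal_p50p95":
        mu, sigma = spec.mu_sigma
        if sigma == 0.0:  # degenerate: all mass at p50
            return np.full(n, p[0])
        return rng.lognormal(mean=mu, sigma=sigma, size=n)
    if spec.family == "normal_meansd":
        return rng.normal(loc=p[0], scale=p[1], size=n)
    if spec.family == "uniform":
        return rng.uniform(low=p[0], high=p[1], size=n)
    if spec.family == "triangular":
        if p[0] == p[2]:
            return np.full(n, p[0])
        return rng.triangular(left=p[0], mode=p[1], right=p[2], size=n)
    # point
    return np.full(n, p[0])


def lognormal_from_percentiles(
    spec: DistributionSpec, n: int, seed: int
) -> np.ndarray:
    """Draw ``n`` positive values from a lognormal given by (p50, p95).

    The underlying normal has ``mu = ln(p50)`` and
    ``sigma = (ln p95 - ln p50) / 1.6449``; reproducible under ``seed``.
    """
    if spec.family != "lognormal_p50p95":
        raise InvalidSpecError(f"expected lognormal_p50p95 spec, got {spec.family}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return sample(spec, n, rng)
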