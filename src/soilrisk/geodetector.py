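"""Geographic detector: factor and interaction detectors with optimal
discretization of continuous covariates.

The factor detector's q-statistic measures how much of a numeric
response's variance a categorical spatial stratification explains:

    q = 1 - SSW / SST = 1 - sum_h(N_h * var_h) / (N * var),

with population (divide-by-N) variances so the two forms coincide
exactly.  q is 0 when strata are uninformative and 1 when the response
is constant within every stratum.  The interaction detector computes q
on the cross-classification of two factors and classifies the joint
effect against the individual q values.  Significance is assessed by a
permutation test of the stratum labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "StrataData",
    "QResult",
    "InteractionResult",
    "factor_q",
    "q_significance",
    "interaction_q",
    "classify_interaction",
    "optimal_discretize",
]

INTERACTION_TYPES = (
    "nonlinear_weaken",
    "univariate_weaken",
    "bivariate_enhance",
    "independent",
    "nonlinear_enhance",
)


@dataclass
class StrataData:
    """Aligned response / stratum-label vectors with nodata exclusion."""

    y: np.ndarray
    strata: np.ndarray
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.strata = np.asarray(self.strata)
        if self.y.shape != self.strata.shape:
            raise ValueError("y and strata must have equal length")
        mask = ~np.isnan(self.y)
        if np.issubdtype(self.strata.dtype, np.number):
            mask &= self.strata != -1
            mask &= ~np.isnan(self.strata.astype(float))
        if self.valid is not None:
            mask &= np.asarray(self.valid, dtype=bool)
        self.valid = mask
        if mask.sum() < 1:
            raise ValueError("no valid observations")


@dataclass
class QResult:
    q: float
    ssw: float
    sst: float
    L: int
    p_value: Optional[float] = None


@dataclass
class InteractionResult:
    q1: float
    q2: float
    q12: float
    type: str


def _q_decomposition(y: np.ndarray, strata: np.ndarray) -> Tuple[float, float, int]:
    """(SSW, SST, L) using population variances."""
    n = y.size
    sst = n * y.var()
    ssw = 0.0
    uniq = np.unique(strata)
    # groupby via sort: one pass regardless of label dtype
    order = np.argsort(strata, kind="stable")
    ys = y[order]
    bounds = np.searchsorted(strata[order], uniq, side="left")
    bounds = np.append(bounds, n)
    for i in range(uniq.size):
        grp = ys[bounds[i] : bounds[i + 1]]
        ssw += grp.size * grp.var()
    return float(ssw), float(sst), int(uniq.size)


def factor_q(data: StrataData) -> QResult:
    """Factor-detector q-statistic of the stratification in ``data``."""
    y = data.y[data.valid]
    strata = data.strata[data.valid]
    if y.size < 2:
        raise ValueError("need at least 2 valid observations")
    ssw, sst, L = _q_decomposition(y, strata)
    if sst <= 0:
        raise ValueError("constant response: total variance is zero")
    q = 1.0 - ssw / sst
    # clamp tiny negative round-off; q is bounded in [0, 1] analytically
    q = min(1.0, max(0.0, q))
    return QResult(q=q, ssw=ssw, sst=sst, L=L)


def q_significance(
    data: StrataData, n_perm: int = 999, seed: int = 0
) -> float:
    """Permutation p-value: share of label shuffles with q >= observed.

    p = (1 + #{permuted q >= q_obs}) / (1 + n_perm), always in (0, 1].
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    obs = factor_q(data).q
    y = data.y[data.valid]
    strata = data.strata[data.valid].copy()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        rng.shuffle(strata)
        ssw, sst, _ = _q_decomposition(y, strata)
        if 1.0 - ssw / sst >= obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


def classify_interaction(q1: float, q2: float, q12: float, tol: float = 1e-6) -> str:
    """Five-way interaction taxonomy.

    nonlinear_weaken   q12 < min(q1, q2)
    univariate_weaken  min(q1, q2) <= q12 <= max(q1, q2)
    bivariate_enhance  max(q1, q2) < q12 < q1 + q2
    independent        |q12 - (q1 + q2)| <= tol
    nonlinear_enhance  q12 > q1 + q2
    """
    for v in (q1, q2, q12):
        if not (0 <= v <= 1):
            raise ValueError("q values must lie in [0, 1]")
    if abs(q12 - (q1 + q2)) <= tol:
        return "independent"
    if q12 > q1 + q2:
        return "nonlinear_enhance"
    if q12 > max(q1, q2):
        return "bivariate_enhance"
    if q12 >= min(q1, q2):
        return "univariate_weaken"
    return "nonlinear_weaken"


def interaction_q(
    y: np.ndarray,
    strata_a: np.ndarray,
    strata_b: np.ndarray,
    tol: float = 1e-6,
) -> InteractionResult:
    """q of the overlay (A, B) cross-classification plus its interaction type."""
    da = StrataData(y, strata_a)
    db = StrataData(y, strata_b)
    valid = da.valid & db.valid
    if valid.sum() < 2:
        raise ValueError("overlay has fewer than 2 valid observations")
    ya = np.where(valid, np.asarray(y, dtype=float), np.nan)
    q1 = factor_q(StrataData(ya, strata_a)).q
    q2 = factor_q(StrataData(ya, strata_b)).q

    a = np.asarray(strata_a)[valid]
    b = np.asarray(strata_b)[valid]
    # encode ordered pairs as single integer labels
    _, ai = np.unique(a, return_inverse=True)
    ub, bi = np.unique(b, return_inverse=True)
    overlay = ai * ub.size + bi
    yv = np.asarray(y, dtype=float)[valid]
    ssw, sst, L = _q_decomposition(yv, overlay)
    if L == yv.size and ssw == 0.0:
        warnings.warn(
            "overlay produced all-singleton strata; q12 = 1 is uninformative",
            stacklevel=2,
        )
    q12 = min(1.0, max(0.0, 1.0 - ssw / sst))
    return InteractionResult(
        q1=q1, q2=q2, q12=q12, type=classify_interaction(q1, q2, q12, tol)
    )


def _breaks_for(x: np.ndarray, method: str, k: int) -> np.ndarray:
    """Interior class boundaries for a discretization method."""
    if method == "equal_interval":
        return np.linspace(x.min(), x.max(), k + 1)[1:-1]
    if method == "quantile":
        return np.unique(np.quantile(x, np.linspace(0, 1, k + 1)[1:-1]))
    if method == "natural_breaks":
        # 1-D variance-minimizing clustering; boundaries midway between
        # adjacent cluster extremes
        km = KMeans(n_clusters=k, n_init=5, random_state=0).fit(x.reshape(-1, 1))
        centers = np.sort(km.cluster_centers_.ravel())
        labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        cuts = []
        for i in range(k - 1):
            lo = x[labels == i]
            hi = x[labels == i + 1]
            if lo.size and hi.size:
                cuts.append((lo.max() + hi.min()) / 2.0)
        return np.asarray(cuts)
    raise ValueError(f"unknown discretization method {method!r}")


def optimal_discretize(
    y: np.ndarray,
    x: np.ndarray,
    methods: Sequence[str] = ("equal_interval", "quantile", "natural_breaks"),
    k_range: Tuple[int, int] = (2, 8),
) -> Tuple[np.ndarray, str, int, float]:
    """Pick the (method, class count) maximizing q for a continuous covariate.

    Evaluates ``factor_q`` for every method x k in ``k_range`` (inclusive,
    within [2, 15]) and returns ``(breaks, method, k, q)`` of the argmax.
    Ties prefer fewer classes, then earlier method order.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    if x.size < 2 or x.min() == x.max():
        raise ValueError("covariate must be non-constant")
    lo, hi = k_range
    if lo < 2 or hi > 15 or lo > hi:
        raise ValueError("k_range must lie within [2, 15]")

    best = None  # (q, k, method_idx, breaks)
    for k in range(lo, hi + 1):
        for mi, method in enumerate(methods):
            try:
                cuts = _breaks_for(x, method, k)
            except ValueError:
                continue
            labels = np.digitize(x, cuts)
            if np.unique(labels).size < 2:
                continue
            q = factor_q(StrataData(y, labels)).q
            key = (-q, k, mi)
            if best is None or key < best[0]:
                best = (key, cuts, method, k, q)
    if best is None:
        raise ValueError("all candidate discretizations are degenerate")
    return best[1], best[2], best[3], best[4]
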