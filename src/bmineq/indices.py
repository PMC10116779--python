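"""Weighted fractional ranks and concentration indices for bounded outcomes.

Socio-economic inequality in a bounded health outcome y in [a, b] is measured
by rank-covariance indices.  With fractional rank r over a deprivation-ordered
dimension (most deprived at the LOW end of the rank scale) and weighted mean
mu:

* Erreygers corrected concentration index
      E = (4 mu / (b - a)) * (2 cov_w(y, r) / mu) = 8 cov_w(y, r) / (b - a)
  attainable range [-1, 1]; negative means the outcome is concentrated among
  the most deprived.

* Wagstaff (bounded-outcome normalised) concentration index
      W = 2 cov_w(y, r) * (b - a) / ((b - mu) (mu - a))
  which for a 0/1 outcome reduces to C/(1 - mu) and satisfies the identity
  E = 4 mu (1 - mu) W.

Standard errors come from a seeded nonparametric bootstrap (records resampled
with their weights, ranks recomputed per replicate) or from the "convenient
regression" delta method: the WLS slope of (8 var_w(r)/(b-a)) * y on r equals
E, so its heteroskedasticity-robust slope SE serves as the index SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .exceptions import ConfigurationError, EstimationError

#: default outcome bounds: binary flags on [0, 1], continuous BMI on [12, 60]
BMI_BOUNDS = (12.0, 60.0)

DEFAULT_BOOTSTRAP_REPS = 1000


def weighted_fractional_rank(levels: np.ndarray, w: np.ndarray,
                             order: Sequence | None = None) -> np.ndarray:
    """Weighted fractional rank in (0, 1) over a deprivation-ordered scale.

    ``order`` lists the category codes most-deprived-first; by default the
    codes are taken in descending numeric order (this package codes all
    deprivation dimensions with the highest code = most deprived).  Each
    record's rank is the cumulative weight share of strictly more deprived
    categories plus half its own category's share; ties within a category
    share the mid-rank.
    """
    levels = np.asarray(levels)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ConfigurationError("rank weights must be positive")
    uniq = np.unique(levels)
    if order is None:
        order = list(np.sort(uniq)[::-1])
    else:
        order = list(order)
        unknown = set(uniq.tolist()) - set(order)
        if unknown:
            raise ConfigurationError(f"unknown deprivation levels {sorted(unknown)}")
    pos = {lv: i for i, lv in enumerate(order)}
    idx = np.fromiter((pos[lv] for lv in levels.tolist()), dtype=int, count=len(levels))
    cat_w = np.bincount(idx, weights=w, minlength=len(order))
    total = cat_w.sum()
    cum_before = np.cumsum(cat_w) - cat_w
    r_cat = (cum_before + cat_w / 2.0) / total
    return r_cat[idx]


def weighted_cov(y: np.ndarray, r: np.ndarray, w: np.ndarray) -> float:
    """Population-style weighted covariance sum w (y - mu)(r - rbar) / sum w."""
    y = np.asarray(y, dtype=float)
    r = np.asarray(r, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(y) == len(r) == len(w)):
        raise ConfigurationError("y, r, w must have equal lengths")
    if len(y) < 2:
        raise EstimationError("need at least 2 records for a covariance")
    if np.any(w <= 0):
        raise ConfigurationError("weights must be positive")
    total = w.sum()
    mu = float(np.sum(w * y) / total)
    rbar = float(np.sum(w * r) / total)
    return float(np.sum(w * (y - mu) * (r - rbar)) / total)


@dataclass
class RankedVector:
    """Outcome values with bounds, weights and fractional ranks.

    Invariants: ranks in (0, 1) with weighted mean 0.5; a <= min(y) and
    max(y) <= b.  Build from raw categories with :meth:`from_levels`.
    """

    y: np.ndarray
    w: np.ndarray
    r: np.ndarray
    a: float
    b: float
    levels: np.ndarray | None = None  # retained so bootstrap can recompute ranks
    order: list | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if not (len(self.y) == len(self.w) == len(self.r)):
            raise ConfigurationError("y, w, r must have equal lengths")
        if self.b <= self.a:
            raise ConfigurationError("need a < b")
        if np.any(self.w <= 0):
            raise ConfigurationError("weights must be positive")
        if np.any((self.r <= 0) | (self.r >= 1)):
            raise ConfigurationError("ranks must lie strictly in (0, 1)")
        if self.y.min() < self.a or self.y.max() > self.b:
            raise ConfigurationError("outcome outside declared bounds [a, b]")

    @property
    def mu(self) -> float:
        return float(np.sum(self.w * self.y) / self.w.sum())

    @classmethod
    def from_levels(cls, y, levels, w, bounds=(0.0, 1.0), order=None) -> "RankedVector":
        levels = np.asarray(levels)
        r = weighted_fractional_rank(levels, w, order=order)
        if order is None:
            order = list(np.sort(np.unique(levels))[::-1])
        return cls(y=np.asarray(y, float), w=np.asarray(w, float), r=r,
                   a=float(bounds[0]), b=float(bounds[1]),
                   levels=levels, order=list(order))


@dataclass
class ConcentrationEstimate:
    """A concentration index value with (optional) inference and context."""

    value: float
    variant: str                       # 'erreygers' | 'wagstaff'
    se: float | None = None
    p_value: float | None = None
    n_effective: float | None = None
    stratum: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in ("erreygers", "wagstaff"):
            raise ConfigurationError(f"unknown index variant {self.variant!r}")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ConfigurationError("p_value outside [0, 1]")


def _kish_n(w: np.ndarray) -> float:
    return float(w.sum() ** 2 / np.sum(w ** 2))


def erreygers_cci(v: RankedVector) -> ConcentrationEstimate:
    """Erreygers corrected concentration index 8 cov_w(y, r) / (b - a).

    The simplified 8*cov form is used throughout, so a zero-prevalence outcome
    is well defined (index 0) even though the textbook 4mu/(b-a) * 2cov/mu
    factorisation divides by mu.
    """
    cov = weighted_cov(v.y, v.r, v.w)
    value = 8.0 * cov / (v.b - v.a)
    return ConcentrationEstimate(value=value, variant="erreygers", n_effective=_kish_n(v.w))


def wagstaff_ci(v: RankedVector) -> ConcentrationEstimate:
    """Wagstaff normalised concentration index for a bounded outcome."""
    mu = v.mu
    if mu <= v.a or mu >= v.b:
        raise EstimationError("Wagstaff normalisation undefined: mean at an outcome bound")
    cov = weighted_cov(v.y, v.r, v.w)
    value = 2.0 * cov * (v.b - v.a) / ((v.b - mu) * (mu - v.a))
    return ConcentrationEstimate(value=value, variant="wagstaff", n_effective=_kish_n(v.w))


def _index_value(v: RankedVector, variant: str) -> float:
    est = erreygers_cci(v) if variant == "erreygers" else wagstaff_ci(v)
    return est.value


def _bootstrap_values(v: RankedVector, variant: str, reps: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Bootstrap replicate index values; ranks recomputed per replicate.

    Uses per-category sufficient statistics (category weight totals and
    weighted outcome sums), so each replicate costs O(n) bincounts.
    """
    if v.levels is None:
        raise EstimationError("bootstrap requires the RankedVector's category levels")
    order = v.order
    pos = {lv: i for i, lv in enumerate(order)}
    idx = np.fromiter((pos[lv] for lv in np.asarray(v.levels).tolist()),
                      dtype=int, count=len(v.y))
    n, k = len(v.y), len(order)
    wy = v.w * v.y
    out = np.empty(reps)
    span = v.b - v.a
    for rep in range(reps):
        take = rng.integers(0, n, n)
        cats = idx[take]
        W = np.bincount(cats, weights=v.w[take], minlength=k)
        S = np.bincount(cats, weights=wy[take], minlength=k)
        total = W.sum()
        cum = np.cumsum(W)
        r_cat = (cum - W / 2.0) / total
        mu = S.sum() / total
        rbar = float(np.sum(W * r_cat) / total)
        cov = float(np.sum(r_cat * S) / total - mu * rbar)
        if variant == "erreygers":
            out[rep] = 8.0 * cov / span
        else:
            denom = (v.b - mu) * (mu - v.a)
            out[rep] = 2.0 * cov * span / denom if denom > 0 else np.nan
    return out


def _delta_se(v: RankedVector, variant: str) -> float:
    """Robust-WLS slope SE of the convenient regression for the index."""
    total = v.w.sum()
    rbar = float(np.sum(v.w * v.r) / total)
    var_r = float(np.sum(v.w * (v.r - rbar) ** 2) / total)
    if variant == "erreygers":
        scale = 8.0 * var_r / (v.b - v.a)
    else:
        mu = v.mu
        if mu <= v.a or mu >= v.b:
            raise EstimationError("Wagstaff normalisation undefined at an outcome bound")
        scale = 2.0 * var_r * (v.b - v.a) / ((v.b - mu) * (mu - v.a))
    X = sm.add_constant(v.r)
    fit = sm.WLS(scale * v.y, X, weights=v.w).fit(cov_type="HC1")
    return float(fit.bse[1])


def cci_inference(v: RankedVector, variant: str = "erreygers",
                  method: str = "bootstrap", reps: int = DEFAULT_BOOTSTRAP_REPS,
                  seed: int | np.random.SeedSequence = 0) -> tuple[float, float]:
    """(se, p) for a concentration index.

    ``method='bootstrap'`` (default): resample records, recompute ranks and
    index per replicate; SE is the replicate SD and p the two-sided normal
    approximation of value/SE.  ``method='delta'``: convenient-regression
    robust SE.  Requires n >= 30.
    """
    if len(v.y) < 30:
        raise EstimationError("inference requires n >= 30")
    value = _index_value(v, variant)
    if method == "bootstrap":
        if reps < 50:
            warnings.warn("fewer than 50 bootstrap replicates; SE will be noisy",
                          stacklevel=2)
        rng = np.random.default_rng(seed)
        vals = _bootstrap_values(v, variant, reps, rng)
        vals = vals[np.isfinite(vals)]
        se = float(vals.std(ddof=1))
        if se == 0.0:
            raise EstimationError("degenerate bootstrap distribution (zero spread)")
    elif method == "delta":
        se = _delta_se(v, variant)
        if se == 0.0:
            raise EstimationError("degenerate delta-method SE")
    else:
        raise ConfigurationError(f"unknown inference method {method!r}")
    p = float(2.0 * (1.0 - norm.cdf(abs(value) / se)))
    return se, p


def estimate_index(y, levels, w, variant: str = "erreygers", bounds=(0.0, 1.0),
                   order=None, inference: str | None = "bootstrap",
                   reps: int = DEFAULT_BOOTSTRAP_REPS, seed=0,
                   stratum: dict | None = None) -> ConcentrationEstimate:
    """One-call convenience: ranks, index and (optionally) inference."""
    v = RankedVector.from_levels(y, levels, w, bounds=bounds, order=order)
    est = erreygers_cci(v) if variant == "erreygers" else wagstaff_ci(v)
    if inference is not None:
        est.se, est.p_value = cci_inference(v, variant, method=inference,
                                            reps=reps, seed=seed)
    est.stratum = dict(stratum or {})
    return est
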