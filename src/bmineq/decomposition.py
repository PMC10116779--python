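"""Shapley decomposition of the dissimilarity index of a binary outcome.

The "explained inequality" of a binary outcome given a set of categorical
factors is summarised by the dissimilarity index (DI) of the fitted
probabilities from a weighted logistic main-effects model:

    DI = sum_i w_i |p_i - pbar| / (2 pbar sum_i w_i),

the weighted share of outcome mass that would have to be redistributed for
everyone to face the overall prevalence pbar.  Each factor's independent
contribution is its Shapley value: the average of its marginal DI
contribution over all orders in which factors can be eliminated, computed by
exact subset enumeration with memoised model fits.  DI of the empty factor
set is 0, so the Shapley values sum exactly to the full-model DI
(efficiency).

Model fits use a ridge-damped Newton solver over dummy-coded designs; with
2^m subset fits per decomposition (and again per bootstrap replicate) this is
the package's hot loop.  Tests cross-check it against statsmodels GLM.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .exceptions import ConfigurationError, EstimationError

log = logging.getLogger(__name__)

#: the factor universe of the decomposition analyses
ALL_FACTORS = ("imd_quintile", "region", "age_group", "gender", "ethnicity",
               "limiting_illness", "marital_status", "urbanicity",
               "occupation", "education")

DEFAULT_PVALUE_REPS = 200


@dataclass
class FactorSet:
    """An ordered, duplicate-free list of decomposition factors."""

    factors: tuple[str, ...]
    specification: int | None = None  # 1 | 2 | 3 when part of the ladder

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        if len(set(self.factors)) != len(self.factors):
            raise ConfigurationError("duplicate factors in FactorSet")
        unknown = set(self.factors) - set(ALL_FACTORS)
        if unknown:
            raise ConfigurationError(f"unknown factors {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.factors)


@dataclass
class DecompositionResult:
    """Full-model DI plus per-factor Shapley values and % contributions."""

    di: float
    factors: tuple[str, ...]
    shapley_values: dict[str, float]
    contrib_percent: dict[str, float]
    p_values: dict[str, float] | None
    n_observations: int
    outcome: str
    loglik: float | None = None
    k_params: int | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.factors:
            rows.append({
                "factor": f,
                "shapley_value": self.shapley_values[f],
                "contrib_percent": self.contrib_percent[f],
                "p_value": None if self.p_values is None else self.p_values.get(f),
            })
        df = pd.DataFrame(rows)
        df["DI"] = self.di
        df["n"] = self.n_observations
        df["outcome"] = self.outcome
        return df


# ---------------------------------------------------------------------------
# weighted logistic fits over dummy-coded categorical designs
# ---------------------------------------------------------------------------

def _fit_weighted_logit(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                        ridge: float = 1e-8, max_iter: int = 60,
                        tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Newton fit of a weighted logistic model; returns (beta, weighted loglik).

    A tiny ridge keeps the Hessian invertible under near-separation; if the
    fit still fails to converge the ridge is escalated with a warning
    (penalised fallback).
    """
    n, k = X.shape
    beta = np.zeros(k)
    beta[0] = _logit_of_mean(y, w)
    for attempt, lam in enumerate((ridge, 1e-4, 1e-2)):
        b = beta.copy()
        ll_old = -np.inf
        for _ in range(max_iter):
            eta = X @ b
            p = expit(eta)
            ll = float(np.sum(w * (y * np.log(np.clip(p, 1e-300, 1)) +
                                   (1 - y) * np.log(np.clip(1 - p, 1e-300, 1))))) \
                - 0.5 * lam * float(b[1:] @ b[1:])
            grad = X.T @ (w * (y - p))
            grad[1:] -= lam * b[1:]
            s = w * p * (1 - p)
            H = (X * s[:, None]).T @ X
            H[np.arange(1, k), np.arange(1, k)] += lam
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            # step-halving to guarantee ascent
            t = 1.0
            for _ in range(30):
                b_new = b + t * step
                p_new = expit(X @ b_new)
                ll_new = float(np.sum(w * (y * np.log(np.clip(p_new, 1e-300, 1)) +
                                           (1 - y) * np.log(np.clip(1 - p_new, 1e-300, 1))))) \
                    - 0.5 * lam * float(b_new[1:] @ b_new[1:])
                if ll_new >= ll - 1e-12:
                    break
                t /= 2.0
            b = b + t * step
            if abs(ll_new - ll_old) < tol * (abs(ll_old) + 1.0):
                p = expit(X @ b)
                ll_unpen = float(np.sum(w * (y * np.log(np.clip(p, 1e-300, 1)) +
                                             (1 - y) * np.log(np.clip(1 - p, 1e-300, 1)))))
                if attempt > 0:
                    warnings.warn("near-separation: logistic fit used a penalised fallback",
                                  stacklevel=2)
                return b, ll_unpen
            ll_old = ll_new
    raise EstimationError("weighted logistic fit did not converge")


def _logit_of_mean(y: np.ndarray, w: np.ndarray) -> float:
    m = float(np.sum(w * y) / np.sum(w))
    m = min(max(m, 1e-10), 1 - 1e-10)
    return math.log(m / (1 - m))


class _DesignCache:
    """Dummy-coded column blocks per factor, built once per table."""

    def __init__(self, table: pd.DataFrame, factors: tuple[str, ...]):
        self.n = len(table)
        self.blocks: dict[str, np.ndarray] = {}
        for f in factors:
            vals = table[f].to_numpy()
            levels = np.unique(vals)
            if len(levels) < 2:
                raise EstimationError(f"factor {f!r} has a single level (no variation)")
            # drop-first dummy coding
            self.blocks[f] = (vals[:, None] == levels[None, 1:]).astype(float)

    def design(self, subset: tuple[str, ...]) -> np.ndarray:
        cols = [np.ones((self.n, 1))]
        cols += [self.blocks[f] for f in subset]
        return np.hstack(cols)


def fit_outcome_model(table: pd.DataFrame, factors, outcome: str,
                      weights: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, float, int]:
    """Weighted logistic main-effects fit; returns (probabilities, loglik, k).

    An empty factor set returns the constant weighted prevalence.
    """
    if isinstance(factors, FactorSet):
        factors = factors.factors
    factors = tuple(factors)
    y = table[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ConfigurationError(f"outcome {outcome!r} is not binary")
    w = np.ones(len(table)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ConfigurationError("model weights must be positive")
    if not factors:
        pbar = float(np.sum(w * y) / w.sum())
        ll = float(np.sum(w * (y * math.log(max(pbar, 1e-300)) +
                               (1 - y) * math.log(max(1 - pbar, 1e-300)))))
        return np.full(len(table), pbar), ll, 1
    cache = _DesignCache(table, factors)
    X = cache.design(factors)
    beta, ll = _fit_weighted_logit(X, y, w)
    return expit(X @ beta), ll, X.shape[1]


def dissimilarity_index(p: np.ndarray, w: np.ndarray) -> float:
    """DI = sum w |p - pbar| / (2 pbar sum w), pbar the weighted mean of p."""
    p = np.asarray(p, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("probabilities outside [0, 1]")
    if np.any(w <= 0):
        raise ConfigurationError("weights must be positive")
    total = w.sum()
    pbar = float(np.sum(w * p) / total)
    if pbar == 0.0:
        raise EstimationError("mean probability is 0; DI undefined")
    return float(np.sum(w * np.abs(p - pbar)) / (2.0 * pbar * total))


def bic(loglik: float, k_params: int, n: int) -> float:
    """Bayesian information criterion k ln(n) - 2 loglik."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    return k_params * math.log(n) - 2.0 * loglik


# ---------------------------------------------------------------------------
# Shapley attribution over factor subsets
# ---------------------------------------------------------------------------

def _subset_di(table, factors, outcome, w, cache: _DesignCache,
               y: np.ndarray, memo: dict) -> dict[tuple[str, ...], float]:
    """DI for every subset of ``factors`` (memoised model fits)."""
    for size in range(len(factors) + 1):
        for subset in itertools.combinations(factors, size):
            key = frozenset(subset)
            if key in memo:
                continue
            if not subset:
                memo[key] = 0.0  # DI of the empty specification is defined as 0
                continue
            X = cache.design(subset)
            beta, _ = _fit_weighted_logit(X, y, w)
            memo[key] = dissimilarity_index(expit(X @ beta), w)
    return memo


def _shapley_from_di(factors: tuple[str, ...], di: dict) -> dict[str, float]:
    m = len(factors)
    fact = [math.factorial(i) for i in range(m + 1)]
    values = {}
    for f in factors:
        others = tuple(x for x in factors if x != f)
        total = 0.0
        for size in range(m):
            coeff = fact[size] * fact[m - size - 1] / fact[m]
            for subset in itertools.combinations(others, size):
                key = frozenset(subset)
                total += coeff * (di[key | {f}] - di[key])
        values[f] = total
    return values


def shapley_decompose(table: pd.DataFrame, factors, outcome: str,
                      weights: np.ndarray | None = None,
                      specification: int | None = None) -> DecompositionResult:
    """Exact Shapley decomposition of the DI over all 2^m factor subsets."""
    if isinstance(factors, FactorSet):
        spec_id = factors.specification
        factors = factors.factors
    else:
        spec_id = specification
    factors = tuple(factors)
    if not factors:
        raise ConfigurationError("need at least one factor")
    if len(factors) > 12:
        raise ConfigurationError("more than 12 factors: 2^m subset fits refused")
    w = np.ones(len(table)) if weights is None else np.asarray(weights, dtype=float)
    y = table[outcome].to_numpy(dtype=float)
    cache = _DesignCache(table, factors)
    memo: dict = {}
    di = _subset_di(table, factors, outcome, w, cache, y, memo)
    values = _shapley_from_di(factors, di)
    full = di[frozenset(factors)]
    total = sum(values.values())
    # efficiency holds analytically; guard against numerical drift
    if abs(total - full) > 1e-6 * max(1.0, abs(full)):
        raise EstimationError("Shapley efficiency identity violated beyond tolerance")
    contrib = {f: (100.0 * v / full if full > 0 else np.nan) for f, v in values.items()}
    X = cache.design(factors)
    beta, ll = _fit_weighted_logit(X, y, w)
    return DecompositionResult(
        di=full, factors=factors, shapley_values=values, contrib_percent=contrib,
        p_values=None, n_observations=len(table), outcome=outcome,
        loglik=ll, k_params=X.shape[1],
        meta={} if spec_id is None else {"specification": spec_id},
    )


def decomposition_pvalues(table: pd.DataFrame, factors, outcome: str,
                          weights: np.ndarray | None = None,
                          reps: int = DEFAULT_PVALUE_REPS,
                          seed: int | np.random.SeedSequence = 0,
                          ) -> tuple[dict[str, float], dict[str, float]]:
    """Bootstrap (p_values, standard_errors) for each factor's Shapley value.

    Records are resampled with replacement; p is the two-sided normal
    approximation of value/SE.  Non-finite replicates are dropped with a log
    entry; more than 5% dropped is an error.
    """
    if reps < 100:
        raise ConfigurationError("decomposition p-values need reps >= 100")
    if isinstance(factors, FactorSet):
        factors = factors.factors
    factors = tuple(factors)
    w = np.ones(len(table)) if weights is None else np.asarray(weights, dtype=float)
    base = shapley_decompose(table, factors, outcome, weights=w)
    rng = np.random.default_rng(seed)
    n = len(table)
    reps_ok: list[dict[str, float]] = []
    dropped = 0
    for _ in range(reps):
        take = rng.integers(0, n, n)
        t = table.iloc[take].reset_index(drop=True)
        try:
            res = shapley_decompose(t, factors, outcome, weights=w[take])
            if not all(np.isfinite(v) for v in res.shapley_values.values()):
                raise EstimationError("non-finite replicate")
            reps_ok.append(res.shapley_values)
        except (EstimationError, np.linalg.LinAlgError):
            dropped += 1
            log.info("dropped a non-finite bootstrap replicate")
    if dropped > 0.05 * reps:
        raise EstimationError(f"{dropped}/{reps} bootstrap replicates dropped")
    ses, ps = {}, {}
    for f in factors:
        vals = np.array([r[f] for r in reps_ok])
        se = float(vals.std(ddof=1))
        ses[f] = se
        ps[f] = 1.0 if se == 0.0 else float(2.0 * (1.0 - norm.cdf(abs(base.shapley_values[f]) / se)))
    return ps, ses


# ---------------------------------------------------------------------------
# specification ladder
# ---------------------------------------------------------------------------

SES_DIMENSIONS = ("imd_quintile", "occupation", "education")
_INTRINSIC = ("region", "age_group", "gender", "ethnicity")
_CIRCUMSTANCES = ("limiting_illness", "marital_status", "urbanicity")


def specification_factors(ses_dimension: str) -> dict[int, FactorSet]:
    """The nested specification ladder for one deprivation dimension under
    study: 1 = intrinsic characteristics + the dimension; 2 = + personal
    circumstances; 3 = + the remaining deprivation dimensions (full model)."""
    if ses_dimension not in SES_DIMENSIONS:
        raise ConfigurationError(f"unknown SES dimension {ses_dimension!r}")
    spec1 = (ses_dimension,) + _INTRINSIC
    spec2 = spec1 + _CIRCUMSTANCES
    spec3 = spec2 + tuple(d for d in SES_DIMENSIONS if d != ses_dimension)
    return {1: FactorSet(spec1, 1), 2: FactorSet(spec2, 2), 3: FactorSet(spec3, 3)}


def specification_ladder(table: pd.DataFrame, outcome: str,
                         ses_dimension: str = "imd_quintile",
                         weights: np.ndarray | None = None,
                         pvalue_reps: int = 0, seed=0,
                         ) -> tuple[dict[int, DecompositionResult], pd.DataFrame]:
    """Decomposition + BIC for specifications 1, 2, 3.

    Returns (results per specification id, BIC table).  ``pvalue_reps > 0``
    adds bootstrap p-values (costly: reps x 2^m fits per specification).
    """
    specs = specification_factors(ses_dimension)
    missing = [f for f in specs[3].factors if f not in table.columns]
    if missing:
        raise ConfigurationError(f"missing covariates: {missing}")
    results: dict[int, DecompositionResult] = {}
    bic_rows = []
    for sid, fs in specs.items():
        res = shapley_decompose(table, fs, outcome, weights=weights)
        if pvalue_reps:
            ps, ses = decomposition_pvalues(table, fs, outcome, weights=weights,
                                            reps=pvalue_reps, seed=seed)
            res.p_values = ps
            res.meta["shapley_se"] = ses
        res.meta["ses_dimension"] = ses_dimension
        results[sid] = res
        bic_rows.append({"specification": sid, "n_factors": len(fs),
                         "k_params": res.k_params, "loglik": res.loglik,
                         "bic": bic(res.loglik, res.k_params, res.n_observations)})
    return results, pd.DataFrame(bic_rows)
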