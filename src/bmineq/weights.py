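"""Analysis-weight construction: response propensities, IPW and raking.

The combined analysis weight used by every estimator in this package is

    combined = design_weight x ipw_factor x raking_factor,

mean-normalised over responders.  The IPW factor corrects for missing BMI
under a missing-at-random assumption (inverse of a modelled response
propensity, floored to bound variance); the raking factor aligns the weighted
sample margins with known population quotas by iterative proportional fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ConfigurationError, ConvergenceError, EstimationError

log = logging.getLogger(__name__)

DEFAULT_PROPENSITY_FLOOR = 0.02
DEFAULT_WEIGHT_CAP_RATIO = 5.0
DEFAULT_RAKING_TOL = 1e-6
DEFAULT_RAKING_MAX_ITER = 50


@dataclass
class MarginTargets:
    """Population margin proportions per (dimension, level).

    ``targets[dim]`` maps level code -> proportion; each dimension's
    proportions must sum to 1.
    """

    targets: dict[str, dict[int, float]]

    def __post_init__(self) -> None:
        for dim, levels in self.targets.items():
            total = sum(levels.values())
            if abs(total - 1.0) > 1e-8:
                raise ConfigurationError(
                    f"margin targets for {dim!r} sum to {total:.10g}, not 1")
            for lv, p in levels.items():
                if not (0.0 < p <= 1.0):
                    raise ConfigurationError(
                        f"margin target for {dim!r} level {lv} is {p}, not in (0, 1]")

    @classmethod
    def from_config(cls, config, dimensions) -> "MarginTargets":
        """Targets taken from a synthetic config's (undistorted) marginals."""
        from .synthetic import DIMENSION_LEVELS
        t = {}
        for dim in dimensions:
            levels = DIMENSION_LEVELS[dim]
            t[dim] = {lv: float(p) for lv, p in zip(levels, config.marginals[dim])}
        return cls(t)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MarginTargets":
        df = pd.read_csv(path)
        need = {"dimension", "level", "proportion"}
        if not need.issubset(df.columns):
            raise ConfigurationError(f"margin CSV needs columns {sorted(need)}")
        t: dict[str, dict[int, float]] = {}
        for _, row in df.iterrows():
            t.setdefault(str(row["dimension"]), {})[int(row["level"])] = float(row["proportion"])
        return cls(t)

    def to_csv(self, path: str | Path) -> None:
        rows = [(d, lv, p) for d, levels in self.targets.items()
                for lv, p in levels.items()]
        pd.DataFrame(rows, columns=["dimension", "level", "proportion"]).to_csv(path, index=False)


@dataclass
class RakingReport:
    iterations: int
    max_deviation: float
    converged: bool


@dataclass
class WeightVector:
    """Per-record factors and their product.  Non-responders carry zero
    combined weight; responders are mean-normalised to 1."""

    design_weight: np.ndarray
    ipw_factor: np.ndarray
    raking_factor: np.ndarray
    combined_weight: np.ndarray
    n_capped: int = 0


def fit_response_propensity(table: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Main-effects logistic model of ``responded`` on categorical covariates.

    Returns a propensity in (0, 1) per record.  A constant-1 response column
    yields all-ones with a warning (IPW then degenerates to a no-op); perfect
    separation raises with advice to collapse sparse covariate levels.
    """
    y = table["responded"].to_numpy(dtype=float)
    if set(np.unique(y)) <= {1.0}:
        warnings.warn("responded is constantly 1; propensities set to 1", stacklevel=2)
        return np.ones(len(table))
    if set(np.unique(y)) <= {0.0}:
        raise EstimationError("no responders in table; cannot fit propensity model")
    X = _dummy_design(table, covariates)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
        raise EstimationError(
            "perfect separation in the response-propensity model; "
            "collapse sparse covariate levels and refit") from exc
    p = np.asarray(fit.fittedvalues)
    eps = 1e-12
    if np.any(p <= eps) or np.any(p >= 1 - eps):
        raise EstimationError(
            "fitted response propensities hit 0/1; collapse sparse covariate levels")
    log.info("propensity model: %d covariates, %d params, deviance %.2f",
             len(covariates), X.shape[1], fit.deviance)
    return p


def _dummy_design(table: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols = [np.ones((len(table), 1))]
    for cov in covariates:
        d = pd.get_dummies(table[cov].astype("category"), drop_first=True, dtype=float)
        cols.append(d.to_numpy())
    return np.hstack(cols)


def compute_ipw(propensity: np.ndarray, responded: np.ndarray,
                floor: float = DEFAULT_PROPENSITY_FLOOR) -> np.ndarray:
    """Inverse-probability factors: 1/max(propensity, floor) for responders,
    0 for non-responders (they are excluded from all weighted estimators)."""
    p = np.asarray(propensity, dtype=float)
    if np.any(p <= 0):
        raise EstimationError("propensity <= 0 encountered")
    if not (0.0 < floor < 1.0):
        raise ConfigurationError("propensity floor must be in (0, 1)")
    resp = np.asarray(responded, dtype=bool)
    factor = np.zeros(len(p))
    factor[resp] = 1.0 / np.maximum(p[resp], floor)
    return factor


def rake(table: pd.DataFrame, starting_weights: np.ndarray, targets: MarginTargets,
         tol: float = DEFAULT_RAKING_TOL, max_iter: int = DEFAULT_RAKING_MAX_ITER,
         ) -> tuple[np.ndarray, RakingReport]:
    """Iterative proportional fitting of weights to the target margins.

    Returns per-record raking factors (final/start weight ratio) and a
    convergence report.  Raises if a targeted level is empty in the data, or if
    the margins have not all converged within ``max_iter`` sweeps.
    """
    w0 = np.asarray(starting_weights, dtype=float)
    if np.any(w0 < 0):
        raise ConfigurationError("starting weights must be non-negative")
    active = w0 > 0
    w = w0.copy()
    dims = list(targets.targets)
    masks: dict[str, dict[int, np.ndarray]] = {}
    for dim in dims:
        vals = table[dim].to_numpy()
        masks[dim] = {}
        for lv in targets.targets[dim]:
            m = (vals == lv) & active
            if not m.any():
                raise EstimationError(
                    f"raking target for {dim!r} level {lv} has no (weighted) records")
            masks[dim][lv] = m

    max_dev = np.inf
    for it in range(1, max_iter + 1):
        for dim in dims:
            total = w[active].sum()
            for lv, target_p in targets.targets[dim].items():
                m = masks[dim][lv]
                achieved = w[m].sum() / total
                if achieved > 0:
                    w[m] *= target_p / achieved
        max_dev = 0.0
        total = w[active].sum()
        for dim in dims:
            for lv, target_p in targets.targets[dim].items():
                achieved = w[masks[dim][lv]].sum() / total
                max_dev = max(max_dev, abs(achieved - target_p))
        if max_dev <= tol:
            log.info("raking converged in %d iterations (max deviation %.2e)", it, max_dev)
            factors = np.ones(len(w))
            factors[active] = w[active] / w0[active]
            return factors, RakingReport(iterations=it, max_deviation=max_dev, converged=True)
    raise ConvergenceError(
        f"raking did not converge in {max_iter} iterations (max deviation {max_dev:.3e})",
        last_deviation=max_dev)


def combine_weights(design: np.ndarray, ipw: np.ndarray, raking: np.ndarray,
                    cap_ratio: float = DEFAULT_WEIGHT_CAP_RATIO) -> WeightVector:
    """Product of the three factors, capped at ``cap_ratio`` x median and
    mean-normalised to 1 over responders (records with positive IPW factor)."""
    design = np.asarray(design, dtype=float)
    ipw = np.asarray(ipw, dtype=float)
    raking = np.asarray(raking, dtype=float)
    if not (len(design) == len(ipw) == len(raking)):
        raise ConfigurationError("weight factors have unequal lengths")
    if np.any(design <= 0) or np.any(raking <= 0) or np.any(ipw < 0):
        raise ConfigurationError("weight factors must be positive (ipw may be 0 for non-responders)")
    combined = design * ipw * raking
    resp = ipw > 0
    if not resp.any():
        raise EstimationError("no responders carry weight")
    med = float(np.median(combined[resp]))
    cap = cap_ratio * med
    n_capped = int(np.sum(combined[resp] > cap))
    if n_capped:
        log.info("capping %d weights at %.1f x median", n_capped, cap_ratio)
        combined = np.minimum(combined, cap)
        combined[~resp] = 0.0
    combined = combined / combined[resp].mean()
    return WeightVector(design_weight=design, ipw_factor=ipw, raking_factor=raking,
                        combined_weight=combined, n_capped=n_capped)
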