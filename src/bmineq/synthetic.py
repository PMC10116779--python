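"""Synthetic survey generator emulating the structure of an HSE-2019-like sample.

Produces individual adult records (BMI plus socio-demographic covariates) with
known, configurable deprivation gradients, missing-at-random BMI non-response
and sampling-quota imbalance, so every downstream estimator in this package has
a parameter-recovery test surface.

Coding conventions
------------------
All categorical dimensions are integer-coded.  The three deprivation dimensions
are coded in *increasing deprivation order*:

* ``imd_quintile``  1..5 (5 = most deprived neighbourhood quintile)
* ``occupation``    1..6 (NS-SEC classes, 6 = most deprived)
* ``education``     1..8 (NVQ-based scale, 8 = most deprived)

Other dimensions: ``region`` 1..9, ``age_group`` 1..7 (20-29 ... 80+),
``gender`` 1..2, ``ethnicity`` 1..5, ``marital_status`` 1..5, and the binary
``limiting_illness`` / ``urbanicity`` coded 0/1.

BMI is drawn from an additive linear model over the covariate levels plus a
Gaussian residual, floored at 12 kg/m^2.  Binary outcome flags (excess weight,
obesity, morbid obesity) are derived from continuous BMI at the standard
cut-points so spectrum analyses stay internally consistent; an optional
logistic mode (``binary_gradient``) simulates the excess-weight indicator
directly for calibration studies with closed-form truth.

Dependence between the deprivation dimensions uses an equicorrelated Gaussian
copula (single latent factor), which keeps both sampling and the analytic
ground-truth computation exact.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri
from scipy.stats import norm

from .exceptions import ConfigurationError

FORMAT_VERSION = "bmineq-survey-v1"

BMI_FLOOR = 12.0

#: binary outcome flags and the BMI threshold defining each (half-open, >=)
OUTCOME_CUTPOINTS = {"excess_weight": 25.0, "obese": 30.0, "morbid": 35.0}

#: dimension -> ordered list of integer level codes
DIMENSION_LEVELS: dict[str, list[int]] = {
    "region": list(range(1, 10)),
    "age_group": list(range(1, 8)),
    "gender": [1, 2],
    "ethnicity": list(range(1, 6)),
    "education": list(range(1, 9)),
    "occupation": list(range(1, 7)),
    "imd_quintile": list(range(1, 6)),
    "limiting_illness": [0, 1],
    "marital_status": list(range(1, 6)),
    "urbanicity": [0, 1],
}

#: dimensions ordered most-deprived-at-the-highest-code
DEPRIVATION_DIMS = ("imd_quintile", "occupation", "education")

#: dimensions coupled through the Gaussian copula
COPULA_DIMS = ("imd_quintile", "education", "occupation")

_COLUMNS = [
    "id", "bmi", "excess_weight", "obese", "morbid",
    "region", "age_group", "gender", "ethnicity", "education", "occupation",
    "imd_quintile", "limiting_illness", "marital_status", "urbanicity",
    "design_weight", "responded",
]


def _as_prob_vector(name: str, values, k: int) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.shape != (k,):
        raise ConfigurationError(f"{name}: expected {k} probabilities, got shape {v.shape}")
    if np.any(v < 0):
        raise ConfigurationError(f"{name}: negative probability")
    if abs(v.sum() - 1.0) > 1e-12:
        raise ConfigurationError(f"{name}: probabilities sum to {v.sum():.15g}, not 1")
    return v


@dataclass
class SyntheticConfig:
    """All knobs of the generator; same config + seed gives byte-identical output.

    ``marginals`` holds one probability vector per dimension (aligned with
    :data:`DIMENSION_LEVELS`).  ``bmi_effects`` holds additive kg/m^2 offsets per
    level; ``missingness_effects`` holds log-odds offsets per level entering the
    non-response logit together with ``missingness_intercept``.  Quota
    distortion multiplies sampling probabilities per (dimension, level) to
    emulate quota/sample imbalance that raking must undo; the population the
    ground truth describes is the *undistorted* one.
    """

    n_individuals: int = 6387
    seed: int = 2019
    marginals: dict[str, np.ndarray] = field(default_factory=dict)
    bmi_intercept: float = 24.3
    bmi_effects: dict[str, np.ndarray] = field(default_factory=dict)
    bmi_residual_sd: float = 5.0
    binary_gradient: dict | None = None
    missingness_intercept: float = -np.inf  # default: no missingness
    missingness_effects: dict[str, np.ndarray] = field(default_factory=dict)
    copula_rho: float = 0.3
    quota_distortion: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if self.bmi_residual_sd <= 0:
            raise ConfigurationError("bmi_residual_sd must be > 0")
        if not (0.0 <= self.copula_rho < 1.0):
            raise ConfigurationError("copula_rho must be in [0, 1)")
        full = dict(_default_marginals())
        for dim, probs in self.marginals.items():
            if dim not in DIMENSION_LEVELS:
                raise ConfigurationError(f"marginals: unknown dimension {dim!r}")
            full[dim] = _as_prob_vector(f"marginals[{dim}]", probs, len(DIMENSION_LEVELS[dim]))
        self.marginals = full
        effects = {d: np.zeros(len(lv)) for d, lv in DIMENSION_LEVELS.items()}
        for dim, e in self.bmi_effects.items():
            if dim not in DIMENSION_LEVELS:
                raise ConfigurationError(f"bmi_effects: unknown dimension {dim!r}")
            e = np.asarray(e, dtype=float)
            if e.shape != (len(DIMENSION_LEVELS[dim]),):
                raise ConfigurationError(f"bmi_effects[{dim}]: wrong length")
            effects[dim] = e
        self.bmi_effects = effects
        miss = {}
        for dim, e in self.missingness_effects.items():
            if dim not in DIMENSION_LEVELS:
                raise ConfigurationError(f"missingness_effects: unknown dimension {dim!r}")
            e = np.asarray(e, dtype=float)
            if e.shape != (len(DIMENSION_LEVELS[dim]),):
                raise ConfigurationError(f"missingness_effects[{dim}]: wrong length")
            miss[dim] = e
        self.missingness_effects = miss
        if self.quota_distortion is not None:
            qd = {}
            for dim, m in self.quota_distortion.items():
                if dim not in DIMENSION_LEVELS:
                    raise ConfigurationError(f"quota_distortion: unknown dimension {dim!r}")
                m = np.asarray(m, dtype=float)
                if m.shape != (len(DIMENSION_LEVELS[dim]),) or np.any(m <= 0):
                    raise ConfigurationError(f"quota_distortion[{dim}]: need positive multipliers per level")
                qd[dim] = m
            self.quota_distortion = qd
        if self.binary_gradient is not None:
            bg = dict(self.binary_gradient)
            bg.setdefault("intercept", 0.0)
            eff = {}
            for dim, e in bg.get("effects", {}).items():
                if dim not in DIMENSION_LEVELS:
                    raise ConfigurationError(f"binary_gradient: unknown dimension {dim!r}")
                e = np.asarray(e, dtype=float)
                if e.shape != (len(DIMENSION_LEVELS[dim]),):
                    raise ConfigurationError(f"binary_gradient[{dim}]: wrong length")
                eff[dim] = e
            bg["effects"] = eff
            self.binary_gradient = bg

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, float) and math.isinf(x):
                return "-inf" if x < 0 else "inf"
            return x

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        mi = d.get("missingness_intercept")
        if isinstance(mi, str):
            d["missingness_intercept"] = float(mi)
        for key in ("marginals", "bmi_effects", "missingness_effects", "quota_distortion"):
            if d.get(key):
                d[key] = {k: np.asarray(v, float) for k, v in d[key].items()}
        return cls(**d)

    @classmethod
    def hse_default(cls, n_individuals: int = 6387, seed: int = 2019,
                    target_missing: float = 0.186, **overrides) -> "SyntheticConfig":
        """HSE-2019-informed defaults: Table-1-style marginals, SES gradients in
        BMI, covariate-dependent MAR non-response calibrated to ``target_missing``
        overall, and a mild quota distortion on age and gender."""
        kwargs = dict(
            n_individuals=n_individuals,
            seed=seed,
            bmi_effects=_default_bmi_effects(),
            missingness_intercept=0.0,
            missingness_effects={
                "limiting_illness": np.array([0.0, 0.4]),
                "age_group": 0.08 * (np.arange(7) - 3.0),
            },
            quota_distortion={
                "age_group": np.array([0.8, 0.9, 1.0, 1.0, 1.1, 1.15, 1.2]),
                "gender": np.array([0.9, 1.1]),
            },
        )
        kwargs.update(overrides)
        cfg = cls(**kwargs)
        cfg.missingness_intercept = calibrate_missingness_intercept(cfg, target_missing)
        return cfg


def _default_marginals() -> dict[str, np.ndarray]:
    # England-wide category proportions of an HSE-2019-like adult sample
    def norm1(v):
        v = np.asarray(v, float)
        return v / v.sum()

    return {
        "region": norm1([548, 833, 664, 573, 606, 717, 761, 1020, 596]),
        "age_group": norm1([0.11, 0.17, 0.18, 0.18, 0.17, 0.14, 0.06]),
        "gender": norm1([0.45, 0.55]),
        "ethnicity": norm1([0.87, 0.02, 0.08, 0.03, 0.01]),
        "education": norm1([0.31, 0.11, 0.14, 0.18, 0.04, 0.01, 0.19, 0.02]),
        "occupation": norm1([0.39, 0.14, 0.11, 0.07, 0.28, 0.02]),
        "imd_quintile": norm1([0.21, 0.20, 0.20, 0.19, 0.20]),
        "limiting_illness": norm1([0.75, 0.25]),
        "marital_status": norm1([0.51, 0.10, 0.23, 0.09, 0.07]),
        "urbanicity": norm1([0.18, 0.82]),
    }


def _default_bmi_effects() -> dict[str, np.ndarray]:
    # kg/m^2 offsets; deprivation dims get monotone positive gradients
    return {
        "region": np.array([0.6, 0.3, 0.2, 0.25, 0.6, -0.1, -0.8, -0.6, 0.4]),
        "age_group": np.array([0.0, 1.2, 1.8, 2.1, 2.2, 1.9, 1.2]),
        "gender": np.array([0.0, -0.2]),
        "ethnicity": np.array([0.0, -0.5, -0.8, 0.5, -0.5]),
        "education": 0.22 * np.arange(8, dtype=float),
        "occupation": 0.28 * np.arange(6, dtype=float),
        "imd_quintile": 0.35 * np.arange(5, dtype=float),
        "limiting_illness": np.array([0.0, 1.6]),
        "marital_status": np.array([0.0, 0.2, -0.3, 0.3, 0.4]),
        "urbanicity": np.array([0.3, 0.0]),
    }


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sampling_marginals(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Marginals actually used to draw the sample (quota distortion applied)."""
    out = {}
    for dim, probs in config.marginals.items():
        if config.quota_distortion and dim in config.quota_distortion:
            p = probs * config.quota_distortion[dim]
            out[dim] = p / p.sum()
        else:
            out[dim] = probs
    return out


def _draw_levels(u: np.ndarray, probs: np.ndarray, levels: list[int]) -> np.ndarray:
    idx = np.searchsorted(np.cumsum(probs), u, side="right")
    idx = np.clip(idx, 0, len(levels) - 1)
    return np.asarray(levels, dtype=int)[idx]


def _level_index(dim: str, values: np.ndarray) -> np.ndarray:
    levels = DIMENSION_LEVELS[dim]
    return np.asarray(values, dtype=int) - levels[0]


def _linear_predictor(table: pd.DataFrame, intercept: float,
                      effects: dict[str, np.ndarray]) -> np.ndarray:
    eta = np.full(len(table), float(intercept))
    for dim, e in effects.items():
        eta += e[_level_index(dim, table[dim].to_numpy())]
    return eta


def generate_population(config: SyntheticConfig) -> pd.DataFrame:
    """Draw ``n_individuals`` complete records (no missingness yet applied).

    Deterministic under (config, seed).  The IMD/education/occupation triple is
    coupled through the one-factor Gaussian copula with correlation
    ``copula_rho``; all other dimensions are drawn independently.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    probs = _sampling_marginals(config)

    rho = config.copula_rho
    f = rng.standard_normal(n)
    cols: dict[str, np.ndarray] = {}
    for dim in COPULA_DIMS:
        z = math.sqrt(rho) * f + math.sqrt(1.0 - rho) * rng.standard_normal(n)
        cols[dim] = _draw_levels(ndtr(z), probs[dim], DIMENSION_LEVELS[dim])
    for dim in DIMENSION_LEVELS:
        if dim in COPULA_DIMS:
            continue
        cols[dim] = _draw_levels(rng.random(n), probs[dim], DIMENSION_LEVELS[dim])

    table = pd.DataFrame(cols)
    eta = _linear_predictor(table, config.bmi_intercept, config.bmi_effects)
    bmi = eta + config.bmi_residual_sd * rng.standard_normal(n)
    bmi = np.maximum(bmi, BMI_FLOOR)
    table.insert(0, "bmi", bmi)
    table.insert(0, "id", np.arange(n))

    for flag, cut in OUTCOME_CUTPOINTS.items():
        table[flag] = (bmi >= cut).astype(float)
    if config.binary_gradient is not None:
        p = expit(_linear_predictor(table, config.binary_gradient["intercept"],
                                    config.binary_gradient["effects"]))
        table["excess_weight"] = (rng.random(n) < p).astype(float)

    table["design_weight"] = 1.0
    table["responded"] = 1
    return table[_COLUMNS]


def missingness_probability(table: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    """Per-record probability that the BMI measurement is missing (MAR: the
    logit involves observed covariates only, never BMI itself)."""
    if np.isneginf(config.missingness_intercept) and not config.missingness_effects:
        return np.zeros(len(table))
    eta = _linear_predictor(table, config.missingness_intercept, config.missingness_effects)
    p = expit(eta)
    if np.any(p >= 1.0 - 1e-12):
        raise ConfigurationError("missingness logit yields probability ~1 for some cell")
    return p


def impose_missingness(table: pd.DataFrame, config: SyntheticConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Mask BMI (and the BMI-derived flags) at random per the missingness logit.

    Requires a complete-BMI table.  Returns a new table with ``responded`` set
    to 0 for masked records; the realised missing fraction is reported in
    ``table.attrs['missing_fraction']``.
    """
    if table["bmi"].isna().any():
        raise ConfigurationError("impose_missingness expects a complete-BMI table")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    p = missingness_probability(table, config)
    miss = rng.random(len(table)) < p
    out = table.copy()
    out.loc[miss, "bmi"] = np.nan
    for flag in OUTCOME_CUTPOINTS:
        out.loc[miss, flag] = np.nan
    out.loc[miss, "responded"] = 0
    out.attrs["missing_fraction"] = float(miss.mean())
    return out


# ---------------------------------------------------------------------------
# analytic ground truth over the discrete covariate grid
# ---------------------------------------------------------------------------

_AXES = list(DIMENSION_LEVELS)  # fixed axis order of the grid tensors


def _copula_joint(config: SyntheticConfig, marginals: dict[str, np.ndarray],
                  n_nodes: int = 80) -> np.ndarray:
    """Exact joint pmf over the (imd, education, occupation) grid under the
    one-factor Gaussian copula, by Gauss-Hermite quadrature over the factor."""
    rho = config.copula_rho
    shapes = [len(DIMENSION_LEVELS[d]) for d in COPULA_DIMS]
    if rho == 0.0:
        p = np.ones(shapes)
        for ax, dim in enumerate(COPULA_DIMS):
            sh = [1, 1, 1]
            sh[ax] = shapes[ax]
            p = p * marginals[dim].reshape(sh)
        return p
    nodes, wts = np.polynomial.hermite_e.hermegauss(n_nodes)
    wts = wts / math.sqrt(2.0 * math.pi)  # weights of the standard normal factor
    s = math.sqrt(1.0 - rho)
    per_dim = []
    for dim in COPULA_DIMS:
        cum = np.concatenate([[0.0], np.cumsum(marginals[dim])])
        cum[-1] = 1.0
        t = ndtri(np.clip(cum, 0.0, 1.0))  # thresholds, +-inf at the ends
        # P(level | f) for each quadrature node: shape (n_nodes, k)
        z = (t[None, :] - math.sqrt(rho) * nodes[:, None]) / s
        cdf = ndtr(z)
        per_dim.append(np.diff(cdf, axis=1))
    joint = np.einsum("fi,fj,fk,f->ijk", per_dim[0], per_dim[1], per_dim[2], wts)
    joint = np.maximum(joint, 0.0)
    return joint / joint.sum()


def _population_grid(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """(probability tensor, BMI-mean tensor) over the full covariate grid of the
    undistorted population, axes ordered as :data:`DIMENSION_LEVELS`."""
    shapes = [len(DIMENSION_LEVELS[d]) for d in _AXES]
    prob = np.ones(shapes)
    joint3 = _copula_joint(config, config.marginals)  # (imd, edu, occ)
    for ax, dim in enumerate(_AXES):
        if dim in COPULA_DIMS:
            continue
        sh = [1] * len(shapes)
        sh[ax] = shapes[ax]
        prob = prob * config.marginals[dim].reshape(sh)
    i_imd, i_edu, i_occ = (_AXES.index(d) for d in COPULA_DIMS)
    # place joint3 onto the (education, occupation, imd) axes of the big tensor
    full_shape = [1] * len(shapes)
    for src, ax in zip(range(3), (i_imd, i_edu, i_occ)):
        full_shape[ax] = joint3.shape[src]
    jt = np.transpose(joint3, np.argsort([i_imd, i_edu, i_occ]))
    prob = prob * jt.reshape(full_shape)

    mean = np.full(shapes, config.bmi_intercept)
    for ax, dim in enumerate(_AXES):
        sh = [1] * len(shapes)
        sh[ax] = shapes[ax]
        mean = mean + config.bmi_effects[dim].reshape(sh)
    return prob, mean


def _grid_effects(shapes, intercept, effects):
    eta = np.full(shapes, float(intercept))
    for ax, dim in enumerate(_AXES):
        if dim in effects:
            sh = [1] * len(shapes)
            sh[ax] = shapes[ax]
            eta = eta + effects[dim].reshape(sh)
    return eta


def _cci_from_level_stats(p_level: np.ndarray, ey_level: np.ndarray,
                          order: np.ndarray) -> tuple[float, float]:
    """(Erreygers for a binary outcome, Wagstaff) from per-level shares and means.

    ``order`` indexes levels most-deprived-first; ranks ascend toward the least
    deprived, so pro-deprived concentration comes out negative.
    """
    p = p_level[order]
    ey = ey_level[order]
    cw = np.cumsum(p)
    r = cw - p / 2.0
    mu = float(np.sum(p * ey))
    cov = float(np.sum(p * ey * r) - mu * np.sum(p * r))
    err = 8.0 * cov
    wag = np.nan
    if 0.0 < mu < 1.0:
        wag = 2.0 * cov / (mu * (1.0 - mu))
    return err, wag


def _deprivation_order(dim: str) -> np.ndarray:
    """Level indices sorted most-deprived-first (highest code first)."""
    k = len(DIMENSION_LEVELS[dim])
    return np.arange(k)[::-1]


@dataclass(frozen=True)
class GroundTruth:
    """Exact population quantities implied by a :class:`SyntheticConfig`."""

    mean_bmi: float
    prevalence: dict[str, float]          # outcome -> population prevalence
    cci: dict[tuple[str, str], float]     # (outcome, dimension) -> Erreygers CCI
    wagstaff: dict[tuple[str, str], float]
    missing_fraction: float


def ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Exact expectation over the discrete covariate grid (no simulation).

    BMI prevalences use the Gaussian residual model; the mean accounts for the
    12 kg/m^2 floor.  Per-dimension concentration indices use the population
    marginal ranks of each deprivation dimension.
    """
    prob, mean = _population_grid(config)
    sd = config.bmi_residual_sd

    alpha = (BMI_FLOOR - mean) / sd
    cell_mean = mean * (1.0 - ndtr(alpha)) + sd * norm.pdf(alpha) + BMI_FLOOR * ndtr(alpha)
    mean_bmi = float(np.sum(prob * cell_mean))

    outcome_grids: dict[str, np.ndarray] = {}
    for flag, cut in OUTCOME_CUTPOINTS.items():
        outcome_grids[flag] = 1.0 - ndtr((cut - mean) / sd)
    if config.binary_gradient is not None:
        outcome_grids["excess_weight"] = expit(_grid_effects(
            prob.shape, config.binary_gradient["intercept"], config.binary_gradient["effects"]))

    prevalence = {k: float(np.sum(prob * g)) for k, g in outcome_grids.items()}

    cci: dict[tuple[str, str], float] = {}
    wag: dict[tuple[str, str], float] = {}
    for dim in DEPRIVATION_DIMS:
        ax = _AXES.index(dim)
        other = tuple(i for i in range(prob.ndim) if i != ax)
        p_level = prob.sum(axis=other)
        order = _deprivation_order(dim)
        for flag, g in outcome_grids.items():
            ey_level = np.asarray((prob * g).sum(axis=other)) / p_level
            e, w = _cci_from_level_stats(p_level, ey_level, order)
            cci[(flag, dim)] = e
            wag[(flag, dim)] = w

    pm = expit(_grid_effects(prob.shape, config.missingness_intercept,
                             config.missingness_effects)) \
        if not (np.isneginf(config.missingness_intercept) and not config.missingness_effects) \
        else np.zeros(prob.shape)
    missing = float(np.sum(prob * pm))

    return GroundTruth(mean_bmi=mean_bmi, prevalence=prevalence, cci=cci,
                       wagstaff=wag, missing_fraction=missing)


def calibrate_missingness_intercept(config: SyntheticConfig, target: float,
                                    tol: float = 1e-10) -> float:
    """Intercept of the non-response logit such that the population missing
    fraction equals ``target`` exactly, given the configured covariate effects."""
    if not (0.0 < target < 1.0):
        raise ConfigurationError("target missing fraction must be in (0, 1)")
    prob, _ = _population_grid(config)
    eta = _grid_effects(prob.shape, 0.0, config.missingness_effects)

    from scipy.optimize import brentq

    def f(b0):
        return float(np.sum(prob * expit(b0 + eta))) - target

    return float(brentq(f, -30.0, 30.0, xtol=tol))


# ---------------------------------------------------------------------------
# CSV round-trip with versioned sidecar
# ---------------------------------------------------------------------------

def write_survey_csv(table: pd.DataFrame, path: str | Path,
                     config: SyntheticConfig | None = None) -> None:
    """Write the table as plain CSV plus a ``<path>.meta.json`` sidecar holding
    the format version and, if given, the generating config."""
    path = Path(path)
    table.to_csv(path, index=False)
    meta = {"format": FORMAT_VERSION, "n_rows": int(len(table))}
    if config is not None:
        meta["config"] = config.to_dict()
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_survey_csv(path: str | Path) -> tuple[pd.DataFrame, SyntheticConfig | None]:
    path = Path(path)
    table = pd.read_csv(path)
    cfg = None
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("format") != FORMAT_VERSION:
            raise ConfigurationError(f"unsupported survey format {meta.get('format')!r}")
        if "config" in meta:
            cfg = SyntheticConfig.from_dict(meta["config"])
    return table, cfg
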