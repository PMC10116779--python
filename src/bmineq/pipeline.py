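"""End-to-end analysis pipeline: validation, weighting, stratified indices,
decomposition ladder, and a reproducible report.

The run is fully seeded: every stochastic step (bootstrap inference,
decomposition p-values) draws its own child seed from the configured master
seed, so the same config + seed regenerates a byte-identical report payload.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError, DataValidationError, EstimationError
from .synthetic import (BMI_FLOOR, DIMENSION_LEVELS, OUTCOME_CUTPOINTS,
                        SyntheticConfig, generate_population, impose_missingness)
from .weights import (MarginTargets, combine_weights, compute_ipw,
                      fit_response_propensity, rake)
from .indices import BMI_BOUNDS, estimate_index
from .decomposition import SES_DIMENSIONS, specification_ladder

log = logging.getLogger(__name__)

MANDATORY_COLUMNS = [
    "bmi", "region", "age_group", "gender", "ethnicity", "education",
    "occupation", "imd_quintile", "limiting_illness", "marital_status",
    "urbanicity", "design_weight", "responded",
]

#: BMI category labels with half-open [lower, upper) intervals
BMI_CATEGORIES = [
    ("underweight", -np.inf, 18.5),
    ("healthy", 18.5, 25.0),
    ("overweight", 25.0, 30.0),
    ("obesity_1", 30.0, 35.0),
    ("obesity_2", 35.0, 40.0),
    ("obesity_3", 40.0, np.inf),
]

DEFAULT_PROPENSITY_COVARIATES = ["region", "age_group", "gender",
                                "imd_quintile", "limiting_illness"]


def validate_input(path_or_table) -> pd.DataFrame:
    """Typed, codebook-validated survey table from a delimited file.

    Checks mandatory columns, level codes against the codebooks (5 IMD
    quintiles, 6 occupation classes, 8 education levels, ...), positive design
    weights and the responded/BMI consistency rule.  Responder rows with BMI
    below the 12 kg/m^2 floor are excluded (bounds rule) and counted.
    """
    if isinstance(path_or_table, (str, Path)):
        table = pd.read_csv(path_or_table)
    else:
        table = path_or_table.copy()
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise DataValidationError(f"missing mandatory columns: {missing}")
    for dim, levels in DIMENSION_LEVELS.items():
        vals = table[dim].dropna()
        bad = ~vals.isin(levels)
        if bad.any():
            row = int(vals.index[bad][0])
            raise DataValidationError(
                f"row {row}: {dim}={vals[bad].iloc[0]!r} not in allowed levels {levels}")
    if (table["design_weight"] <= 0).any():
        row = int(table.index[table["design_weight"] <= 0][0])
        raise DataValidationError(f"row {row}: non-positive design_weight")
    resp = table["responded"].astype(int)
    bmi_present = table["bmi"].notna()
    if ((resp == 1) != bmi_present).any():
        row = int(table.index[(resp == 1) != bmi_present][0])
        raise DataValidationError(f"row {row}: responded flag inconsistent with BMI presence")
    low = bmi_present & (table["bmi"] < BMI_FLOOR)
    n_drop = int(low.sum())
    if n_drop:
        log.info("excluding %d rows with BMI below %.0f kg/m^2 (bounds rule)", n_drop, BMI_FLOOR)
        table = table[~low]
    log.info("validated %d rows (%d dropped)", len(table), n_drop)
    table = table.reset_index(drop=True)
    table.attrs["n_dropped"] = n_drop
    return table


def derive_outcomes(table: pd.DataFrame) -> pd.DataFrame:
    """BMI category label plus the three nested binary flags.

    Half-open intervals [lower, upper) resolve the boundary overlap of the
    usual ">=" category notation: BMI 25.0 is overweight (excess_weight=1,
    obese=0), 30.0 is obesity I, 18.4 is underweight with all flags 0.
    Underweight records keep flags 0 so they stay in denominators.
    """
    out = table.copy()
    bmi = out["bmi"]
    cat = pd.Series(pd.NA, index=out.index, dtype="object")
    for name, lo, hi in BMI_CATEGORIES:
        cat[(bmi >= lo) & (bmi < hi)] = name
    out["bmi_category"] = cat
    for flag, cut in OUTCOME_CUTPOINTS.items():
        out[flag] = (bmi >= cut).astype(float).where(bmi.notna())
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Declarative description of one full analysis run."""

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    outcomes: tuple[str, ...] = ("excess_weight", "obese", "morbid")
    dimensions: tuple[str, ...] = tuple(SES_DIMENSIONS)
    strata: tuple[str, ...] = ("national",)          # of {national, region, gender}
    variants: tuple[str, ...] = ("erreygers", "wagstaff")
    bootstrap_reps: int = 1000
    decomposition_outcomes: tuple[str, ...] = ()     # subset of outcomes to decompose
    decomposition_dimension: str = "imd_quintile"
    pvalue_reps: int = 0
    seed: int = 0
    min_stratum_n: int = 100
    rank_within_stratum: bool = True
    raking_dimensions: tuple[str, ...] = ()          # empty: infer from synthetic config
    margin_targets_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.input_path is None and self.synthetic is None:
            raise ConfigurationError("need either input_path or a synthetic config")
        if not self.outcomes:
            raise ConfigurationError("need at least one outcome")
        if not self.dimensions:
            raise ConfigurationError("need at least one deprivation dimension")
        bad = set(self.outcomes) - set(OUTCOME_CUTPOINTS)
        if bad:
            raise ConfigurationError(f"unknown outcomes {sorted(bad)}")
        bad = set(self.dimensions) - set(SES_DIMENSIONS)
        if bad:
            raise ConfigurationError(f"unknown dimensions {sorted(bad)}")
        bad = set(self.strata) - {"national", "region", "gender"}
        if bad:
            raise ConfigurationError(f"unknown strata {sorted(bad)}")
        bad = set(self.variants) - {"erreygers", "wagstaff"}
        if bad:
            raise ConfigurationError(f"unknown variants {sorted(bad)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("synthetic"):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        for key in ("outcomes", "dimensions", "strata", "variants",
                    "decomposition_outcomes", "raking_dimensions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """All pipeline outputs plus run metadata; regenerable from config+seed."""

    indices: pd.DataFrame
    decompositions: dict
    bic_tables: dict
    weighting: dict
    skipped: list
    metadata: dict = field(default_factory=dict)

    def to_payload(self) -> dict:
        return {
            "metadata": self.metadata,
            "indices": self.indices.to_dict(orient="records"),
            "decompositions": self.decompositions,
            "bic": {k: v.to_dict(orient="records") for k, v in self.bic_tables.items()},
            "weighting": self.weighting,
            "skipped": self.skipped,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_payload(), sort_keys=True, indent=1, default=float)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.indices.to_csv(out / "indices.csv", index=False)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _strata_iter(table: pd.DataFrame, strata: tuple[str, ...]):
    for kind in strata:
        if kind == "national":
            yield {"stratum": "national", "value": "england"}, np.ones(len(table), bool)
        elif kind == "region":
            for r in sorted(table["region"].unique()):
                yield {"stratum": "region", "value": int(r)}, (table["region"] == r).to_numpy()
        elif kind == "gender":
            for g in sorted(table["gender"].unique()):
                yield {"stratum": "gender", "value": int(g)}, (table["gender"] == g).to_numpy()


def prepare_weighted_table(config: AnalysisConfig) -> tuple[pd.DataFrame, dict]:
    """Load or simulate, validate, derive outcomes and attach combined weights.

    Returns the responder table (column ``combined_weight``) and weighting
    diagnostics.
    """
    if config.synthetic is not None:
        full = generate_population(config.synthetic)
        table = impose_missingness(full, config.synthetic)
        miss_frac = table.attrs.get("missing_fraction", 0.0)
    else:
        table = pd.read_csv(config.input_path)
        miss_frac = float(1 - table["responded"].mean())
    table = validate_input(table)
    simulated_flag = None
    if config.synthetic is not None and config.synthetic.binary_gradient is not None:
        # excess_weight was simulated directly; don't overwrite it from BMI
        simulated_flag = table["excess_weight"].copy()
    table = derive_outcomes(table)
    if simulated_flag is not None:
        table["excess_weight"] = simulated_flag

    prop = fit_response_propensity(table, DEFAULT_PROPENSITY_COVARIATES)
    ipw = compute_ipw(prop, table["responded"].to_numpy())

    rake_dims = tuple(config.raking_dimensions)
    targets = None
    if config.margin_targets_path:
        targets = MarginTargets.from_csv(config.margin_targets_path)
    elif config.synthetic is not None:
        if not rake_dims and config.synthetic.quota_distortion:
            rake_dims = tuple(config.synthetic.quota_distortion)
        if rake_dims:
            targets = MarginTargets.from_config(config.synthetic, rake_dims)
    diag = {"missing_fraction": miss_frac, "n_records": int(len(table)),
            "n_responders": int(table["responded"].sum())}
    if targets is not None:
        raking, rep = rake(table, table["design_weight"].to_numpy() * ipw, targets)
        diag["raking"] = {"iterations": rep.iterations,
                          "max_deviation": rep.max_deviation,
                          "dimensions": list(targets.targets)}
    else:
        raking = np.ones(len(table))
        diag["raking"] = None
    wv = combine_weights(table["design_weight"].to_numpy(), ipw, raking)
    diag["n_capped"] = wv.n_capped
    table["combined_weight"] = wv.combined_weight
    resp = table[table["responded"] == 1].reset_index(drop=True)
    return resp, diag


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Weighting -> ranking -> stratified indices -> decomposition ladder.

    Strata with fewer responders than ``min_stratum_n`` are skipped with a
    logged reason rather than silently dropped.  Fractional ranks are
    recomputed within each stratum by default.
    """
    ss = np.random.SeedSequence(config.seed)
    seed_idx = iter(range(10 ** 6))

    resp, diag = prepare_weighted_table(config)
    w = resp["combined_weight"].to_numpy()

    national_ranks: dict[str, np.ndarray] = {}
    if not config.rank_within_stratum:
        from .indices import weighted_fractional_rank
        for dim in config.dimensions:
            national_ranks[dim] = weighted_fractional_rank(resp[dim].to_numpy(), w)

    rows = []
    skipped = []
    for stratum, mask in _strata_iter(resp, config.strata):
        n = int(mask.sum())
        if n < config.min_stratum_n:
            skipped.append({**stratum, "n": n, "reason": f"n < {config.min_stratum_n}"})
            log.info("skipping stratum %s (n=%d)", stratum, n)
            continue
        sub = resp[mask]
        wsub = w[mask]
        for dim in config.dimensions:
            for outcome in config.outcomes:
                for variant in config.variants:
                    child = np.random.SeedSequence([config.seed, next(seed_idx)])
                    try:
                        if config.rank_within_stratum:
                            est = estimate_index(
                                sub[outcome].to_numpy(), sub[dim].to_numpy(), wsub,
                                variant=variant, bounds=(0.0, 1.0),
                                inference="bootstrap", reps=config.bootstrap_reps,
                                seed=child, stratum=stratum)
                        else:
                            # national ranks held fixed within the stratum;
                            # delta-method SE (bootstrap would re-rank locally)
                            from .indices import (RankedVector, cci_inference,
                                                  erreygers_cci, wagstaff_ci)
                            v = RankedVector(y=sub[outcome].to_numpy(), w=wsub,
                                             r=national_ranks[dim][mask],
                                             a=0.0, b=1.0)
                            est = erreygers_cci(v) if variant == "erreygers" else wagstaff_ci(v)
                            est.se, est.p_value = cci_inference(v, variant, method="delta")
                            est.stratum = stratum
                    except EstimationError as exc:
                        skipped.append({**stratum, "dimension": dim, "outcome": outcome,
                                        "variant": variant, "n": n, "reason": str(exc)})
                        continue
                    rows.append({**stratum, "dimension": dim, "outcome": outcome,
                                 "variant": variant, "index_value": est.value,
                                 "se": est.se, "p_value": est.p_value,
                                 "n": n, "n_effective": est.n_effective})
    indices = pd.DataFrame(rows)

    decomps: dict = {}
    bic_tables: dict = {}
    for outcome in (config.decomposition_outcomes or ()):
        child = np.random.SeedSequence([config.seed, next(seed_idx)])
        results, bic_df = specification_ladder(
            resp, outcome, ses_dimension=config.decomposition_dimension,
            weights=w, pvalue_reps=config.pvalue_reps, seed=child)
        decomps[outcome] = {
            str(sid): {
                "DI": r.di,
                "factors": list(r.factors),
                "shapley_value": r.shapley_values,
                "contrib_percent": r.contrib_percent,
                "p_value": r.p_values,
                "n": r.n_observations,
            } for sid, r in results.items()
        }
        bic_tables[outcome] = bic_df

    meta = {"seed": config.seed, "config_hash": config.content_hash(),
            "package_version": __version__,
            "source": "synthetic" if config.synthetic is not None else config.input_path}
    report = AnalysisReport(indices=indices, decompositions=decomps,
                            bic_tables=bic_tables, weighting=diag,
                            skipped=skipped, metadata=meta)
    if config.out_dir:
        report.write(config.out_dir)
    return report


def compare_variants(report: AnalysisReport) -> dict:
    """Concordance of Erreygers vs Wagstaff across report rows: per-row sign
    agreement and the Spearman rank correlation of the two value series."""
    from scipy.stats import spearmanr

    df = report.indices
    have = set(df["variant"].unique()) if len(df) else set()
    if not {"erreygers", "wagstaff"} <= have:
        raise ConfigurationError("report must contain both index variants")
    keys = [c for c in ("stratum", "value", "dimension", "outcome") if c in df.columns]
    wide = df.pivot_table(index=keys, columns="variant", values="index_value").dropna()
    e = wide["erreygers"].to_numpy()
    g = wide["wagstaff"].to_numpy()
    agree = float(np.mean(np.sign(e) == np.sign(g)))
    # rank correlation within outcome: the Wagstaff prevalence normalisation
    # differs across outcomes, so pooling them would conflate scales
    rhos = []
    grouper = wide.groupby("outcome") if "outcome" in keys else [(None, wide)]
    for _, grp in grouper:
        if len(grp) > 2:
            rhos.append(spearmanr(grp["erreygers"], grp["wagstaff"]).statistic)
    rho = float(np.mean(rhos)) if rhos else np.nan
    # concordance is meaningless when both indices sit inside sampling noise
    if "se" in df.columns and df["se"].notna().any():
        med_se = float(df.loc[df["variant"] == "erreygers", "se"].median())
        unstable = bool(np.median(np.abs(e)) < 2.0 * med_se)
    else:
        unstable = bool(np.max(np.abs(e), initial=0.0) < 0.01)
    return {"n_rows": int(len(e)), "sign_agreement": agree,
            "rank_correlation": rho, "unstable": unstable}
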