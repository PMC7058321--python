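"""Synthetic two-arm trial generator.

Emulates the structure of a Swedish university-student smoking-cessation
trial: 1590 participants randomized 827:763 to a text-messaging intervention
versus a waiting-list control, ~70% female, and a binary prolonged-abstinence
outcome with marginal prevalence ~25.9% under intervention and ~14.6% under
control.  Covariates are drawn from invented but plausible distributions
(the source trial's covariate marginals were never published): years smoked
and weekly cigarettes are log-normal, and the ordered dependence and
snuff-use categories are weakly coupled to smoking quantity through a shared
latent factor.

Outcomes are drawn from a logistic model on the dummy-encoded covariates —
exactly the structural form the analysis model assumes — optionally with
group-by-covariate interaction terms for effect-modification scenarios.
``calibrate_intercept_and_group_effect`` solves for the intercept and group
log-odds that reproduce the two target marginal prevalences by averaging the
inverse logit over the covariate distribution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .trial_data import (
    DEFAULT_SCHEMA,
    TRIAL_N_INTERVENTION,
    TRIAL_N_TOTAL,
    TRIAL_PREV_CONTROL,
    TRIAL_PREV_INTERVENTION,
    TrialRecord,
    TrialSchema,
    write_trial_csv,
)

__all__ = [
    "SyntheticTrialConfig",
    "default_trial_config",
    "generate_trial",
    "calibrate_intercept_and_group_effect",
    "monte_carlo_prevalences",
    "true_event_probability",
    "write_trial",
]

# Fixed stream for the calibration/marginalization covariate sample, so that
# calibrated configs are reproducible regardless of the trial seed.
_CALIBRATION_SEED = 20200305
_CALIBRATION_DRAWS = 200_000

# Invented defaults: modest covariate effects on the log-odds scale (raw
# covariate units), giving realistic spread in baseline risk without any
# single covariate dominating.
_DEFAULT_COEFFICIENTS: Mapping[str, float] = {
    "sex": 0.15,
    "years_smoked": -0.03,
    "weekly_cigs": -0.008,
    "dependence_2": -0.15,
    "dependence_3": -0.30,
    "dependence_4": -0.45,
    "dependence_5": -0.60,
    "snuff_2": 0.10,
    "snuff_3": 0.10,
    "snuff_4": 0.10,
}


@dataclass(frozen=True)
class SyntheticTrialConfig:
    """Generating model for a synthetic two-arm trial.

    ``true_coefficients`` maps encoded predictor names (``sex``,
    ``years_smoked``, ``weekly_cigs``, ``dependence_2`` .. ``dependence_5``,
    ``snuff_2`` .. ``snuff_4``) plus the special keys ``intercept`` and
    ``group`` to log-odds values on the raw covariate scale.
    ``interaction_terms`` maps a predictor name to a log-odds modifier added
    as ``value * x_predictor`` for intervention-arm participants only; with
    it empty, the generating model has a single constant conditional odds
    ratio for group.
    """

    n_total: int = TRIAL_N_TOTAL
    n_intervention: int = TRIAL_N_INTERVENTION
    prop_female: float = 0.70
    years_smoked_dist: tuple[float, float] = (5.0, 3.0)
    weekly_cigs_dist: tuple[float, float] = (50.0, 30.0)
    n_dependence_levels: int = 5
    n_snuff_levels: int = 4
    dependence_probs: tuple[float, ...] = (0.25, 0.25, 0.20, 0.20, 0.10)
    snuff_probs: tuple[float, ...] = (0.55, 0.20, 0.15, 0.10)
    dependence_latent_corr: float = 0.5
    snuff_latent_corr: float = 0.2
    true_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COEFFICIENTS)
    )
    target_control_prevalence: float = TRIAL_PREV_CONTROL
    target_intervention_prevalence: float = TRIAL_PREV_INTERVENTION
    interaction_terms: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 <= self.n_intervention <= self.n_total:
            raise ValueError("n_intervention must satisfy 0 <= n_intervention <= n_total")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ValueError("prop_female must lie in [0, 1]")
        for name in ("years_smoked_dist", "weekly_cigs_dist"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd <= 0:
                raise ValueError(f"{name} must have positive mean and sd")
        if self.n_dependence_levels < 2:
            raise ValueError("n_dependence_levels must be >= 2")
        if self.n_snuff_levels < 2:
            raise ValueError("n_snuff_levels must be >= 2")
        for name, probs, k in (
            ("dependence_probs", self.dependence_probs, self.n_dependence_levels),
            ("snuff_probs", self.snuff_probs, self.n_snuff_levels),
        ):
            if len(probs) != k:
                raise ValueError(f"{name} must have exactly {k} entries")
            if any(p < 0 for p in probs) or not np.isclose(sum(probs), 1.0):
                raise ValueError(f"{name} must be a probability vector")
        for name in ("target_control_prevalence", "target_intervention_prevalence"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        known = set(_encoded_predictor_names(self)) | {"intercept", "group"}
        unknown = set(self.true_coefficients) - known
        if unknown:
            raise ValueError(f"true_coefficients has unknown predictor(s) {sorted(unknown)}")
        unknown_int = set(self.interaction_terms) - set(_encoded_predictor_names(self))
        if unknown_int:
            raise ValueError(f"interaction_terms has unknown predictor(s) {sorted(unknown_int)}")

    def schema(self) -> TrialSchema:
        if (self.n_dependence_levels, self.n_snuff_levels) == (5, 4):
            return DEFAULT_SCHEMA
        from .trial_data import ColumnSpec

        return TrialSchema(
            predictors=(
                ColumnSpec("group", "binary"),
                ColumnSpec("sex", "binary"),
                ColumnSpec("years_smoked", "continuous"),
                ColumnSpec("weekly_cigs", "continuous"),
                ColumnSpec("dependence", "categorical", tuple(range(1, self.n_dependence_levels + 1))),
                ColumnSpec("snuff", "categorical", tuple(range(1, self.n_snuff_levels + 1))),
            )
        )


def _encoded_predictor_names(config: SyntheticTrialConfig) -> list[str]:
    names = ["sex", "years_smoked", "weekly_cigs"]
    names += [f"dependence_{lv}" for lv in range(2, config.n_dependence_levels + 1)]
    names += [f"snuff_{lv}" for lv in range(2, config.n_snuff_levels + 1)]
    return names


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _categorical_from_latent(
    z: np.ndarray, probs: tuple[float, ...]
) -> np.ndarray:
    """Cut a standard-normal latent at Gaussian quantiles of the cumulative
    category probabilities, preserving the marginal distribution exactly."""
    cuts = norm.ppf(np.cumsum(probs[:-1]))
    return 1 + np.searchsorted(cuts, z, side="left").astype(int)


def _draw_covariates(config: SyntheticTrialConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    sex = (rng.random(n) < config.prop_female).astype(int)
    mu_y, sig_y = _lognormal_params(*config.years_smoked_dist)
    years = rng.lognormal(mean=mu_y, sigma=sig_y, size=n)
    mu_w, sig_w = _lognormal_params(*config.weekly_cigs_dist)
    weekly = rng.lognormal(mean=mu_w, sigma=sig_w, size=n)
    # log(weekly) is exactly normal, so its z-score is an exact N(0,1) latent.
    z_w = (np.log(weekly) - mu_w) / sig_w
    rho_d, rho_u = config.dependence_latent_corr, config.snuff_latent_corr
    z_dep = rho_d * z_w + np.sqrt(1.0 - rho_d**2) * rng.standard_normal(n)
    z_snf = rho_u * z_w + np.sqrt(1.0 - rho_u**2) * rng.standard_normal(n)
    dependence = _categorical_from_latent(z_dep, config.dependence_probs)
    snuff = _categorical_from_latent(z_snf, config.snuff_probs)
    return pd.DataFrame(
        {
            "sex": sex,
            "years_smoked": years,
            "weekly_cigs": weekly,
            "dependence": dependence,
            "snuff": snuff,
        }
    )


def _encoded_column(covariates: pd.DataFrame, name: str) -> np.ndarray:
    if name in covariates.columns:
        return covariates[name].to_numpy(dtype=float)
    base, _, level = name.rpartition("_")
    if base in covariates.columns and level.isdigit():
        return (covariates[base].to_numpy() == int(level)).astype(float)
    raise KeyError(name)


def _base_linear_predictor(config: SyntheticTrialConfig, covariates: pd.DataFrame) -> np.ndarray:
    """Covariate contribution to the log-odds, excluding intercept and group."""
    eta = np.zeros(len(covariates))
    for name, coef in config.true_coefficients.items():
        if name in ("intercept", "group"):
            continue
        eta += coef * _encoded_column(covariates, name)
    return eta


def _interaction_predictor(config: SyntheticTrialConfig, covariates: pd.DataFrame) -> np.ndarray:
    eta = np.zeros(len(covariates))
    for name, coef in config.interaction_terms.items():
        eta += coef * _encoded_column(covariates, name)
    return eta


def true_event_probability(
    config: SyntheticTrialConfig, covariates: pd.DataFrame, group: int
) -> np.ndarray:
    """Generating-model outcome probability for given covariate rows and arm."""
    coefs = config.true_coefficients
    eta = coefs.get("intercept", 0.0) + _base_linear_predictor(config, covariates)
    if group == 1:
        eta = eta + coefs.get("group", 0.0) + _interaction_predictor(config, covariates)
    return expit(eta)


def calibrate_intercept_and_group_effect(
    config: SyntheticTrialConfig,
) -> tuple[float, float]:
    """Solve for (intercept, group coefficient) hitting the target marginal
    prevalences.

    The marginal prevalence under each arm is the inverse logit averaged over
    the covariate distribution (a fixed 200k-draw Monte Carlo sample of
    covariates).  The control target pins the intercept and the intervention
    target then pins the group coefficient; each is found by 1-D root finding
    to |prevalence error| < 1e-4.
    """
    p0, p1 = config.target_control_prevalence, config.target_intervention_prevalence
    for label, p in (("target_control_prevalence", p0), ("target_intervention_prevalence", p1)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{label} must lie strictly in (0, 1) for calibration, got {p}")

    rng = np.random.default_rng(_CALIBRATION_SEED)
    cov = _draw_covariates(config, _CALIBRATION_DRAWS, rng)
    base = _base_linear_predictor(config, cov)
    inter = _interaction_predictor(config, cov)

    def solve(target: float, offset: np.ndarray) -> float:
        f = lambda c: float(np.mean(expit(c + offset))) - target
        lo, hi = -40.0, 40.0
        if f(lo) > 0 or f(hi) < 0:
            raise RuntimeError("calibration root finder failed to bracket the target")
        return float(brentq(f, lo, hi, xtol=1e-10))

    intercept = solve(p0, base)
    group_coef = solve(p1, intercept + base + inter)
    return intercept, group_coef


def default_trial_config(seed: int = 0, **overrides) -> SyntheticTrialConfig:
    """The calibrated default trial: published arm sizes and prevalences,
    invented covariate structure, intercept and group effect solved to hit
    14.6% / 25.9% marginal abstinence."""
    config = SyntheticTrialConfig(seed=seed, **overrides)
    intercept, group_coef = calibrate_intercept_and_group_effect(config)
    coefs = dict(config.true_coefficients)
    coefs["intercept"] = intercept
    coefs["group"] = group_coef
    return dataclasses.replace(config, true_coefficients=coefs)


def generate_trial(config: SyntheticTrialConfig) -> list[TrialRecord]:
    """Draw one synthetic trial table.

    Arm sizes are exact (a seeded permutation of a fixed allocation vector),
    covariates follow the config's distributions, and the outcome is
    Bernoulli with log-odds given by the config's generating model.  The
    same config (including seed) always yields the identical table.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    group = np.zeros(n, dtype=int)
    group[: config.n_intervention] = 1
    group = rng.permutation(group)
    cov = _draw_covariates(config, n, rng)

    coefs = config.true_coefficients
    eta = (
        coefs.get("intercept", 0.0)
        + _base_linear_predictor(config, cov)
        + group * (coefs.get("group", 0.0) + _interaction_predictor(config, cov))
    )
    outcome = (rng.random(n) < expit(eta)).astype(int)

    return [
        TrialRecord(
            group=int(group[i]),
            sex=int(cov["sex"].iat[i]),
            years_smoked=float(cov["years_smoked"].iat[i]),
            weekly_cigs=float(cov["weekly_cigs"].iat[i]),
            dependence=int(cov["dependence"].iat[i]),
            snuff=int(cov["snuff"].iat[i]),
            outcome=int(outcome[i]),
        )
        for i in range(n)
    ]


def monte_carlo_prevalences(
    config: SyntheticTrialConfig, n: int = 1_000_000, seed: int = _CALIBRATION_SEED
) -> tuple[float, float]:
    """Brute-force marginalization oracle: (control, intervention) prevalence
    averaged over ``n`` fresh covariate draws."""
    rng = np.random.default_rng(seed)
    cov = _draw_covariates(config, n, rng)
    p_ctrl = float(np.mean(true_event_probability(config, cov, group=0)))
    p_trt = float(np.mean(true_event_probability(config, cov, group=1)))
    return p_ctrl, p_trt


def write_trial(records, path, config: SyntheticTrialConfig | None = None) -> None:
    """Write the table as CSV; if a config is given, also write a JSON
    sidecar (same stem, ``.config.json``) recording it, seed included."""
    write_trial_csv(records, path)
    if config is not None:
        sidecar = str(path).rsplit(".", 1)[0] + ".config.json"
        payload = dataclasses.asdict(config)
        payload["true_coefficients"] = dict(config.true_coefficients)
        payload["interaction_terms"] = dict(config.interaction_terms)
        with open(sidecar, "w") as fh:
            json.dump(payload, fh, indent=2, default=list)
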