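"""Bayesian logistic regression with horseshoe shrinkage priors.

The outcome model is

    y_i ~ Bernoulli(p_i),   logit(p_i) = beta0 + x_i' beta,
    beta0 ~ Student-t(df=7, 0, 2.5),
    beta_k | tau, lambda_k ~ Normal(0, (tau * lambda_k)^2),
    lambda_k ~ Half-Cauchy(0, 1),
    tau ~ Half-Cauchy(0, tau0),

the plain (non-regularized) horseshoe: the global scale tau shrinks all
coefficients towards zero while the heavy-tailed local scales lambda_k let
individual coefficients escape.  tau * lambda_k is the prior *standard
deviation* of beta_k.  The prior scale of the global parameter is

    tau0 = p0 / (K - p0) * 2 / sqrt(N),

where p0 is the number of coefficients believed a priori to be effectively
nonzero, K the number of predictor columns and N the number of records; the
constant 2 is the pseudo-standard-deviation of a Bernoulli observation.
This module exposes the densities as pure functions so that any sampler can
target ``log_likelihood + log_prior``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .trial_data import DesignMatrix

__all__ = [
    "HorseshoeConfig",
    "ModelParameters",
    "default_p0",
    "compute_tau0",
    "log_likelihood",
    "log_prior",
    "half_cauchy_logpdf",
]


@dataclass(frozen=True)
class HorseshoeConfig:
    """Prior hyperparameters for one model fit.

    tau0_rule selects the reading of the global-scale formula:
    "two-over-sqrt-n" (default, the pseudo-variance recommendation) or
    "two-over-n".  half_cauchy_scale_squared switches the prior on tau from
    Half-Cauchy(scale=tau0) (default) to Half-Cauchy(scale=tau0^2).
    """

    p0: int
    K: int
    N: int
    tau0: float | None = None
    intercept_df: float = 7.0
    intercept_scale: float = 2.5
    tau0_rule: str = "two-over-sqrt-n"
    half_cauchy_scale_squared: bool = False

    def __post_init__(self) -> None:
        if self.K >= 1 and self.tau0 is None and not 0 < self.p0 < self.K:
            raise ValueError("p0 must satisfy 0 < p0 < K")
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.tau0 is not None and self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        if self.intercept_df <= 0 or self.intercept_scale <= 0:
            raise ValueError("intercept prior df and scale must be positive")
        if self.tau0_rule not in ("two-over-sqrt-n", "two-over-n"):
            raise ValueError(f"unknown tau0_rule {self.tau0_rule!r}")

    @property
    def global_scale(self) -> float:
        """tau0 (computed from p0, K, N unless given explicitly)."""
        tau0 = self.tau0
        if tau0 is None:
            tau0 = compute_tau0(self.p0, self.K, self.N, rule=self.tau0_rule)
        return tau0

    @property
    def tau_prior_scale(self) -> float:
        """The scale actually handed to the half-Cauchy prior on tau."""
        s = self.global_scale
        return s * s if self.half_cauchy_scale_squared else s

    @classmethod
    def for_design(cls, design: DesignMatrix, p0: int | None = None, **kwargs) -> "HorseshoeConfig":
        k = design.k
        return cls(p0=p0 if p0 is not None else default_p0(k), K=k, N=design.n, **kwargs)


@dataclass(frozen=True)
class ModelParameters:
    """One point in parameter space: intercept, coefficients, scales."""

    beta0: float
    beta: np.ndarray
    tau: float
    lam: np.ndarray

    def __post_init__(self) -> None:
        if np.shape(self.beta) != np.shape(self.lam):
            raise ValueError("beta and lam must have equal length")


def default_p0(K: int) -> int:
    """Default prior count of effectively nonzero coefficients: half the
    predictor columns, rounded up — a neutral stance between 'none matter'
    and 'all matter'."""
    if K < 2:
        raise ValueError("K must be >= 2")
    return math.ceil(K / 2)


def compute_tau0(p0: int, K: int, N: int, rule: str = "two-over-sqrt-n") -> float:
    """Global-scale prior hyperparameter tau0 = p0/(K-p0) * 2/sqrt(N)."""
    if not 0 < p0 < K:
        raise ValueError("p0 must satisfy 0 < p0 < K")
    if N <= 0:
        raise ValueError("N must be positive")
    ratio = p0 / (K - p0)
    if rule == "two-over-sqrt-n":
        return ratio * 2.0 / math.sqrt(N)
    if rule == "two-over-n":
        return ratio * 2.0 / N
    raise ValueError(f"unknown tau0_rule {rule!r}")


def log_likelihood(params: ModelParameters, design: DesignMatrix) -> float:
    """Bernoulli-logit log likelihood, overflow-safe.

    sum_i [ y_i eta_i - log(1 + exp(eta_i)) ] with eta_i = beta0 + x_i'beta;
    the log-sum term is evaluated as logaddexp(0, eta).
    """
    beta = np.asarray(params.beta, dtype=float)
    if beta.shape[0] != design.k:
        raise ValueError(f"beta has length {beta.shape[0]}, design has K={design.k}")
    eta = params.beta0 + design.X @ beta
    return float(np.sum(design.y * eta - np.logaddexp(0.0, eta)))


def _student_t_logpdf(x: float, df: float, scale: float) -> float:
    z = x / scale
    return float(
        gammaln((df + 1) / 2) - gammaln(df / 2)
        - 0.5 * math.log(df * math.pi) - math.log(scale)
        - (df + 1) / 2 * math.log1p(z * z / df)
    )


def half_cauchy_logpdf(x: np.ndarray | float, scale: float) -> np.ndarray | float:
    """log density 2 / (pi * scale * (1 + (x/scale)^2)) on x > 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        math.log(2.0 / (math.pi * scale)) - np.log1p((x / scale) ** 2),
        -np.inf,
    )
    return float(out) if out.ndim == 0 else out


def log_prior(params: ModelParameters, config: HorseshoeConfig) -> float:
    """Joint log prior density of (beta0, beta, tau, lambda).

    Returns -inf (rather than raising) when tau or any lambda is
    non-positive, so samplers can treat support violations as rejections.
    """
    beta = np.asarray(params.beta, dtype=float)
    lam = np.asarray(params.lam, dtype=float)
    if beta.shape[0] != config.K:
        raise ValueError(f"beta has length {beta.shape[0]}, config has K={config.K}")
    if params.tau <= 0 or np.any(lam <= 0):
        return -math.inf

    total = _student_t_logpdf(params.beta0, config.intercept_df, config.intercept_scale)
    sd = params.tau * lam
    total += float(np.sum(-0.5 * math.log(2 * math.pi) - np.log(sd) - 0.5 * (beta / sd) ** 2))
    total += float(np.sum(half_cauchy_logpdf(lam, 1.0)))
    total += float(half_cauchy_logpdf(params.tau, config.tau_prior_scale))
    return total
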