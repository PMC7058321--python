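"""Cross-validated held-out prediction and calibration assessment.

The assessment procedure: randomly partition participants into ten folds,
and for each fold fit the model on the other nine (the learning data,
~90%), then predict the held-out tenth (the testing data) — so that every
participant receives exactly one held-out predicted probability.
Standardization parameters and posterior draws for a fold depend only on
its learning data; held-out rows are transformed with the stored
learning-set moments, never re-fitted.

Calibration is then read off the pooled held-out predictions two ways:
ten equal-width probability bins (mean prediction vs. empirical outcome
rate per bin), and a lowess smooth of outcome against prediction — in
effect infinitely many bins.  A per-fold maximum-likelihood logistic fit
of the same model (no priors) serves as comparator; its plug-in
predictions are characteristically over-dispersed relative to the
posterior-predictive ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .horseshoe_model import HorseshoeConfig
from .posterior_inference import PosteriorDraws, predictive_probabilities, sample_posterior
from .trial_data import DesignMatrix, Standardizer, TrialSchema, encode_design, records_to_frame

__all__ = [
    "FoldPlan",
    "FoldFit",
    "CrossvalResult",
    "CalibrationResult",
    "make_fold_plan",
    "run_crossval",
    "crossval_predict",
    "mle_comparator_predict",
    "bin_calibration",
    "lowess_calibration",
    "assess_calibration",
    "calibration_report",
    "plot_reliability",
    "fold_seed",
]

DEFAULT_N_FOLDS = 10
DEFAULT_LOWESS_FRAC = 2.0 / 3.0
# No robustness iterations: with a binary outcome, every y=1 residual looks
# like an outlier to the robustifying weights, which drags the smooth toward
# zero. Plain weighted local regression is the standard choice for binary
# calibration curves.
DEFAULT_LOWESS_IT = 0


# ---------------------------------------------------------------------------
# Fold plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Partition of n participants into F folds (labels 1..F)."""

    n: int
    fold_assignment: np.ndarray
    f: int
    seed: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.fold_assignment)
        if labels.shape != (self.n,):
            raise ValueError("fold_assignment must have length n")
        sizes = np.bincount(labels, minlength=self.f + 1)[1:]
        if sizes.sum() != self.n or (labels < 1).any() or (labels > self.f).any():
            raise ValueError("every participant must belong to exactly one fold in 1..F")
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes may differ by at most one")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignment == fold)

    def learn_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignment != fold)


def make_fold_plan(n: int, f: int = DEFAULT_N_FOLDS, seed: int = 0) -> FoldPlan:
    """Uniformly random partition into F near-equal folds (sizes differ by
    at most one); reproducible from the seed."""
    if not 2 <= f <= n:
        raise ValueError(f"need 2 <= F <= n, got F={f}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    base, extra = divmod(n, f)
    start = 0
    for fold in range(1, f + 1):
        size = base + (1 if fold <= extra else 0)
        labels[perm[start : start + size]] = fold
        start += size
    return FoldPlan(n=n, fold_assignment=labels, f=f, seed=seed)


def fold_seed(seed: int, fold: int) -> int:
    """Deterministic per-fold sampler seed derived from (master seed, fold)."""
    return int(np.random.SeedSequence([int(seed), int(fold)]).generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# Cross-validated Bayesian prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldFit:
    """Everything learned from one fold's learning data."""

    fold: int
    test_indices: np.ndarray
    draws: PosteriorDraws
    standardizer: Standardizer | None
    config: HorseshoeConfig


@dataclass(frozen=True)
class CrossvalResult:
    """Per-participant held-out predictions plus the per-fold fits."""

    predictions: pd.DataFrame  # columns: participant, fold, p_hat, outcome
    fold_fits: tuple[FoldFit, ...]
    schema: TrialSchema


def _fold_designs(frame, plan, fold, schema):
    learn_idx = plan.learn_indices(fold)
    test_idx = plan.test_indices(fold)
    learn = encode_design(frame.iloc[learn_idx], schema)
    test = encode_design(frame.iloc[test_idx], schema, standardizer=learn.standardizer)
    return learn_idx, test_idx, learn, test


def run_crossval(
    records,
    plan: FoldPlan,
    config: HorseshoeConfig | None = None,
    n_draws: int = 500,
    seed: int = 0,
    schema: TrialSchema | None = None,
) -> CrossvalResult:
    """Fit the horseshoe model once per fold and predict its held-out rows.

    With ``config=None`` (the default) each fold gets its own prior scaled
    to its learning data: K from the encoded design, N the learning-set
    size, p0 = ceil(K/2) and tau0 from those.  An explicit config is used
    verbatim for every fold.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if schema is None:
        from .trial_data import DEFAULT_SCHEMA

        schema = DEFAULT_SCHEMA
    if plan.n != len(frame):
        raise ValueError(f"plan covers {plan.n} participants, records have {len(frame)}")

    rows = []
    fits = []
    for fold in range(1, plan.f + 1):
        _, test_idx, learn, test = _fold_designs(frame, plan, fold, schema)
        fold_config = config if config is not None else HorseshoeConfig.for_design(learn)
        try:
            draws = sample_posterior(learn, fold_config, n_draws=n_draws, seed=fold_seed(seed, fold))
        except ValueError as exc:
            raise ValueError(f"fold {fold}: {exc}") from exc
        p_hat = predictive_probabilities(draws, test.X)
        fits.append(FoldFit(fold=fold, test_indices=test_idx, draws=draws,
                            standardizer=learn.standardizer, config=fold_config))
        for i, idx in enumerate(test_idx):
            rows.append((int(idx), fold, float(p_hat[i]), int(test.y[i])))

    preds = (
        pd.DataFrame(rows, columns=["participant", "fold", "p_hat", "outcome"])
        .sort_values("participant")
        .reset_index(drop=True)
    )
    return CrossvalResult(predictions=preds, fold_fits=tuple(fits), schema=schema)


def crossval_predict(
    records,
    plan: FoldPlan,
    config: HorseshoeConfig | None = None,
    n_draws: int = 500,
    seed: int = 0,
    schema: TrialSchema | None = None,
) -> pd.DataFrame:
    """Held-out posterior-predictive probability for every participant."""
    return run_crossval(records, plan, config, n_draws, seed, schema).predictions


# ---------------------------------------------------------------------------
# Maximum-likelihood comparator
# ---------------------------------------------------------------------------

_SEPARATION_COEF = 20.0  # |coefficient| beyond which a fold is treated as separated


def mle_comparator_predict(
    records,
    plan: FoldPlan,
    seed: int = 0,
    schema: TrialSchema | None = None,
) -> pd.DataFrame:
    """Per-fold maximum-likelihood logistic fit (same model, no priors),
    plug-in probabilities for the held-out rows.

    A fold showing (quasi-)separation — non-convergence or coefficients of
    implausible magnitude — is flagged with a warning and its predictions
    are clipped to [0.001, 0.999].
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if schema is None:
        from .trial_data import DEFAULT_SCHEMA

        schema = DEFAULT_SCHEMA
    rows = []
    for fold in range(1, plan.f + 1):
        _, test_idx, learn, test = _fold_designs(frame, plan, fold, schema)
        exog = sm.add_constant(learn.X, has_constant="add")
        separated = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                fit = sm.GLM(learn.y, exog, family=sm.families.Binomial()).fit(maxiter=200)
                params = np.asarray(fit.params)
                converged = bool(getattr(fit, "converged", True))
            except Exception:  # e.g. PerfectSeparationError
                params, converged = None, False
            if params is None or not converged or np.max(np.abs(params)) > _SEPARATION_COEF:
                separated = True
        if separated and params is None:
            # fall back to a barely-regularized fit so predictions still exist
            fit = sm.Logit(learn.y, exog).fit_regularized(alpha=1e-4, disp=0)
            params = np.asarray(fit.params)
        eta = sm.add_constant(test.X, has_constant="add") @ params
        p_hat = 1.0 / (1.0 + np.exp(-eta))
        if separated:
            warnings.warn(
                f"fold {fold}: (quasi-)separation in maximum-likelihood fit; "
                "predictions clipped to [0.001, 0.999]",
                category=UserWarning,
                stacklevel=2,
            )
            p_hat = np.clip(p_hat, 0.001, 0.999)
        for i, idx in enumerate(test_idx):
            rows.append((int(idx), fold, float(p_hat[i]), int(test.y[i])))
    return (
        pd.DataFrame(rows, columns=["participant", "fold", "p_hat", "outcome"])
        .sort_values("participant")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Calibration assessment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    """Binned and/or lowess-smoothed calibration of held-out predictions.

    Bins are the ten equal-width probability intervals [0, 0.1), ...,
    [0.9, 1.0]; empty bins are reported with count 0 (rate NaN), never
    dropped, so the bins always partition [0, 1].  ``lowess_curve`` holds
    (predicted, smoothed empirical) pairs over the observed prediction
    range and ``max_calibration_gap`` the largest |smoothed - predicted|.
    """

    bin_edges: np.ndarray | None = None
    bin_mean_pred: np.ndarray | None = None
    bin_rate: np.ndarray | None = None
    bin_count: np.ndarray | None = None
    lowess_curve: np.ndarray | None = None
    max_calibration_gap: float | None = None

    def occupied_bins(self) -> np.ndarray:
        if self.bin_count is None:
            raise ValueError("no bin part computed")
        return np.flatnonzero(self.bin_count > 0)


def _validate_preds(preds, outcomes):
    preds = np.asarray(preds, dtype=float)
    outcomes = np.asarray(outcomes)
    if preds.shape != outcomes.shape or preds.ndim != 1:
        raise ValueError("predictions and outcomes must be equal-length 1-D arrays")
    if np.any((preds < 0) | (preds > 1)) or not np.all(np.isfinite(preds)):
        raise ValueError("predictions must lie in [0, 1]")
    if not np.isin(outcomes, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    return preds, outcomes.astype(float)


def bin_calibration(preds, outcomes) -> CalibrationResult:
    """Ten equal-width bins: per-bin mean prediction, empirical rate, count."""
    preds, outcomes = _validate_preds(preds, outcomes)
    edges = np.linspace(0.0, 1.0, 11)
    idx = np.minimum((preds * 10).astype(int), 9)  # last bin closed at 1.0
    count = np.bincount(idx, minlength=10)
    mean_pred = np.full(10, np.nan)
    rate = np.full(10, np.nan)
    for b in range(10):
        mask = idx == b
        if mask.any():
            mean_pred[b] = preds[mask].mean()
            rate[b] = outcomes[mask].mean()
    return CalibrationResult(bin_edges=edges, bin_mean_pred=mean_pred,
                             bin_rate=rate, bin_count=count)


def lowess_calibration(
    preds, outcomes, frac: float = DEFAULT_LOWESS_FRAC, it: int = DEFAULT_LOWESS_IT
) -> CalibrationResult:
    """Lowess smooth of outcome against prediction over the pooled held-out
    predictions; the curve is clipped to [0, 1]."""
    preds, outcomes = _validate_preds(preds, outcomes)
    if preds.size < 10:
        raise ValueError("need at least 10 predictions for a lowess curve")
    if np.ptp(preds) == 0.0:
        warnings.warn("constant predictions: lowess curve degenerates to one point",
                      category=UserWarning, stacklevel=2)
        point = np.array([[preds[0], outcomes.mean()]])
        return CalibrationResult(lowess_curve=point,
                                 max_calibration_gap=float(abs(outcomes.mean() - preds[0])))
    smooth = sm_lowess(outcomes, preds, frac=frac, it=it, return_sorted=True)
    curve = np.column_stack([smooth[:, 0], np.clip(smooth[:, 1], 0.0, 1.0)])
    gap = float(np.max(np.abs(curve[:, 1] - curve[:, 0])))
    return CalibrationResult(lowess_curve=curve, max_calibration_gap=gap)


def assess_calibration(
    preds, outcomes, frac: float = DEFAULT_LOWESS_FRAC, it: int = DEFAULT_LOWESS_IT
) -> CalibrationResult:
    """Both calibration views (bins and lowess) on the same predictions."""
    bins = bin_calibration(preds, outcomes)
    curve = lowess_calibration(preds, outcomes, frac=frac, it=it)
    return CalibrationResult(
        bin_edges=bins.bin_edges, bin_mean_pred=bins.bin_mean_pred,
        bin_rate=bins.bin_rate, bin_count=bins.bin_count,
        lowess_curve=curve.lowess_curve, max_calibration_gap=curve.max_calibration_gap,
    )


def calibration_report(result: CalibrationResult, path=None) -> dict:
    """JSON-serializable calibration report (optionally written to path)."""
    def listify(x):
        return None if x is None else np.asarray(x).tolist()

    report = {
        "bin_edges": listify(result.bin_edges),
        "bin_mean_pred": listify(result.bin_mean_pred),
        "bin_rate": listify(result.bin_rate),
        "bin_count": listify(result.bin_count),
        "lowess_curve": listify(result.lowess_curve),
        "max_calibration_gap": result.max_calibration_gap,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def plot_reliability(result: CalibrationResult, path) -> None:
    """Reliability plot: lowess curve (and bins, if present) vs. the diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], color="black", label="perfectly calibrated")
    if result.lowess_curve is not None:
        ax.plot(result.lowess_curve[:, 0], result.lowess_curve[:, 1],
                color="red", label="lowess of outcomes vs. predictions")
    if result.bin_mean_pred is not None:
        occ = result.occupied_bins()
        ax.scatter(result.bin_mean_pred[occ], result.bin_rate[occ],
                   color="steelblue", zorder=3, label="bins")
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("empirical outcome rate")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
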