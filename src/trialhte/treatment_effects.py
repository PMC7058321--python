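"""Individual and conditional treatment effects by counterfactual contrast.

For each participant, the held-out fold model predicts the probability of
prolonged abstinence twice: once with the allocation column forced to 1
(offered the intervention) and once forced to 0 (control), all other
covariates untouched — an intention-to-treat contrast, since the trial
randomized the *offer* of the intervention.  The difference of the two
posterior-predictive probabilities, in percentage points, is the
individual treatment effect (ITE); its mean is the average treatment
effect (ATE), and summaries of the ITEs by covariate value are conditional
average treatment effects (CATEs).

Because the outcome model is logistic with no interaction terms, a
constant conditional odds ratio still implies probability-scale effects
that vary with baseline risk (non-collapsibility); CATE gradients can
therefore appear without any effect modification on the log-odds scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .crossval_calibration import FoldPlan, run_crossval
from .horseshoe_model import HorseshoeConfig
from .posterior_inference import predictive_probabilities, sample_posterior
from .trial_data import DEFAULT_SCHEMA, TrialSchema, encode_design, records_to_frame

__all__ = [
    "CateSummary",
    "individual_effects",
    "average_effect",
    "cate_by_covariate",
    "effects_to_csv",
    "plot_effects_by_covariate",
]

EFFECT_COLUMNS = ["participant", "fold", "p_treat", "p_ctrl", "delta_pp"]


def _counterfactual_probs(draws, X, group_col: int):
    X1 = X.copy()
    X1[:, group_col] = 1.0
    X0 = X.copy()
    X0[:, group_col] = 0.0
    return predictive_probabilities(draws, X1), predictive_probabilities(draws, X0)


def _per_draw_deltas(draws, X, group_col: int) -> np.ndarray:
    """Per-participant, per-draw difference of counterfactual probabilities."""
    X1 = X.copy()
    X1[:, group_col] = 1.0
    X0 = X.copy()
    X0[:, group_col] = 0.0
    eta1 = draws.beta0_draws[None, :] + X1 @ draws.beta_draws.T
    eta0 = draws.beta0_draws[None, :] + X0 @ draws.beta_draws.T
    return expit(eta1) - expit(eta0)


def individual_effects(
    records,
    plan: FoldPlan,
    config: HorseshoeConfig | None = None,
    n_draws: int = 500,
    seed: int = 0,
    schema: TrialSchema | None = None,
    *,
    refit_all: bool = False,
    include_draw_intervals: bool = False,
) -> pd.DataFrame:
    """Counterfactual ITE for every participant from their held-out fold model.

    Returns one row per participant: held-out p_treat and p_ctrl, their
    difference delta_pp in percentage points, the fold id, and the observed
    covariates.  ``refit_all=True`` instead uses a single model fitted on
    all records (no cross-validation) for every participant — a comparison
    variant, not the default reporting path.  ``include_draw_intervals``
    adds the central 90% interval of the per-draw deltas per participant.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    schema = schema if schema is not None else DEFAULT_SCHEMA

    pieces = []
    if refit_all:
        design = encode_design(frame, schema)
        cfg = config if config is not None else HorseshoeConfig.for_design(design)
        draws = sample_posterior(design, cfg, n_draws=n_draws, seed=seed)
        group_col = design.column_names.index("group")
        p1, p0 = _counterfactual_probs(draws, design.X, group_col)
        piece = pd.DataFrame(
            {"participant": np.arange(len(frame)), "fold": 0, "p_treat": p1, "p_ctrl": p0}
        )
        if include_draw_intervals:
            dd = _per_draw_deltas(draws, design.X, group_col)
            piece["delta_q05_pp"] = 100.0 * np.quantile(dd, 0.05, axis=1)
            piece["delta_q95_pp"] = 100.0 * np.quantile(dd, 0.95, axis=1)
        pieces.append(piece)
    else:
        result = run_crossval(frame, plan, config, n_draws, seed, schema)
        for fit in result.fold_fits:
            test = encode_design(
                frame.iloc[fit.test_indices], result.schema, standardizer=fit.standardizer
            )
            group_col = list(test.column_names).index("group")
            p1, p0 = _counterfactual_probs(fit.draws, test.X, group_col)
            piece = pd.DataFrame(
                {"participant": fit.test_indices, "fold": fit.fold, "p_treat": p1, "p_ctrl": p0}
            )
            if include_draw_intervals:
                dd = _per_draw_deltas(fit.draws, test.X, group_col)
                piece["delta_q05_pp"] = 100.0 * np.quantile(dd, 0.05, axis=1)
                piece["delta_q95_pp"] = 100.0 * np.quantile(dd, 0.95, axis=1)
            pieces.append(piece)

    effects = pd.concat(pieces, ignore_index=True).sort_values("participant").reset_index(drop=True)
    effects["delta_pp"] = 100.0 * (effects["p_treat"] - effects["p_ctrl"])
    covs = frame.reset_index(drop=True).loc[effects["participant"].to_numpy()]
    for col in covs.columns:
        effects[col] = covs[col].to_numpy()
    return effects


def average_effect(effects: pd.DataFrame) -> float:
    """Average treatment effect: the mean ITE, in percentage points."""
    if len(effects) == 0:
        raise ValueError("empty effect table")
    return float(effects["delta_pp"].mean())


@dataclass(frozen=True)
class CateSummary:
    """Per-stratum ITE summaries for one stratifying covariate.

    strata is a DataFrame with one row per stratum: the stratum label,
    mean delta_pp, the central 90% range (5th and 95th percentiles of the
    per-participant deltas), and the stratum size.  For continuous
    covariates the strata are 10 quantile bins, labelled by bin midpoint.
    """

    covariate: str
    kind: str  # 'categorical' or 'continuous'
    strata: pd.DataFrame

    def to_json(self, path=None) -> dict:
        payload = {
            "covariate": self.covariate,
            "kind": self.kind,
            "strata": self.strata.to_dict(orient="records"),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2)
        return payload


def _covariate_kind(name: str, schema: TrialSchema) -> str:
    for spec in schema.predictors:
        if spec.name == name:
            return "continuous" if spec.kind == "continuous" else "categorical"
    raise ValueError(f"unknown covariate {name!r}")


def cate_by_covariate(
    effects: pd.DataFrame,
    covariate: str,
    schema: TrialSchema = DEFAULT_SCHEMA,
    n_quantile_bins: int = 10,
) -> CateSummary:
    """Conditional average treatment effect by covariate stratum.

    Categorical covariates stratify by level; continuous covariates by
    ``n_quantile_bins`` quantile bins of the observed values.  Stratum
    sizes sum to the number of participants.
    """
    if covariate not in effects.columns:
        raise ValueError(f"unknown covariate {covariate!r}")
    kind = _covariate_kind(covariate, schema)
    deltas = effects["delta_pp"].to_numpy()

    if kind == "categorical":
        keys = effects[covariate]
        labels = sorted(keys.unique().tolist())
        groups = [(lv, deltas[(keys == lv).to_numpy()]) for lv in labels]
    else:
        values = effects[covariate].to_numpy(dtype=float)
        bins = pd.qcut(values, q=n_quantile_bins, duplicates="drop")
        groups = []
        for interval in bins.categories:
            sel = np.asarray(bins == interval)
            groups.append((float(interval.mid), deltas[sel]))

    rows = []
    for label, d in groups:
        rows.append(
            {
                "stratum": label,
                "mean_delta_pp": float(np.mean(d)),
                "q05_delta_pp": float(np.quantile(d, 0.05)),
                "q95_delta_pp": float(np.quantile(d, 0.95)),
                "size": int(d.size),
            }
        )
    return CateSummary(covariate=covariate, kind=kind, strata=pd.DataFrame(rows))


def effects_to_csv(effects: pd.DataFrame, path) -> None:
    effects.to_csv(path, index=False)


def plot_effects_by_covariate(effects: pd.DataFrame, covariate: str, path,
                              schema: TrialSchema = DEFAULT_SCHEMA) -> None:
    """Scatter of per-participant delta_pp against one covariate, with
    stratum means overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = cate_by_covariate(effects, covariate, schema)
    fig, ax = plt.subplots(figsize=(5, 4))
    jitter = (np.random.default_rng(0).random(len(effects)) - 0.5) * 0.2
    x = effects[covariate].to_numpy(dtype=float)
    if summary.kind == "categorical":
        x = x + jitter
    ax.scatter(x, effects["delta_pp"], s=6, alpha=0.3, color="grey")
    ax.plot(summary.strata["stratum"], summary.strata["mean_delta_pp"],
            "o-", color="firebrick", label="stratum mean")
    ax.set_xlabel(covariate)
    ax.set_ylabel("predicted effect (percentage points)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
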