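"""Fold plans, leakage-free held-out prediction, calibration assessment,
and the maximum-likelihood comparator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

import trialhte as t
from trialhte.crossval_calibration import fold_seed
from trialhte.trial_data import ColumnSpec, TrialSchema, records_to_frame


# ---------------------------------------------------------------------------
# Fold plans
# ---------------------------------------------------------------------------

def test_fold_plan_small_exact():
    plan = t.make_fold_plan(20, 10, seed=1)
    sizes = np.bincount(plan.fold_assignment)[1:]
    assert (sizes == 2).all()
    assert sorted(np.concatenate([plan.test_indices(f) for f in range(1, 11)]).tolist()) == list(range(20))


def test_fold_plan_trial_size():
    plan = t.make_fold_plan(1590, 10, seed=0)
    sizes = np.bincount(plan.fold_assignment)[1:]
    assert (sizes == 159).all()


def test_fold_plan_determinism_and_errors():
    a = t.make_fold_plan(53, 10, seed=9)
    b = t.make_fold_plan(53, 10, seed=9)
    assert np.array_equal(a.fold_assignment, b.fold_assignment)
    sizes = np.bincount(a.fold_assignment)[1:]
    assert sizes.max() - sizes.min() <= 1
    with pytest.raises(ValueError):
        t.make_fold_plan(5, 10, seed=0)


# ---------------------------------------------------------------------------
# Cross-validated Bayesian prediction
# ---------------------------------------------------------------------------

def test_crossval_contract(small_records):
    plan = t.make_fold_plan(60, 3, seed=2)
    preds = t.crossval_predict(small_records, plan, n_draws=50, seed=2)
    assert len(preds) == 60
    assert preds["participant"].tolist() == list(range(60))
    assert ((preds["p_hat"] >= 0) & (preds["p_hat"] <= 1)).all()
    # each participant predicted in their own fold
    assert np.array_equal(preds.sort_values("participant")["fold"].to_numpy(),
                          plan.fold_assignment)


def test_no_signal_null_concentrates_at_base_rate():
    """With zero coefficients everywhere, the only learnable quantity is the
    ~30% base rate; held-out predictions concentrate around it."""
    cfg = t.SyntheticTrialConfig(
        n_total=1000, n_intervention=500,
        true_coefficients={"intercept": float(logit(0.3))}, seed=21,
    )
    records = t.generate_trial(cfg)
    plan = t.make_fold_plan(1000, 10, seed=21)
    preds = t.crossval_predict(records, plan, n_draws=200, seed=21)
    within = np.abs(preds["p_hat"].to_numpy() - 0.3) < 0.1
    assert within.mean() >= 0.95


def test_record_permutation_leaves_predictions_stable(small_records):
    """Permuting record order (with the fold plan permuted to match) keeps
    each participant's held-out prediction, up to Monte Carlo error."""
    plan = t.make_fold_plan(60, 3, seed=4)
    preds = t.crossval_predict(small_records, plan, n_draws=400, seed=4)

    rng = np.random.default_rng(0)
    perm = rng.permutation(60)
    permuted_records = [small_records[i] for i in perm]
    permuted_plan = t.FoldPlan(
        n=60, fold_assignment=plan.fold_assignment[perm], f=3, seed=plan.seed
    )
    preds_perm = t.crossval_predict(permuted_records, permuted_plan, n_draws=400, seed=4)

    a = preds.set_index("participant")["p_hat"]
    b = preds_perm.set_index("participant")["p_hat"].to_numpy()
    # participant j of the permuted data is original participant perm[j]
    assert np.allclose(a.to_numpy()[perm], b, atol=0.05)


def test_no_leakage_from_testing_records(default_records):
    """Perturbing a testing-set record leaves its fold's model unchanged:
    posterior draws must be bit-identical."""
    records = list(default_records[:200])
    plan = t.make_fold_plan(200, 4, seed=3)
    result = t.run_crossval(records, plan, n_draws=60, seed=3)

    victim = int(plan.test_indices(2)[0])
    perturbed = list(records)
    perturbed[victim] = dataclasses.replace(
        records[victim],
        years_smoked=99.0, weekly_cigs=999.0, outcome=1 - records[victim].outcome,
    )
    result2 = t.run_crossval(perturbed, plan, n_draws=60, seed=3)
    fit = next(f for f in result.fold_fits if f.fold == 2)
    fit2 = next(f for f in result2.fold_fits if f.fold == 2)
    assert np.array_equal(fit.draws.beta0_draws, fit2.draws.beta0_draws)
    assert np.array_equal(fit.draws.beta_draws, fit2.draws.beta_draws)
    assert fit.standardizer.means == fit2.standardizer.means


def test_fold_seeds_are_deterministic():
    assert fold_seed(5, 1) == fold_seed(5, 1)
    assert fold_seed(5, 1) != fold_seed(5, 2)
    assert fold_seed(5, 1) != fold_seed(6, 1)


# ---------------------------------------------------------------------------
# Binned calibration
# ---------------------------------------------------------------------------

def test_bin_calibration_single_bin():
    preds = np.full(100, 0.15)
    outcomes = np.r_[np.ones(15), np.zeros(85)]
    result = t.bin_calibration(preds, outcomes)
    assert result.bin_count[1] == 100 and result.bin_count.sum() == 100
    assert result.bin_mean_pred[1] == pytest.approx(0.15)
    assert result.bin_rate[1] == pytest.approx(0.15)
    assert np.isnan(result.bin_rate[0])  # empty bins reported, not dropped


def test_bin_calibration_perfect_predictions():
    preds = np.r_[np.zeros(5), np.ones(5)]
    outcomes = np.r_[np.zeros(5), np.ones(5)]
    result = t.bin_calibration(preds, outcomes)
    assert result.bin_rate[0] == 0.0
    assert result.bin_rate[9] == 1.0  # 1.0 falls in the closed last bin
    assert result.bin_count[[0, 9]].sum() == 10


def test_bin_calibration_calibrated_simulator():
    rng = np.random.default_rng(6)
    preds = rng.uniform(0.02, 0.98, 10_000)
    outcomes = (rng.random(10_000) < preds).astype(int)
    result = t.bin_calibration(preds, outcomes)
    occ = result.occupied_bins()
    assert np.all(np.abs(result.bin_mean_pred[occ] - result.bin_rate[occ]) < 0.03)


def test_bin_calibration_rejects_invalid():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        t.bin_calibration([1.2, 0.5], [1, 0])
    with pytest.raises(ValueError, match="equal-length"):
        t.bin_calibration([0.5], [1, 0])


# ---------------------------------------------------------------------------
# Lowess calibration
# ---------------------------------------------------------------------------

def test_lowess_calibrated_simulator_small_gap():
    rng = np.random.default_rng(7)
    preds = rng.uniform(0.02, 0.98, 10_000)
    outcomes = (rng.random(10_000) < preds).astype(int)
    result = t.lowess_calibration(preds, outcomes)
    assert result.max_calibration_gap < 0.05
    assert np.all((result.lowess_curve[:, 1] >= 0) & (result.lowess_curve[:, 1] <= 1))


def test_lowess_detects_constructed_miscalibration():
    """Outcomes deterministically thresholded at 0.5 are maximally
    miscalibrated probabilities; the smooth leaves the diagonal mid-range."""
    rng = np.random.default_rng(8)
    preds = rng.uniform(0.0, 1.0, 5000)
    outcomes = (preds > 0.5).astype(int)
    result = t.lowess_calibration(preds, outcomes)
    assert result.max_calibration_gap > 0.2


def test_lowess_constant_predictions_warn():
    with pytest.warns(UserWarning, match="constant predictions"):
        result = t.lowess_calibration(np.full(50, 0.4), np.r_[np.ones(20), np.zeros(30)])
    assert result.lowess_curve.shape == (1, 2)


def test_assess_calibration_combines_views():
    rng = np.random.default_rng(9)
    preds = rng.uniform(0.1, 0.9, 2000)
    outcomes = (rng.random(2000) < preds).astype(int)
    result = t.assess_calibration(preds, outcomes)
    assert result.bin_count.sum() == 2000
    assert result.max_calibration_gap is not None
    report = t.crossval_calibration.calibration_report(result)
    assert len(report["bin_rate"]) == 10


# ---------------------------------------------------------------------------
# Maximum-likelihood comparator
# ---------------------------------------------------------------------------

def test_mle_intercept_only_recovers_base_rate():
    rng = np.random.default_rng(10)
    frame = pd.DataFrame({"outcome": rng.permutation(np.r_[np.ones(30), np.zeros(70)]).astype(int)})
    schema = TrialSchema(predictors=())
    plan = t.make_fold_plan(100, 5, seed=1)
    preds = t.mle_comparator_predict(frame, plan, seed=1, schema=schema)
    assert np.allclose(preds["p_hat"], 0.3, atol=0.06)


def test_mle_flags_separated_folds():
    """Outcome identical to allocation is perfectly separated: every fold is
    flagged and its predictions clipped into [0.001, 0.999]."""
    rng = np.random.default_rng(3)
    group = rng.permutation(np.r_[np.ones(30), np.zeros(30)]).astype(int)
    frame = pd.DataFrame({"group": group, "outcome": group})
    schema = TrialSchema(predictors=(ColumnSpec("group", "binary"),))
    plan = t.make_fold_plan(60, 3, seed=0)
    with pytest.warns(UserWarning, match="separation"):
        preds = t.mle_comparator_predict(frame, plan, seed=0, schema=schema)
    assert ((preds["p_hat"] >= 0.001) & (preds["p_hat"] <= 0.999)).all()


def test_mle_matches_direct_likelihood_maximization(default_records):
    """Fold predictions agree with probabilities from an independent
    numerical maximization of the Bernoulli log likelihood."""
    schema = TrialSchema(
        predictors=(ColumnSpec("group", "binary"), ColumnSpec("years_smoked", "continuous"))
    )
    frame = records_to_frame(default_records[:200])
    plan = t.make_fold_plan(200, 3, seed=5)
    preds = t.mle_comparator_predict(frame, plan, seed=5, schema=schema)

    for fold in range(1, 4):
        learn_idx = plan.learn_indices(fold)
        test_idx = plan.test_indices(fold)
        learn = t.encode_design(frame.iloc[learn_idx], schema)
        test = t.encode_design(frame.iloc[test_idx], schema, standardizer=learn.standardizer)
        Z = np.column_stack([np.ones(learn.n), learn.X])

        def nll(theta):
            eta = Z @ theta
            return -np.sum(learn.y * eta - np.logaddexp(0.0, eta))

        opt = minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-10})
        assert np.max(np.abs(opt.x)) < 15  # no separation in these folds
        eta_test = np.column_stack([np.ones(test.n), test.X]) @ opt.x
        expected = expit(eta_test)
        got = preds.set_index("participant").loc[test_idx, "p_hat"].to_numpy()
        assert np.allclose(got, expected, atol=1e-6)
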