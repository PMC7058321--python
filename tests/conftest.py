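import dataclasses

import numpy as np
import pytest

import trialhte as t


@pytest.fixture(scope="session")
def default_config():
    """Calibrated default trial config (1590 participants, 827:763)."""
    return t.default_trial_config(seed=5)


@pytest.fixture(scope="session")
def default_records(default_config):
    return t.generate_trial(default_config)


@pytest.fixture(scope="session")
def small_records():
    """A 60-participant trial for fast pipeline contract tests."""
    cfg = t.default_trial_config(seed=11, n_total=60, n_intervention=30)
    return t.generate_trial(cfg)


@pytest.fixture()
def stub_draws():
    """Hand-built posterior draws over the default 11-column design."""
    names = (
        "group", "sex", "years_smoked", "weekly_cigs",
        "dependence_2", "dependence_3", "dependence_4", "dependence_5",
        "snuff_2", "snuff_3", "snuff_4",
    )

    def make(beta0, beta_rows):
        beta = np.atleast_2d(np.asarray(beta_rows, dtype=float))
        s = beta.shape[0]
        return t.PosteriorDraws(
            beta0_draws=np.full(s, float(beta0)) if np.isscalar(beta0) else np.asarray(beta0, float),
            beta_draws=beta,
            tau_draws=np.ones(s),
            lam_draws=np.ones((s, beta.shape[1])),
            column_names=names[: beta.shape[1]],
            diagnostics={},
        )

    return make
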