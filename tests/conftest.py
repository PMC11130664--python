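"""Shared fixtures: session-scoped synthetic studies reused across tests."""

import numpy as np
import pytest

from mealmr.simulate import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cfg():
    """Mixed-effect study: traits 0-7 carry a fasting effect, 8-15 a
    response effect, the rest are null."""
    n_met = 24
    beta_f = np.zeros(n_met)
    beta_f[:8] = 0.07
    beta_r = np.zeros(n_met)
    beta_r[8:16] = -0.08
    return SynthConfig(
        n_random=700,
        n_oversampled=1300,
        n_snps=80,
        n_metabolites=n_met,
        n_classes=6,
        beta_fasting=tuple(beta_f),
        beta_response=tuple(beta_r),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def null_data():
    """All-null effects, independent traits."""
    cfg = SynthConfig(
        n_random=500,
        n_oversampled=700,
        n_snps=60,
        n_metabolites=30,
        n_classes=30,
        class_loading=0.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240316)
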