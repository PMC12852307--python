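"""Shared fixtures: small synthetic cohorts and fast optimizer settings."""

import numpy as np
import pytest

import cohortgp as cg


@pytest.fixture(scope="session")
def fast_opt():
    """Reduced-restart optimizer used throughout the suite to keep fits quick."""
    return cg.OptimizerConfig(restarts=2)


@pytest.fixture(scope="session")
def small_cohort():
    """A 5-member, 2-input, 2-output high-similarity cohort."""
    cfg = cg.SyntheticCohortConfig(
        n_inputs=2, d_latent=2, n_members=5, n_sims=60, n_outputs=2,
        discrepancy_scale=0.05, latent_smoothness=2.0, seed=7,
    )
    return cg.generate_cohort(cfg)


@pytest.fixture(scope="session")
def refs_small(small_cohort, fast_opt):
    return cg.train_individual_cohort(
        small_cohort.dataset, "all", seed=0, optimizer_config=fast_opt
    )


@pytest.fixture(scope="session")
def het_cohort():
    """A 10-member heterogeneous cohort whose members are mutually distinguishable.

    Used for support-recovery experiments, which are only identifiable when the
    reference functions are not nearly collinear.
    """
    cfg = cg.SyntheticCohortConfig(
        n_inputs=2, d_latent=2, n_members=10, n_sims=150, n_outputs=1,
        discrepancy_scale=1.5, latent_smoothness=0.5, seed=11,
    )
    return cg.generate_cohort(cfg)


@pytest.fixture(scope="session")
def refs_het(het_cohort, fast_opt):
    return cg.train_individual_cohort(
        het_cohort.dataset, "all", seed=0, optimizer_config=fast_opt
    )


@pytest.fixture(scope="session")
def rough_gp_data():
    """Well-conditioned noiseless regression fixture for interpolation checks."""
    rng = np.random.default_rng(3)
    X = rng.uniform(0, 1, (12, 2))
    y = np.sin(6 * X[:, 0]) * np.cos(4 * X[:, 1])
    return X, y
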