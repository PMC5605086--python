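"""Shared fixtures: small simulated cohorts reused across test modules."""

import pytest

from rdnacn import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A 20-patient cohort under generator defaults (seed 11)."""
    return simulate_cohort(SimulationConfig(n_patients=20, seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """A noise-minimised cohort: no site heterogeneity, no batch spread,
    no tumor change — for sharp recovery arithmetic."""
    cfg = SimulationConfig(
        n_patients=8,
        site_het_sd=0.0,
        batch_sd=0.0,
        tumor_5s_gain_mean=1.0,
        tumor_45s_loss_mean=1.0,
        tumor_fold_log_sd=0.0,
        driver_effect=0.0,
        locus_1q42_gain_rate=0.0,
        aneuploidy_rate=0.0,
        fraction_cross_plate=0.0,
        seed=5,
    )
    return simulate_cohort(cfg)
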