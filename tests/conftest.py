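import pytest

from clptel import SimulationParams, fixture_cohort_table1


@pytest.fixture(scope="session")
def table1_cohort():
    """Deterministic 115-mouse cohort reconstructed from the hourly table."""
    return fixture_cohort_table1()


@pytest.fixture
def noise_free_params():
    """Factory for deterministic single-shape simulation settings."""

    def make(**overrides):
        base = dict(
            n_mice=1,
            seed=0,
            onset_log_sigma=0.0,
            noise_sd_hr=0.0,
            noise_sd_temp=0.0,
            non_deteriorator_fraction=0.0,
            hr_peak_range=(700.0, 700.0),
            temp_peak_range=(37.5, 37.5),
            include_activity=False,
        )
        base.update(overrides)
        return SimulationParams(**base)

    return make
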