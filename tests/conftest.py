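import pytest

import torporflow as tf


@pytest.fixture(scope="session")
def protocol():
    """Default cabinet protocol: hold at 5 deg C from 01:30, ramp to 37."""
    return tf.make_default_protocol("01:30", torpor_flow=150.0)


@pytest.fixture(scope="session")
def clean_analyzer():
    """Analyzer with no drift, no noise, no washout."""
    return tf.AnalyzerModel()


@pytest.fixture(scope="session")
def group2_phenotype():
    """A bat that arouses below the lower critical temperature (group 2)."""
    return tf.BatPhenotype(
        mass_start=8.3,
        bmr=15.5,
        rmr_slope=2.9,
        t_lc=29.7,
        tmr_coeff_a=0.127,
        tmr_base_b=1.148,
        arousal_ta=24.0,
        entry_delay_min=100,
        arousal_peak_vo2=78.0,
    )


@pytest.fixture(scope="session")
def clean_experiment(group2_phenotype, protocol, clean_analyzer):
    """One noise-free simulated experiment reused across read-only tests."""
    return tf.simulate_experiment(
        group2_phenotype, protocol, clean_analyzer, seed=0
    )
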