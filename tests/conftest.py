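import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_run():
    """Noise-free experiment with known transfer fractions in all directions."""
    import dataclasses

    import mycoflux as mf

    cfg = dataclasses.replace(
        mf.default_config(
            phi_c_orchid_to_pine=0.02,
            phi_c_pine_to_orchid=0.05,
            phi_n_orchid_to_pine=0.01,
            phi_n_pine_to_orchid=0.004,
        ),
        analytical_sd_permil=0.0,
    )
    measurements, truth = mf.simulate_experiment(cfg, seed=3)
    return cfg, measurements, truth
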