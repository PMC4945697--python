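import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from dissectflow import (  # noqa: E402
    InflowSpec,
    build_network,
    fixture_configs,
    generate_inflow,
    load_heart_params,
    simulate,
    single_rcr_afterload,
)
from dissectflow.heart import simulate_heart, tune_elastance  # noqa: E402


@pytest.fixture(scope="session")
def inflow():
    """Default synthetic aortic inflow (SV 94 mL, period 1.3 s, 25 phases)."""
    return generate_inflow(InflowSpec())


@pytest.fixture(scope="session")
def configs():
    return fixture_configs()


@pytest.fixture(scope="session")
def variant_solutions(inflow, configs):
    """Converged simulations of all four packaged fixtures."""
    return {name: simulate(build_network(cfg), inflow)
            for name, cfg in configs.items()}


@pytest.fixture(scope="session")
def heart_params():
    return load_heart_params("dissected")


@pytest.fixture(scope="session")
def reference_heart_run(heart_params):
    """Untuned heart against the packaged single-RCR afterload."""
    return simulate_heart(heart_params, single_rcr_afterload())


@pytest.fixture(scope="session")
def co_targets(inflow):
    """Mean (4.4 L/min) and peak cardiac-output targets from the inflow."""
    return 4.4e6 / 60.0, inflow.metrics()["peak"]


@pytest.fixture(scope="session")
def tuned_baseline(heart_params, co_targets):
    mean_t, peak_t = co_targets
    return tune_elastance(mean_t, peak_t, single_rcr_afterload(), heart_params)


@pytest.fixture(scope="session")
def tuned_high_afterload(heart_params, co_targets):
    """Re-tuned to the same output against a 1.2x-resistance afterload."""
    mean_t, peak_t = co_targets
    return tune_elastance(mean_t, peak_t, single_rcr_afterload().scaled(1.2),
                          heart_params)
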