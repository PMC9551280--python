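import pytest

from afbiofilm import ModelParams, run_replicates


@pytest.fixture(scope="session")
def baseline_params() -> ModelParams:
    """The published parameter set (6-month horizon)."""
    return ModelParams.create()


@pytest.fixture(scope="session")
def baseline_ensemble(baseline_params):
    """200 independent replicates at the published baseline, 6 months,
    establishment-time summaries only."""
    return run_replicates(
        baseline_params, 200, base_seed=2024, stop_at_establishment=True
    )


@pytest.fixture(scope="session")
def observable_params() -> ModelParams:
    """Reduced biofilm threshold (N* = 0.65 K) so that establishment is a
    frequent event at desk scale; used by the phenomenology tests."""
    return ModelParams.create(N_star=0.65 * 550, t_max=3000.0)


@pytest.fixture(scope="session")
def rare_event_params() -> ModelParams:
    """Threshold N* = 0.69 K: establishment is rare compared with the
    community relaxation time, the memoryless (Poisson) regime."""
    return ModelParams.create(N_star=0.69 * 550, t_max=8760.0)


@pytest.fixture(scope="session")
def rare_event_ensemble(rare_event_params):
    return run_replicates(
        rare_event_params, 150, base_seed=7, stop_at_establishment=True
    )
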