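import pytest
from hypothesis import settings

from ebpr import SBRConfig, simulate_cycle, simulate_to_steady_state

# deterministic property tests, no on-disk example database
settings.register_profile("deterministic", derandomize=True, database=None,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config() -> SBRConfig:
    return SBRConfig()


@pytest.fixture(scope="session")
def steady_phase0(config):
    """Steady state at the enrichment condition (0.64 P-mmol/L influent)."""
    results, _ = simulate_to_steady_state(config, phase_schedule=[(0, 0.64)])
    return results[0]


@pytest.fixture(scope="session")
def steady_schedule(config):
    """Steady states of all six influent phases, run in sequence.

    The state carries over between phases, so the repeated doses at the end of
    the schedule probe reversibility of the preceding shifts.
    """
    results, _ = simulate_to_steady_state(config)
    return results


@pytest.fixture(scope="session")
def noiseless_cycle(config, steady_phase0):
    """One exact (noise-free) cycle simulated from the phase-0 steady state."""
    return simulate_cycle(steady_phase0.state, config, phosphate_mmol=0.64)
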