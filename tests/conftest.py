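import pytest

from presspulse.design import ExperimentDesign, SimulationParams, Treatment
from presspulse.metrics import PerturbationIndices
from presspulse.simulate import simulate_experiment
from presspulse.windows import CycleSegmenter


@pytest.fixture(scope="session")
def ref_design() -> ExperimentDesign:
    return ExperimentDesign.default()


@pytest.fixture(scope="session")
def sim_timeseries(ref_design):
    """One simulated reference-design experiment, shared across tests."""
    return simulate_experiment(ref_design, SimulationParams(seed=42))


@pytest.fixture(scope="session")
def sim_windows(ref_design, sim_timeseries):
    seg = CycleSegmenter(pulse_days=ref_design.pulse_days)
    return seg.fit(sim_timeseries).transform(sim_timeseries)


@pytest.fixture(scope="session")
def sim_metrics(ref_design, sim_windows):
    idx = PerturbationIndices(design=ref_design)
    return idx.fit(sim_windows).transform(sim_windows)


@pytest.fixture
def closed_design() -> ExperimentDesign:
    """Closed configuration: no dosing, no refill; pulses still occur."""
    return ExperimentDesign(
        treatments=(Treatment("control"),),
        n_replicates=1,
        sample_loss_volume=0.0,
    )
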