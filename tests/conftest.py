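import numpy as np
import pytest

from hybridoe.datamodel import Design, Segment
from hybridoe.synthetic import GroundTruth, make_dataset, simulate_run, simulate_truth


@pytest.fixture(scope="session")
def gt():
    return GroundTruth()


@pytest.fixture(scope="session")
def center_design_shaker():
    return Design(
        doe_mode="static", segments=[Segment(72.0, 34.0, "F2")], planned_duration=336.0
    )


@pytest.fixture(scope="session")
def center_design_bioreactor():
    return Design(
        doe_mode="static", segments=[Segment(72.0, 34.0, "F2")], planned_duration=360.0
    )


@pytest.fixture(scope="session")
def shaker_cp_noiseless(gt, center_design_shaker):
    """Noiseless shake-flask center-point run (harvest rule applied)."""
    return simulate_run(center_design_shaker, "shake_flask", gt, noiseless=True, run_id="CP-SF")


@pytest.fixture(scope="session")
def bioreactor_cp_noiseless(gt, center_design_bioreactor):
    return simulate_run(center_design_bioreactor, "bioreactor", gt, noiseless=True, run_id="CP-BR")


@pytest.fixture(scope="session")
def shaker_cp_truth(gt, center_design_shaker):
    """Dense ground-truth traces for the shake-flask center point."""
    return simulate_truth(center_design_shaker, "shake_flask", gt)


@pytest.fixture(scope="session")
def bioreactor_cp_truth(gt, center_design_bioreactor):
    return simulate_truth(center_design_bioreactor, "bioreactor", gt)


@pytest.fixture(scope="session")
def transfer_data(gt):
    """The transfer study scenario at the protocol seed (noisy)."""
    return make_dataset("transfer_training", gt, seed=0)


@pytest.fixture(scope="session")
def small_noisy_runs(transfer_data):
    """A handful of runs covering both scales, for cheap unit tests."""
    d = transfer_data
    return d["train"][:3] + d["train"][18:20] + d["test"][:1]


def daily(times, trace, days):
    return np.interp(np.asarray(days) * 24.0, times, trace)
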