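import numpy as np
import pytest

from nof1sim import SimulationModel, TrialDataset, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scenario1_model():
    return SimulationModel.scenario(1, tau=0.25)


@pytest.fixture
def small_cohort(scenario1_model, rng):
    """A 5-patient, 3-cycle N-of-1 cohort for quick fitter checks."""
    return simulate_cohort(scenario1_model, 5, rng)


def make_single_patient_nof1(treatments, outcomes, patient_id=0):
    """Hand-build one patient's N-of-1 records from explicit period sequences."""
    k = len(treatments)
    assert k % 2 == 0
    c = k // 2
    treatments = np.asarray(treatments, dtype=np.int8)
    pid = np.full(k, patient_id, dtype=np.int64)
    from nof1sim.trial_sim import compute_prev_treated

    return dict(
        patient_id=pid,
        cycle=np.repeat(np.arange(1, c + 1, dtype=np.int64), 2),
        look=np.tile(np.array([1, 2], dtype=np.int64), c),
        treatment=treatments,
        outcome=np.asarray(outcomes, dtype=np.float64),
        prev_treated=compute_prev_treated(pid, treatments),
        population=np.zeros(k, dtype=np.int8),
    )


def build_nof1_dataset(patients):
    """Concatenate per-patient record dicts into a TrialDataset."""
    cols = {
        key: np.concatenate([p[key] for p in patients])
        for key in patients[0]
    }
    return TrialDataset(design="nof1", **cols)
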