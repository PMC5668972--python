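import numpy as np
import pytest

import pulmonarx as px
from pulmonarx.simulate import RmProtocol, VirtualPatient, simulate_rm


@pytest.fixture(scope="session")
def inclass_sim():
    """Noiseless 7-step VC manoeuvre from a patient inside the model class
    (elastance spanned by the basis functions, short resistance kernel)."""
    patient = VirtualPatient(
        elastance=px.ElastanceCurve([8.0, 12.0, 5.0, 20.0]),
        resistance=np.array([7.0, 1.5, 0.8, 0.4, 0.2]),
        name="in-class",
    )
    protocol = RmProtocol(
        peep_start=10.0,
        n_steps=7,
        breaths_per_step=10,
        noise_sd=0.0,
        flow_noise_sd=0.0,
        seed=3,
    )
    return simulate_rm(patient, protocol)


@pytest.fixture(scope="session")
def inclass_dataset(inclass_sim):
    return px.StepDataset.from_record(inclass_sim.record)


@pytest.fixture(scope="session")
def noisy_sim():
    """Small noisy manoeuvre with default (clinical-level) noise."""
    patient = VirtualPatient(
        elastance=px.RecruitmentElastance(
            base=14.0, rise=25.0, centre=38.0, slope=0.18, quad=3.0
        ),
        resistance=9.0,
    )
    protocol = RmProtocol(peep_start=10.0, n_steps=5, breaths_per_step=8, seed=11)
    return simulate_rm(patient, protocol)
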