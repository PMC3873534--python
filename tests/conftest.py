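import numpy as np
import pytest

from hhspike.model import Epoch, Session, SpikeTrain
from hhspike.synth import DEFAULT_COHORT_LAYOUT


def make_train(times, unit_id="u0", channel_id=1, epoch_id="e0"):
    return SpikeTrain(unit_id, channel_id, np.asarray(times, float), epoch_id)


@pytest.fixture
def cohort_session() -> Session:
    """Session mirroring the reference cohort layout with empty spike trains."""
    patients = {}
    uid = 0
    for p_idx, counts in enumerate(DEFAULT_COHORT_LAYOUT):
        pid = f"P{p_idx + 1:02d}"
        epochs = []
        for e_idx, n_units in enumerate(counts):
            eid = f"{pid}-E{e_idx + 1}"
            trains = [
                SpikeTrain(f"U{uid + k:04d}", (k % 8) + 1, np.array([]), eid)
                for k in range(n_units)
            ]
            uid += n_units
            epochs.append(Epoch(eid, pid, 300.0, trains))
        patients[pid] = epochs
    return Session(patients)


@pytest.fixture
def small_session() -> Session:
    """Two patients, three epochs, a handful of spiking units."""
    rng = np.random.default_rng(7)
    patients = {}
    uid = 0
    for pid, n_epochs in (("PA", 2), ("PB", 1)):
        epochs = []
        for e in range(n_epochs):
            eid = f"{pid}-E{e + 1}"
            trains = []
            for k in range(3):
                times = np.sort(rng.uniform(0, 30.0, size=rng.integers(5, 40)))
                trains.append(SpikeTrain(f"U{uid:03d}", k + 1, times, eid))
                uid += 1
            epochs.append(Epoch(eid, pid, 30.0, trains))
        patients[pid] = epochs
    return Session(patients)
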