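import numpy as np
import pytest

from apmskit.decoydb import DbEntry, SequenceDatabase
from apmskit.synthgen import SimulationSpec


@pytest.fixture
def organism_db() -> SequenceDatabase:
    return SequenceDatabase(
        [
            DbEntry("P1", "MKLVNNAGIR"),
            DbEntry("P2", "AAKRPPLESK"),
            DbEntry("P3", "MMSTTVVK"),
        ]
    )


@pytest.fixture
def contaminant_db() -> SequenceDatabase:
    return SequenceDatabase(
        [
            DbEntry("C1", "KERATINLIKE", origin="contaminant"),
            DbEntry("C2", "TRYPSINLIKE", origin="contaminant"),
        ]
    )


@pytest.fixture
def small_spec() -> SimulationSpec:
    return SimulationSpec(
        seed=11,
        n_proteins=60,
        n_contaminants=5,
        n_true_psms=400,
        n_false_psms=400,
        n_decoy_psms=400,
        n_count_proteins=100,
        n_interactors=10,
        n_intervals=80,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
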