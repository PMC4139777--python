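import numpy as np
import pytest

from snosite.physchem import load_property_table
from snosite.pssm import PSSMProfile
from snosite.sstruct import SSString
from snosite.windows import ProteinRecord, window_at


@pytest.fixture(scope="session")
def property_table():
    return load_property_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20140623)


@pytest.fixture()
def toy_protein():
    return ProteinRecord(id="p1", sequence="MKACDEFGHCIKLMNPQRSTVWYC")


@pytest.fixture()
def toy_profile(toy_protein, rng):
    scores = rng.integers(-10, 11, size=(len(toy_protein), 20))
    return PSSMProfile(protein_id=toy_protein.id, scores=scores,
                       residues=toy_protein.sequence)


@pytest.fixture()
def toy_ss(toy_protein, rng):
    labels = "".join(rng.choice(list("HEC"), size=len(toy_protein)))
    return SSString(protein_id=toy_protein.id, labels=labels)


def make_window(sequence, center_pos, xi=10, label=None, pid="p"):
    return window_at(ProteinRecord(id=pid, sequence=sequence), center_pos,
                     xi=xi, label=label)
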