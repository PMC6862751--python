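import numpy as np
import pytest

from islandswap.allele_caller import illumina_frame, pacbio_frames
from islandswap.bisulfite_caller import build_bisulfite_refs
from islandswap.reference_model import build_model


@pytest.fixture(scope="session")
def model():
    return build_model(1)


@pytest.fixture(scope="session")
def pb_frames(model):
    return pacbio_frames(model)


@pytest.fixture(scope="session")
def pb_refs(pb_frames):
    return [f.ref for f in pb_frames.values()]


@pytest.fixture(scope="session")
def ill_frame(model):
    return illumina_frame(model)


@pytest.fixture(scope="session")
def bis_refs(model):
    return build_bisulfite_refs(model)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
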