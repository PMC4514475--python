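import numpy as np
import pytest

from porescope import default_topology
from porescope.model import StructureFrame
from porescope import synthetic as syn


@pytest.fixture(scope="session")
def topo():
    return default_topology()


@pytest.fixture(scope="session")
def open_pentamer(topo):
    return syn.build_pentamer(syn.open_blueprint(), topo)


@pytest.fixture(scope="session")
def collapsed_pentamer(topo):
    return syn.build_pentamer(syn.collapsed_blueprint(), topo)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def make_frame(coords, names=None, resnames=None, resseqs=None, chains=None,
               elements=None) -> StructureFrame:
    """Small ad-hoc frame for geometry unit tests."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return StructureFrame(
        serial=np.arange(1, n + 1),
        name=np.array(names if names is not None else ["X"] * n),
        resname=np.array(resnames if resnames is not None else ["ALA"] * n),
        resseq=np.array(resseqs if resseqs is not None else np.arange(1, n + 1)),
        chain=np.array(chains if chains is not None else ["A"] * n),
        element=np.array(elements if elements is not None else ["C"] * n),
        coords=coords,
    )
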