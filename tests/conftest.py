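import numpy as np
import pytest

from confdyn.core import AtomRecord, DomainPartition, EnsembleModel
from confdyn.synthetic import SyntheticSpec, make_ensemble, make_toy_protein


def bead(atom_id, pos, residue=0, name="CA", element="C", resname="ALA",
         chain="A", **kw):
    return AtomRecord(atom_id=atom_id, name=name, element=element,
                      residue_index=residue, residue_name=resname,
                      chain_id=chain, position=np.asarray(pos, float), **kw)


def bead_ensemble(frames, **kw):
    """Ensemble of single-atom-per-residue CA beads from raw coordinates."""
    frames = np.asarray(frames, dtype=float)
    atoms = [bead(i + 1, frames[0, i], residue=i)
             for i in range(frames.shape[1])]
    return EnsembleModel(atoms=atoms, frames=frames, **kw)


@pytest.fixture
def toy_spec():
    return SyntheticSpec(seed=1, n_frames=60)


@pytest.fixture
def toy_protein(toy_spec):
    return make_toy_protein(toy_spec)


@pytest.fixture
def toy_ensemble(toy_spec):
    return make_ensemble(toy_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
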