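import numpy as np
import pytest

from contactfold.fixtures import FixtureSpec, make_native, true_contacts
from contactfold.folding import FoldConfig
from contactfold.io_formats import Model, SequenceRecord
from contactfold.restraints import build_contact_restraints, build_ss_restraints


@pytest.fixture(scope="session")
def bundle():
    """The canonical 3-helix-bundle toy target: (spec, native, ss)."""
    spec = FixtureSpec()
    native, ss = make_native(spec)
    return spec, native, ss


@pytest.fixture(scope="session")
def bundle_contacts(bundle):
    _, native, _ = bundle
    return true_contacts(native)


@pytest.fixture(scope="session")
def bundle_restraints(bundle, bundle_contacts):
    _, native, ss = bundle
    return build_ss_restraints(ss) + build_contact_restraints(
        bundle_contacts, native.sequence
    )


@pytest.fixture
def short_cfg():
    """A desk-scale annealing schedule for unit tests."""
    return FoldConfig(n_steps=400, sweep_iters=15, n_blocks=10, seed=0)


def random_model(L: int, seed: int) -> Model:
    """A random (not chain-valid) model, for I/O round trips and TM tests."""
    rng = np.random.default_rng(seed)
    seq = SequenceRecord(id=f"rnd{seed}", residues="".join(
        rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L)))
    ca = rng.normal(0, 10, (L, 3))
    cb = ca + rng.normal(0, 1, (L, 3))
    is_gly = np.array([c == "G" for c in seq.residues])
    cb[is_gly] = ca[is_gly]
    return Model(sequence=seq, ca=ca, cb=cb, label=f"rnd{seed}")
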