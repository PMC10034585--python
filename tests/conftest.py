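import numpy as np
import pytest

import profscan as ps


@pytest.fixture(scope="session")
def blosum62():
    return ps.load_substitution_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def small_family(blosum62):
    """A 6-member synthetic family at moderate divergence."""
    spec = ps.SyntheticFamilySpec(family="famA", core_length=120, n_members=6,
                                  divergence=0.2, indel_rate=0.01, rng_seed=7)
    members = ps.sample_family(spec, blosum62)
    return ps.FamilySeedSet(family="famA", members=members,
                            master_id=members[0].id)


@pytest.fixture(scope="session")
def small_pssm(small_family, blosum62):
    return ps.build_family_pssm(small_family, blosum62)


def random_protein(rng, length, background):
    from profscan.sequences import AMINO_ACIDS
    codes = rng.choice(20, size=length, p=background)
    return "".join(AMINO_ACIDS[c] for c in codes)


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.Philox(1234))
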