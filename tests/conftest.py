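import pytest

from mitomotif import synthetic_rcrs
from mitomotif.fixtures import FixtureSpec, make_motif_tree, make_reference


@pytest.fixture(scope="session")
def rcrs():
    return synthetic_rcrs()


@pytest.fixture(scope="session")
def toy_spec():
    return FixtureSpec(seed=3, ref_length=600, n_haplogroups=10,
                       motif_separation=3, heteroplasmy_rate=0.3,
                       length_variant_rate=0.3)


@pytest.fixture(scope="session")
def toy_ref(toy_spec):
    return make_reference(toy_spec)


@pytest.fixture(scope="session")
def toy_db(toy_spec, toy_ref):
    return make_motif_tree(toy_spec, toy_ref)
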