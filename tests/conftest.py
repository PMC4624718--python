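import numpy as np
import pytest

from bindprof.fixtures import FixtureSpec, make_template_family, make_toy_dimer
from bindprof.profiles import collect_templates
from bindprof.structmodel import extract_interface


@pytest.fixture(scope="session")
def toy_spec():
    return FixtureSpec(seed=7, n_templates=50, noise_sigma=1.0)


@pytest.fixture(scope="session")
def toy_dimer(toy_spec):
    return make_toy_dimer(toy_spec)


@pytest.fixture(scope="session")
def query_iface(toy_dimer):
    """Classified interface model of the toy dimer (includes SASA)."""
    return extract_interface(toy_dimer)


@pytest.fixture(scope="session")
def family(toy_dimer, toy_spec):
    """Template family with graded coordinate noise and known π."""
    return make_template_family(toy_dimer, toy_spec)


@pytest.fixture(scope="session")
def hits_all(query_iface, family):
    """All template hits against the toy query, sorted by Iscore."""
    return collect_templates(query_iface, family.templates,
                             metric="iscore", cutoff=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
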