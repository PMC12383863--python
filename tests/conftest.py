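import numpy as np
import pytest

from epiclust.amplicons import make_amplicon_reference
from epiclust.cohort import generate_cohort, study_cohort_spec


@pytest.fixture(scope="session")
def bdnf_like_ref():
    """A 168 bp amplicon with 11 CpGs, the layout of the BDNF intron-1 target."""
    return make_amplicon_reference(length=168, n_cpg=11, seed=1, name="A")


@pytest.fixture(scope="session")
def other_ref():
    return make_amplicon_reference(length=200, n_cpg=5, seed=7, name="B")


@pytest.fixture(scope="session")
def two_refs(bdnf_like_ref, other_ref):
    return [bdnf_like_ref, other_ref]


@pytest.fixture(scope="session")
def study_spec():
    return study_cohort_spec()


@pytest.fixture(scope="session")
def study_cohort(study_spec):
    """One seeded cohort of 200 subjects with its true component labels."""
    return generate_cohort(study_spec, seed=11)


@pytest.fixture(scope="session")
def tscores(study_cohort):
    table, _ = study_cohort
    return table[["internalizing", "externalizing"]].to_numpy(float)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
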