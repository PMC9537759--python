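import numpy as np
import pytest

from hepaflux import build_reference_model


@pytest.fixture(scope="session")
def reference_doc():
    return build_reference_model()


@pytest.fixture(scope="session")
def reference_partition(reference_doc):
    from hepaflux import partition_stoichiometry

    return partition_stoichiometry(reference_doc.to_stoichiometric_model())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
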