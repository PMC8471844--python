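import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

import karyostd as ks


@pytest.fixture(scope="session")
def reference_karyotypes():
    """The packaged reference karyotypes (CAU, CCA, CGI), categories verbatim."""
    return ks.load_reference_karyotypes()


@pytest.fixture(scope="session")
def derived_karyotypes():
    """Karyotypes rebuilt by classifying the reference median columns."""
    return {
        sp: ks.build_karyotype(sp, ks.reference_medians(sp))
        for sp in ("CAU", "CCA", "CGI")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20210907)
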