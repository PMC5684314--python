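from __future__ import annotations

import numpy as np
import pytest

from toolkit_scan.ceg import CegReference
from toolkit_scan.search import ScoringScheme, local_align
from toolkit_scan.synth import toy_ceg_reference


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session", autouse=True)
def warm_kernels(scheme):
    """Trigger the one-off JIT compilation outside any timed assertion."""
    local_align("MKV", "MKV", scheme)


@pytest.fixture(scope="session")
def toy_reference() -> CegReference:
    proteins, cds = toy_ceg_reference()
    return CegReference(proteins=dict(proteins), cds=dict(cds))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
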