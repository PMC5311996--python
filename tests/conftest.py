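"""Shared fixtures: small synthetic objects reused across the suite.

Everything is generated programmatically; session scope keeps the
expensive 128-matrix objects to a single construction.
"""

from __future__ import annotations

import numpy as np
import pytest

from mjbsense import (
    SenseKernel,
    make_csm,
    make_phantom,
    synthesize_blades,
    undersample,
)


@pytest.fixture(scope="session")
def truth64():
    return make_phantom(64)


@pytest.fixture(scope="session")
def csm64():
    return make_csm(64, 6, seed=0)


@pytest.fixture(scope="session")
def truth128():
    return make_phantom(128)


@pytest.fixture(scope="session")
def csm128():
    return make_csm(128, 8, seed=0)


@pytest.fixture(scope="session")
def blades128_r4(truth128, csm128):
    """16 blades, ETL 10 at R=4 (width 40), noise-free, no motion."""
    full = synthesize_blades(truth128, csm128, 16, 40, 128)
    return undersample(full, 4)


@pytest.fixture(scope="session")
def kernel128_r4(blades128_r4, csm128):
    return SenseKernel.prepare(blades128_r4, csm128)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
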