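from __future__ import annotations

import numpy as np
import pytest

from ndescan import (
    ProteinRecord,
    ReferencePanel,
    SimulationConfig,
    annotate,
    build_benchmark,
)
from ndescan.simulate import random_protein

#: Seed for every randomized fixture in the suite.
SUITE_SEED = 11


@pytest.fixture(scope="session")
def default_benchmark():
    """The default synthetic benchmark: 20 true homologs (35-90% identity),
    20 outgroup-side decoys, 10 length decoys, 50 random decoys over 60
    samples."""
    return build_benchmark(SimulationConfig(seed=SUITE_SEED))


@pytest.fixture(scope="session")
def default_annotation(default_benchmark):
    """Full cascade run on the default benchmark (shared; ~30 s)."""
    return annotate(default_benchmark.panels, default_benchmark.proteomes)


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture(scope="session")
def small_panel():
    """A tiny panel with one reference and one distantly related outgroup."""
    rng = np.random.default_rng(101)
    ref = random_protein(rng, 120, id="ref1")
    out = random_protein(rng, 120, id="out1")
    return ReferencePanel("NicX", (ref,), (out,))


def make_protein(seq: str, id: str = "p", **kw) -> ProteinRecord:
    return ProteinRecord(id, seq, **kw)
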