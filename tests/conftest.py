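"""Shared fixtures: a toy hairpin with known calls, and simulated corpora."""

from __future__ import annotations

import pytest

from mirtail.formats import HairpinRecord, MatureAnnotation
from mirtail.mapper import MapConfig
from mirtail.simulate import (
    SimConfig,
    classify_simulated,
    generate_library,
    make_reference,
)

# let-7-like toy reference: the mature spans the first 22 nt of the hairpin
TOY_HAIRPIN_SEQ = "TGAGGTAGTAGGTTGTATAGTTGGGATCCAA"
TOY_MATURE_SEQ = TOY_HAIRPIN_SEQ[:22]


@pytest.fixture(scope="session")
def toy_hairpin() -> HairpinRecord:
    return HairpinRecord("hp-toy", TOY_HAIRPIN_SEQ)


@pytest.fixture(scope="session")
def toy_mature() -> MatureAnnotation:
    return MatureAnnotation("mir-toy", "hp-toy", 0, 22)


@pytest.fixture(scope="session")
def map_cfg() -> MapConfig:
    return MapConfig()


@pytest.fixture(scope="session")
def sim_corpus():
    """The package's reference simulation: 50k reads at the default study
    conditions, classified per read.  Shared across recovery/soundness tests."""
    cfg = SimConfig(seed=101)
    reference = make_reference(cfg)
    reads, truth = generate_library(cfg, reference)
    calls = classify_simulated(reads, reference)
    return cfg, reference, reads, truth, calls
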