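import numpy as np
import pytest

from pliertlc.genome import Viewpoint, digest_reference
from pliertlc.simulate import (
    Rearrangement,
    SimulationConfig,
    make_reference,
    simulate_sample,
)

# A small 3 Mb geometry for unit tests (fast to digest and simulate).
SMALL_CHROMS = (("chr1", 1_000_000), ("chr2", 1_000_000), ("chr3", 1_000_000))
SMALL_VP = Viewpoint(name="TARGET1", chrom="chr1", start=450_000, end=550_000)
SMALL_REAR = Rearrangement(
    viewpoint="TARGET1",
    kind="reciprocal",
    target_chrom="chr1",
    target_breakpoint=500_000,
    partner_chrom="chr2",
    partner_breakpoint=500_000,
)


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        chromosome_lengths=SMALL_CHROMS,
        viewpoints=(SMALL_VP,),
        n_reads=20_000,
        seed=3,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_reference():
    sequences, chroms = make_reference(dict(SMALL_CHROMS), 141, seed=1)
    return sequences, chroms


@pytest.fixture(scope="session")
def small_segments(small_reference):
    sequences, _ = small_reference
    return digest_reference(sequences)


@pytest.fixture(scope="session")
def rearranged_library(small_reference, small_segments):
    """A fully rearranged small library (every cell carries the event)."""
    sequences, _ = small_reference
    cfg = small_config(rearrangements=(SMALL_REAR,), rearranged_fraction=1.0, seed=5)
    rs, truth = simulate_sample(cfg, sequences=sequences, segments=small_segments)
    return cfg, rs, truth
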