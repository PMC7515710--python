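import numpy as np
import pytest

from archterm import SimulationConfig, StrandedTrack, TranscriptionUnit
from archterm.synthetic_data import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-TU simulated study (2 conditions x 2 replicates), shared
    read-only across tests."""
    return simulate_dataset(SimulationConfig(seed=11, n_tus=40))


@pytest.fixture
def flat_genome_lengths():
    return {"chr1": 1000}


def make_track(lengths, kind="three_prime_end", **positions):
    """Hand-built track; positions maps strand -> {pos: count}."""
    track = StrandedTrack(lengths, kind=kind)
    for strand, vals in positions.items():
        for chrom in lengths:
            arr = track.get(chrom, strand)
            for pos, count in vals.items():
                arr[pos] = count
    return track


def plus_tu(tu_id="TU0", start=100, end=600, sce=399, tts=None):
    return TranscriptionUnit(tu_id, "chr1", "+", start, end,
                             stop_codon_end=sce, tts=tts)
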