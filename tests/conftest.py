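import numpy as np
import pytest

from hybrec.alignment_io import build_pileup
from hybrec.encoding import encode_read
from hybrec.synthetic_data import (
    ErrorProfile,
    figure_fixture,
    oracle_alignments,
    simulate_genome,
    simulate_long_reads,
    simulate_short_reads,
)


@pytest.fixture(scope="session")
def fig():
    """The worked-example fixture: long read, alignments, pileup, encoding."""
    long_read, alignments = figure_fixture()
    pileup = build_pileup(long_read, alignments)
    encoded = encode_read(pileup, None, long_read)
    return {
        "long_read": long_read,
        "alignments": alignments,
        "pileup": pileup,
        "encoded": encoded,
        "map": encoded.map,
    }


def make_sim(
    seed: int,
    genome_length: int = 8000,
    n_long: int = 4,
    long_mean: int = 1500,
    long_profile: ErrorProfile | None = None,
    coverage: float = 20.0,
    short_profile: ErrorProfile | None = None,
):
    """A small simulated instance: genome, reads, truths, oracle alignments."""
    genome = simulate_genome(genome_length, seed)
    long_profile = long_profile or ErrorProfile(0.05, 0.04, 0.04)
    short_profile = short_profile or ErrorProfile(0.005, 0.0, 0.0)
    long_reads, long_truth = simulate_long_reads(
        genome, n_long, long_mean, long_profile, seed + 1
    )
    short_reads, short_truth = simulate_short_reads(
        genome, coverage, 100, short_profile, seed + 2
    )
    alignments = oracle_alignments(long_reads, long_truth, short_reads, short_truth)
    return {
        "genome": genome,
        "long_reads": long_reads,
        "long_truth": long_truth,
        "short_reads": short_reads,
        "short_truth": short_truth,
        "alignments": alignments,
    }


@pytest.fixture(scope="session")
def small_sim():
    sim = make_sim(seed=11)
    by_target = {}
    for aln in sim["alignments"]:
        by_target.setdefault(aln.target_id, []).append(aln)
    sim["pileups"] = {
        r.id: build_pileup(r, by_target.get(r.id, [])) for r in sim["long_reads"]
    }
    sim["encoded"] = [
        encode_read(sim["pileups"][r.id], None, r) for r in sim["long_reads"]
    ]
    return sim
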