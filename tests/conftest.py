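import numpy as np
import pytest

from mitobait.seq_io import ReadPool, SeqRecord, reverse_complement
from mitobait.simulate import GenomeSpec, SimConfig, simulate_ancestor, simulate_reads


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    """Repeat-free ~3 kb circular genome."""
    return SeqRecord("toy", simulate_ancestor(GenomeSpec(3000, 0.55, rng_seed=7)).seq)


@pytest.fixture
def toy_reads(toy_genome):
    """Error-free 40x 150 bp paired reads from the toy genome (circular sampling)."""
    return simulate_reads(toy_genome,
                          SimConfig(150, 350, 40, 800, rng_seed=3))


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def tile_reads(genome_seq, read_len, step, prefix="t", flip_every=None):
    """Exact tiling reads over a linear sequence; every ``flip_every``-th
    read is reverse-complemented to exercise strand handling."""
    out = []
    i = 0
    starts = list(range(0, len(genome_seq) - read_len + 1, step))
    if starts and starts[-1] != len(genome_seq) - read_len:
        starts.append(len(genome_seq) - read_len)  # cover the tail
    for start in starts:
        seq = genome_seq[start:start + read_len]
        if flip_every and i % flip_every == flip_every - 1:
            seq = reverse_complement(seq)
        out.append(SeqRecord(f"{prefix}{i}", seq))
        i += 1
    return out


def mutate_at(seq, positions):
    """Deterministically substitute each listed position (A<->C, G<->T)."""
    swap = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}
    s = list(seq)
    for p in positions:
        s[p] = swap[s[p]]
    return "".join(s)
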