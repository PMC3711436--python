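"""Baiting module against a brute-force window-scanning oracle."""

import numpy as np
import pytest

from mitobait.baiting import (BaitParams, PoolKmerLookup, bait_reads,
                              build_kmer_index, canonical_kmers)
from mitobait.seq_io import ReadPool, SeqRecord, reverse_complement

from conftest import random_dna


def brute_canonical_kmers(seq, k):
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if "N" in w:
            continue
        out.add(min(w, reverse_complement(w)))
    return out


def encode(kmer):
    v = 0
    for c in kmer:
        v = (v << 2) | "ACGT".index(c)
    return v


def brute_bait(read_seq, ref_seq, k, n):
    """Oracle: count distinct read k-mers occurring exactly in the reference
    on either strand."""
    ref_kmers = brute_canonical_kmers(ref_seq, k)
    shared = brute_canonical_kmers(read_seq, k) & ref_kmers
    return len(shared) >= n


def test_index_of_single_kmer_reference():
    ref = SeqRecord("r", random_dna(np.random.default_rng(0), 31))
    assert len(build_kmer_index([ref], 31)) == 1


def test_index_matches_brute_force_enumeration():
    ref = SeqRecord("r", "ACGTACGTA")
    idx = build_kmer_index([ref], 4)
    expected = {encode(min(w, reverse_complement(w)))
                for w in (ref.seq[i:i + 4] for i in range(6))}
    assert idx.kmers == expected
    assert len(idx) == len(brute_canonical_kmers(ref.seq, 4))


def test_windows_containing_n_are_skipped():
    ref = SeqRecord("r", "ACGTANCGTA")  # N at position 5
    idx = build_kmer_index([ref], 4)
    assert idx.kmers == {encode(min(w, reverse_complement(w)))
                         for w in ("ACGT", "CGTA")}


def test_all_refs_shorter_than_k_is_error():
    with pytest.raises(ValueError, match="no baitable k-mers"):
        build_kmer_index([SeqRecord("r", "ACGT")], 31)


def test_read_equal_to_reference_31mer_recruited(rng):
    ref = SeqRecord("ref", random_dna(rng, 200))
    read = SeqRecord("read", ref.seq[50:81])
    index = build_kmer_index([ref], 31)
    out = bait_reads(ReadPool([read]), index, BaitParams())
    assert [r.id for r in out.records] == ["read"]


def test_reverse_complement_read_recruited(rng):
    ref = SeqRecord("ref", random_dna(rng, 200))
    read = SeqRecord("read", reverse_complement(ref.seq[50:81]))
    index = build_kmer_index([ref], 31)
    out = bait_reads(ReadPool([read]), index, BaitParams())
    assert len(out.records) == 1


def test_thirty_base_shared_stretch_not_recruited(rng):
    """A 100 bp read whose longest exact shared stretch is 30 bp < k=31."""
    ref = SeqRecord("ref", random_dna(rng, 300))
    read_seq = ref.seq[100:130] + random_dna(rng, 70)
    # confirm with the oracle that no 31-mer is shared
    assert not brute_bait(read_seq, ref.seq, 31, 1)
    index = build_kmer_index([ref], 31)
    out = bait_reads(ReadPool([SeqRecord("read", read_seq)]), index, BaitParams())
    assert out.records == []


@pytest.mark.parametrize("n", [1, 2])
def test_bait_equals_brute_force_oracle_on_random_instances(n):
    rng = np.random.default_rng(99)
    for trial in range(20):
        k = int(rng.integers(8, 14))
        ref = SeqRecord("ref", random_dna(rng, int(rng.integers(40, 120))))
        reads = []
        for i in range(30):
            if rng.random() < 0.5:
                s = int(rng.integers(0, max(1, len(ref.seq) - 20)))
                seq = ref.seq[s:s + int(rng.integers(k, 25))]
                if len(seq) < k:
                    seq = random_dna(rng, 20)
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
            else:
                seq = random_dna(rng, int(rng.integers(k, 30)))
            reads.append(SeqRecord(f"r{i}", seq))
        pool = ReadPool(reads)
        index = build_kmer_index([ref], k)
        got = {r.id for r in bait_reads(pool, index, BaitParams(k=k, n=n)).records}
        want = {r.id for r in reads if brute_bait(r.seq, ref.seq, k, n)}
        assert got == want


def test_monotone_in_reference_extension(rng):
    """bait(substring index) is a subset of bait(full reference index)."""
    full = SeqRecord("full", random_dna(rng, 400))
    sub = SeqRecord("sub", full.seq[100:250])
    reads = ReadPool([SeqRecord(f"r{i}", full.seq[s:s + 40])
                      for i, s in enumerate(range(0, 360, 7))])
    small = {r.id for r in bait_reads(reads, build_kmer_index([sub], 31)).records}
    big = {r.id for r in bait_reads(reads, build_kmer_index([full], 31)).records}
    assert small <= big


def test_no_cross_recruitment_without_shared_kmers(rng):
    """Baiting one genome recruits zero error-free reads of another when the
    two share no canonical 31-mer."""
    a = SeqRecord("a", random_dna(rng, 2000))
    b = SeqRecord("b", random_dna(rng, 2000))
    assert not (canonical_kmers(a.seq, 31) & canonical_kmers(b.seq, 31))
    reads_b = ReadPool([SeqRecord(f"b{i}", b.seq[s:s + 100])
                        for i, s in enumerate(range(0, 1900, 50))])
    out = bait_reads(reads_b, build_kmer_index([a], 31), BaitParams())
    assert out.records == []


def test_pair_rescue_recruits_mate(rng):
    ref = SeqRecord("ref", random_dna(rng, 200))
    hit = SeqRecord("p/1", ref.seq[10:60])
    mate = SeqRecord("p/2", random_dna(rng, 50))
    pool = ReadPool([hit, mate], pairing={"p": ("p/1", "p/2")})
    index = build_kmer_index([ref], 31)
    plain = bait_reads(pool, index, BaitParams())
    rescued = bait_reads(pool, index, BaitParams(pair_rescue=True))
    assert {r.id for r in plain.records} == {"p/1"}
    assert {r.id for r in rescued.records} == {"p/1", "p/2"}
    assert rescued.pairing == {"p": ("p/1", "p/2")}


def test_pool_lookup_agrees_with_bait_reads(rng):
    ref = SeqRecord("ref", random_dna(rng, 500))
    reads = [SeqRecord(f"r{i}", random_dna(rng, 60)) for i in range(20)]
    reads += [SeqRecord(f"hit{i}", ref.seq[s:s + 60])
              for i, s in enumerate(range(0, 400, 40))]
    pool = ReadPool(reads)
    index = build_kmer_index([ref], 31)
    expected = {r.id for r in bait_reads(pool, index, BaitParams()).records}
    lookup = PoolKmerLookup(pool.records, 31)
    got = {pool.records[i].id
           for i in lookup.reads_matching(canonical_kmers(ref.seq, 31))}
    assert got == expected
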