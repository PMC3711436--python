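"""Overlap alignment and the two placement acceptance rules."""

import numpy as np
import pytest

from mitobait.assembly import Assembly, Contig
from mitobait.mapping import (MappingParams, Placement, Rejection,
                              align_overlap, place_read)
from mitobait.seq_io import SeqRecord, reverse_complement

from conftest import mutate_at, random_dna

MATCH, MIS, GAP = 1, -1, -2


def oracle_overlap_score(read, contig):
    """Exhaustive free-end-gap DP (pure Python), best score over both strands."""
    def one_strand(q, t):
        m, n = len(q), len(t)
        H = [[0] * (n + 1) for _ in range(m + 1)]
        for i in range(1, m + 1):
            for j in range(1, n + 1):
                s = MATCH if q[i - 1] == t[j - 1] else MIS
                H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + GAP,
                              H[i][j - 1] + GAP)
        return max(max(H[m]), max(H[i][n] for i in range(m + 1)))
    return max(one_strand(read, contig),
               one_strand(reverse_complement(read), contig))


def _asm(seq, circular=False):
    return Assembly([Contig("c1", seq, circular=circular)])


def test_exact_substring_full_length_alignment(rng):
    contig = random_dna(rng, 300)
    read = contig[80:140]
    aln = align_overlap(read, contig)
    assert aln.score == len(read)
    assert aln.mismatches == 0
    assert (aln.ref_start, aln.ref_end) == (80, 140)
    assert aln.ops == [(60, "=")]


def test_hopeless_read_reports_no_alignment():
    assert align_overlap("GGGG", "A" * 40) is None


def test_align_overlap_matches_unbanded_dp_oracle():
    rng = np.random.default_rng(5)
    for trial in range(15):
        contig = random_dna(rng, 300)
        if trial % 3 == 0:
            read = random_dna(rng, 60)
        else:  # reads derived from the contig, some mutated
            s = int(rng.integers(0, 240))
            read = mutate_at(contig[s:s + 60],
                             rng.choice(60, size=int(rng.integers(0, 8)),
                                        replace=False))
            if trial % 2:
                read = reverse_complement(read)
        want = oracle_overlap_score(read, contig)
        aln = align_overlap(read, contig)
        got = aln.score if aln is not None else 0
        assert got == max(want, 0)
        if aln is not None:
            # the reported ops must reproduce the reported score
            recomputed = sum(c if op == "=" else (-c if op == "X" else -2 * c)
                             for c, op in aln.ops)
            assert recomputed == aln.score


def test_interior_mismatch_rule_at_15_percent(rng):
    """100 bp interior read: 15 mismatches accepted, 16 rejected."""
    contig = random_dna(rng, 400)
    base = contig[150:250]
    params = MappingParams()
    read15 = SeqRecord("r15", mutate_at(base, range(40, 85, 3)))  # 15 subs
    read16 = SeqRecord("r16", mutate_at(base, range(40, 88, 3)))  # 16 subs
    p = place_read(read15, _asm(contig), params)
    assert isinstance(p, Placement) and p.mismatches == 15 and p.overlap_len == 100
    r = place_read(read16, _asm(contig), params)
    assert isinstance(r, Rejection) and r.reason == "too_many_mismatches"


@pytest.mark.parametrize("overlap,accepted", [(30, True), (29, False)])
def test_edge_extension_needs_30_base_overlap(rng, overlap, accepted):
    contig = random_dna(rng, 300)
    read = SeqRecord("r", contig[-overlap:] + random_dna(rng, 100 - overlap))
    res = place_read(read, _asm(contig), MappingParams())
    if accepted:
        assert isinstance(res, Placement)
        assert res.overlap_len == overlap
        assert res.right_overhang == read.seq[overlap:]
        assert res.ref_end == 300
    else:
        assert isinstance(res, Rejection)
        assert res.reason == "short_edge_overlap"


def test_identical_interior_read_accepted_with_zero_mismatches(rng):
    contig = random_dna(rng, 400)
    read = SeqRecord("r", contig[100:250])
    p = place_read(read, _asm(contig), MappingParams())
    assert isinstance(p, Placement)
    assert (p.mismatches, p.ref_start, p.ref_end, p.strand) == (0, 100, 250, "+")


def test_acceptance_invariant_under_reverse_complement(rng):
    contig = random_dna(rng, 500)
    for s in (0, 120, 350):
        seq = mutate_at(contig[s:s + 120], [10, 50, 90])
        fwd = place_read(SeqRecord("f", seq), _asm(contig), MappingParams())
        rev = place_read(SeqRecord("r", reverse_complement(seq)), _asm(contig),
                         MappingParams())
        assert isinstance(fwd, Placement) and isinstance(rev, Placement)
        assert (fwd.ref_start, fwd.ref_end, fwd.mismatches) == \
               (rev.ref_start, rev.ref_end, rev.mismatches)
        assert fwd.strand != rev.strand


def test_anchored_placement_agrees_with_full_dp(rng):
    """Anchored (banded) verification equals the exhaustive alignment
    whenever divergence stays within the acceptance threshold."""
    contig = random_dna(rng, 1000)
    for s in range(0, 800, 97):
        positions = rng.choice(150, size=10, replace=False)  # ~7% divergence
        read = SeqRecord("r", mutate_at(contig[s:s + 150], positions))
        p = place_read(read, _asm(contig), MappingParams())
        aln = align_overlap(read.seq, contig)
        assert isinstance(p, Placement)
        assert p.mismatches == aln.mismatches == 10


def test_multi_contig_best_scoring_assignment(rng):
    c1 = random_dna(rng, 200)
    c2 = random_dna(rng, 200)
    read = SeqRecord("r", c2[50:150])
    asm = Assembly([Contig("a", c1), Contig("b", c2)])
    p = place_read(read, asm, MappingParams())
    assert isinstance(p, Placement) and p.contig_id == "b"


def test_circular_contig_accepts_origin_spanning_read(rng):
    seq = random_dna(rng, 500)
    read = SeqRecord("r", seq[450:] + seq[:50])  # spans the origin
    p = place_read(read, _asm(seq, circular=True), MappingParams())
    assert isinstance(p, Placement)
    assert p.mismatches == 0
    assert p.ref_start == 450 and p.ref_end == 550  # modulo contig length
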