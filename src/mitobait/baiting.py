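"""In-silico baiting: recruit reads sharing exact k-mers with a reference.

A read is recruited from the pool iff at least ``n`` of its distinct
canonical k-mers (default k=31, n=1) occur in the reference index. Long
exact k-mers give the step its specificity: the downstream mapping is
tolerant (15% mismatches), so baiting is what keeps foreign reads out of
the growing readpool.

k-mers are canonical (lexicographic/numeric minimum of a window and its
reverse complement) so that matching is strand-symmetric; windows
containing N are skipped because an exact match cannot be satisfied
through an ambiguous base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .seq_io import ReadPool, SeqRecord

__all__ = [
    "BaitParams",
    "KmerIndex",
    "build_kmer_index",
    "bait_reads",
    "PoolKmerLookup",
    "canonical_kmers",
    "iter_kmers",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_RC_CODE = {"A": 3, "C": 2, "G": 1, "T": 0}


@dataclass
class BaitParams:
    """Baiting stringency: require >= n shared canonical k-mers of length k."""

    k: int = 31
    n: int = 1
    pair_rescue: bool = False

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError(f"k must be >= 8, got {self.k}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")


def iter_kmers(seq: str, k: int) -> Iterator[tuple[int, int, int]]:
    """Yield (position, canonical, forward) 2-bit-encoded k-mers of ``seq``.

    Windows containing N (or any non-ACGT character) are skipped. Rolling
    encoding: forward and reverse-complement integers are maintained
    simultaneously; the canonical form is their minimum.
    """
    mask = (1 << (2 * k)) - 1
    shift_rc = 2 * (k - 1)
    fwd = rev = 0
    valid = 0  # length of current N-free run feeding the window
    for i, c in enumerate(seq):
        code = _CODE.get(c)
        if code is None:
            valid = 0
            fwd = rev = 0
            continue
        fwd = ((fwd << 2) | code) & mask
        rev = (rev >> 2) | (_RC_CODE[c] << shift_rc)
        valid += 1
        if valid >= k:
            yield i - k + 1, fwd if fwd <= rev else rev, fwd


def canonical_kmers(seq: str, k: int) -> set[int]:
    """Distinct canonical k-mers of ``seq`` as 2-bit-encoded integers."""
    return {canon for _, canon, _ in iter_kmers(seq, k)}


def decode_kmer(kmer: int, k: int) -> str:
    bases = "ACGT"
    return "".join(bases[(kmer >> (2 * (k - 1 - i))) & 3] for i in range(k))


@dataclass
class KmerIndex:
    """Set of canonical k-mers of the current reference (the baiting filter)."""

    k: int
    kmers: set[int] = field(default_factory=set)

    def __contains__(self, kmer: int) -> bool:
        return kmer in self.kmers

    def __len__(self) -> int:
        return len(self.kmers)


def build_kmer_index(refs: Sequence[SeqRecord], k: int) -> KmerIndex:
    """Index the canonical k-mers of every reference contig jointly.

    All contigs of a (possibly gapped) reference contribute to one index,
    because baiting runs against the whole current reference.
    """
    if not refs:
        raise ValueError("no reference sequences")
    kmers: set[int] = set()
    for ref in refs:
        kmers |= canonical_kmers(ref.seq, k)
    if not kmers:
        raise ValueError(f"no baitable k-mers: all references shorter than k={k} (or all-N)")
    return KmerIndex(k, kmers)


def bait_reads(pool: ReadPool, index: KmerIndex, params: BaitParams | None = None) -> ReadPool:
    """Recruit reads sharing >= n distinct canonical k-mers with the index.

    With ``pair_rescue`` the mate of every recruited read joins the output
    as well. Pairing and provenance annotation survive into the subset.
    """
    params = params or BaitParams(k=index.k)
    if params.k != index.k:
        raise ValueError(f"index built with k={index.k}, params ask k={params.k}")
    hits: set[str] = set()
    for rec in pool.records:
        if params.n == 1:
            if any(canon in index.kmers for _, canon, _ in iter_kmers(rec.seq, params.k)):
                hits.add(rec.id)
        else:
            shared = {c for _, c, _ in iter_kmers(rec.seq, params.k) if c in index.kmers}
            if len(shared) >= params.n:
                hits.add(rec.id)
    if params.pair_rescue:
        mates = pool.mate_map()
        hits |= {mates[i] for i in hits if i in mates}
    return pool.subset(hits)


class PoolKmerLookup:
    """Inverted k-mer index over a read pool for fast repeated baiting.

    The iterative loop baits the same (large) pool against a growing
    reference every iteration. Scanning every read each time is wasteful;
    instead all (canonical k-mer, read) pairs are tabulated once in sorted
    numpy arrays, and each query for a batch of reference k-mers resolves to
    read indices via searchsorted. Distinct k-mers per read are stored, so
    counts answer the ``>= n distinct shared k-mers`` criterion directly.
    """

    def __init__(self, records: Sequence[SeqRecord], k: int):
        if 2 * k > 63:
            raise ValueError("k too large for 64-bit k-mer encoding (k <= 31)")
        self.k = k
        self.n_reads = len(records)
        kmer_chunks: list[np.ndarray] = []
        read_chunks: list[np.ndarray] = []
        for idx, rec in enumerate(records):
            ks = canonical_kmers(rec.seq, k)
            if not ks:
                continue
            arr = np.fromiter(ks, dtype=np.int64, count=len(ks))
            kmer_chunks.append(arr)
            read_chunks.append(np.full(len(ks), idx, dtype=np.int32))
        if kmer_chunks:
            kmers = np.concatenate(kmer_chunks)
            reads = np.concatenate(read_chunks)
            order = np.argsort(kmers, kind="stable")
            self._kmers = kmers[order]
            self._reads = reads[order]
        else:
            self._kmers = np.empty(0, dtype=np.int64)
            self._reads = np.empty(0, dtype=np.int32)

    def reads_matching(self, kmers: Iterable[int], n: int = 1) -> set[int]:
        """Indices of reads sharing >= n distinct canonical k-mers with ``kmers``."""
        query = np.fromiter(set(kmers), dtype=np.int64)
        if query.size == 0 or self._kmers.size == 0:
            return set()
        lo = np.searchsorted(self._kmers, query, side="left")
        hi = np.searchsorted(self._kmers, query, side="right")
        pieces = [self._reads[a:b] for a, b in zip(lo, hi) if b > a]
        if not pieces:
            return set()
        matched = np.concatenate(pieces)
        if n <= 1:
            return set(np.unique(matched).tolist())
        counts = np.bincount(matched, minlength=self.n_reads)
        return set(np.nonzero(counts >= n)[0].tolist())
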