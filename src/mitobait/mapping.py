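"""Tolerant overlap alignment and read placement against the reference.

Acceptance of a read is governed by two rules:

* mismatches (substitutions plus inserted/deleted bases) in at most 15% of
  the columns of the alignment overlap, and
* a read that overhangs a contig end — i.e. would extend the reference —
  needs an overlap of at least 30 bases at that edge.

Candidate locations are found by exact k-mer anchors (baited reads are
guaranteed to share an exact k-mer with the reference, so seed-and-extend
is complete for them) and verified either by direct string comparison
(error-free case) or by an edit-distance alignment of the anchored window
(edlib). ``align_overlap`` additionally provides a full free-end-gap
dynamic-programming alignment used for anchor-less seeds and as the
reference implementation in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .baiting import iter_kmers
from .seq_io import SeqRecord, reverse_complement

__all__ = [
    "MappingParams",
    "Placement",
    "Rejection",
    "OverlapAlignment",
    "align_overlap",
    "place_read",
    "placements_to_tsv",
]

MATCH, MISMATCH, GAP = 1, -1, -2


@dataclass
class MappingParams:
    max_mismatch_frac: float = 0.15
    min_edge_overlap: int = 30
    band_width: int = 20  # window padding around an anchor during verification
    strict_frac: float = 0.05  # high-stringency fraction for the initial mapping
    anchor_k: int = 31
    dp_limit: int = 4_000_000  # max read x contig cells for the anchor-less DP fallback

    def __post_init__(self) -> None:
        if not (0 <= self.strict_frac <= self.max_mismatch_frac <= 1):
            raise ValueError("need 0 <= strict_frac <= max_mismatch_frac <= 1")
        if self.min_edge_overlap < 1:
            raise ValueError("min_edge_overlap must be >= 1")


@dataclass
class Placement:
    """One read's accepted alignment to one contig.

    Coordinates are 0-based half-open on the contig. For circular contigs a
    read may span the origin, in which case ``ref_end`` exceeds the contig
    length and columns are understood modulo the contig length.
    ``read_seq`` is the read oriented to the contig's forward strand.
    """

    read_id: str
    contig_id: str
    ref_start: int
    ref_end: int
    strand: str
    ops: list[tuple[int, str]]  # runs of =, X, I (read-only), D (contig-only)
    mismatches: int
    overlap_len: int
    left_overhang: str = ""
    right_overhang: str = ""
    read_seq: str = ""
    score: int = 0
    contig_index: int = 0


@dataclass
class Rejection:
    read_id: str
    reason: str


@dataclass
class OverlapAlignment:
    score: int
    strand: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    ops: list[tuple[int, str]]
    mismatches: int
    overlap_len: int
    read_seq: str


def _dp_matrix(read: str, contig: str) -> np.ndarray:
    """Free-end-gap (overlap) DP matrix, match +1 / mismatch -1 / gap -2.

    The horizontal recurrence H[i,j] = max(cand[j], H[i,j-1] - 2) is solved
    per row with a prefix max over cand[j] + 2j, which keeps the inner loop
    in numpy.
    """
    m, n = len(read), len(contig)
    carr = np.frombuffer(contig.encode(), dtype=np.uint8)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    idx2 = 2 * np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        sub = np.where(carr == ord(read[i - 1]), MATCH, MISMATCH).astype(np.int32)
        cand = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + GAP)
        g = np.maximum.accumulate(np.concatenate(([0], cand + idx2[1:])))
        H[i, 1:] = np.maximum(cand, g[1:] - idx2[1:])
    return H


def _traceback(H: np.ndarray, read: str, contig: str, i: int, j: int):
    """Walk back from (i, j) to a free-start cell, emitting ops read 5'->3'."""
    ops_rev: list[str] = []
    while i > 0 and j > 0:
        h = H[i, j]
        if h == H[i - 1, j - 1] + (MATCH if read[i - 1] == contig[j - 1] else MISMATCH):
            ops_rev.append("=" if read[i - 1] == contig[j - 1] else "X")
            i -= 1
            j -= 1
        elif h == H[i - 1, j] + GAP:
            ops_rev.append("I")
            i -= 1
        elif h == H[i, j - 1] + GAP:
            ops_rev.append("D")
            j -= 1
        else:  # free-start cell reached (score 0 boundary)
            break
        if H[i, j] == 0 and (i == 0 or j == 0):
            break
    return i, j, _runs(ops_rev[::-1])


def _runs(ops: Sequence[str]) -> list[tuple[int, str]]:
    runs: list[tuple[int, str]] = []
    for op in ops:
        if runs and runs[-1][1] == op:
            runs[-1] = (runs[-1][0] + 1, op)
        else:
            runs.append((1, op))
    return runs


def _ops_stats(ops: list[tuple[int, str]]) -> tuple[int, int]:
    """(mismatches, overlap_len): edits and total columns of an op-run list."""
    mism = sum(c for c, op in ops if op in "XID")
    cols = sum(c for c, op in ops if op in "=XID")
    return mism, cols


def _best_end(H: np.ndarray) -> tuple[int, int]:
    m = H.shape[0] - 1
    n = H.shape[1] - 1
    jbest = int(np.argmax(H[m, :]))
    ibest = int(np.argmax(H[:, n]))
    if H[m, jbest] >= H[ibest, n]:
        return m, jbest
    return ibest, n


def align_overlap(read: SeqRecord | str, contig: str,
                  band_width: int = 20) -> Optional[OverlapAlignment]:
    """Best overlap (free end gap) alignment of read vs contig, both strands.

    Scoring is match +1, mismatch -1, gap -2. Leading/trailing gaps in either
    sequence are free; the reported span is the aligned core. Returns None
    when no alignment scores above zero (no credible overlap). The exhaustive
    matrix is computed — at mitogenome scale this path is only used for
    anchor-less seeds, where completeness matters more than speed;
    ``band_width`` sizes the verification window in the anchored path.
    """
    rseq = read.seq if isinstance(read, SeqRecord) else read
    rid = read.id if isinstance(read, SeqRecord) else "read"
    best: Optional[OverlapAlignment] = None
    for strand, oriented in (("+", rseq), ("-", reverse_complement(rseq))):
        H = _dp_matrix(oriented, contig)
        i_end, j_end = _best_end(H)
        score = int(H[i_end, j_end])
        if score <= 0:
            continue
        i0, j0, ops = _traceback(H, oriented, contig, i_end, j_end)
        mism, cols = _ops_stats(ops)
        aln = OverlapAlignment(score, strand, j0, j_end, i0, i_end,
                               ops, mism, cols, oriented)
        if best is None or score > best.score or (
            score == best.score and (aln.ref_start, strand) < (best.ref_start, best.strand)
        ):
            best = aln
    return best


# ---------------------------------------------------------------------------
# anchored placement


def kmer_pos_map(seq: str, k: int) -> dict[int, list[tuple[int, int]]]:
    """canonical k-mer -> [(position, forward encoding)] over ``seq``."""
    kmap: dict[int, list[tuple[int, int]]] = {}
    for pos, canon, fwd in iter_kmers(seq, k):
        kmap.setdefault(canon, []).append((pos, fwd))
    return kmap


def _contig_kmap(contig, k: int) -> dict[int, list[tuple[int, int]]]:
    """Anchor map for a contig, cached on the object; doubled when circular."""
    cached = getattr(contig, "_kmap", None)
    if cached is not None and getattr(contig, "_kmap_k", None) == k \
            and getattr(contig, "_kmap_len", None) == len(contig.seq):
        return cached
    seq = contig.seq * 2 if getattr(contig, "circular", False) else contig.seq
    kmap = kmer_pos_map(seq, k)
    try:
        contig._kmap = kmap
        contig._kmap_k = k
        contig._kmap_len = len(contig.seq)
    except AttributeError:
        pass
    return kmap


def anchor_candidates(read_seq: str, kmap: dict[int, list[tuple[int, int]]],
                      k: int, max_candidates: int = 50) -> list[tuple[int, str]]:
    """Distinct (start, strand) diagonals implied by exact k-mer anchors."""
    cands: list[tuple[int, str]] = []
    seen: set[tuple[int, str]] = set()
    m = len(read_seq)
    for rpos, canon, rfwd in iter_kmers(read_seq, k):
        for cpos, cfwd in kmap.get(canon, ()):
            if rfwd == cfwd:
                key = (cpos - rpos, "+")
            else:
                key = (cpos - (m - k - rpos), "-")
            if key not in seen:
                seen.add(key)
                cands.append(key)
                if len(cands) >= max_candidates:
                    return cands
    return cands


def _parse_cigar(cigar: str, query: str, target: str, q0: int, t0: int) -> list[tuple[int, str]]:
    """Expand an edlib CIGAR into op runs, resolving M by base comparison."""
    ops: list[str] = []
    qi, ti = q0, t0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        count = int(num)
        num = ""
        if ch in "=M":
            for _ in range(count):
                ops.append("=" if query[qi] == target[ti] else "X")
                qi += 1
                ti += 1
        elif ch == "X":
            ops.extend("X" * count)
            qi += count
            ti += count
        elif ch == "I":  # consumes query only
            ops.extend("I" * count)
            qi += count
        elif ch == "D":  # consumes target only
            ops.extend("D" * count)
            ti += count
        else:
            raise ValueError(f"unexpected CIGAR op {ch!r}")
    return _runs(ops)


def _verify_candidate(read_or: str, contig_seq: str, L: int, circular: bool,
                      start: int, params: MappingParams):
    """Check one anchored diagonal; return (ops, mism, cols, ref_start, ref_end,
    left_oh, right_oh) or None when nothing aligns."""
    m = len(read_or)
    search = contig_seq * 2 if circular else contig_seq
    if circular:
        start %= L
        ref_start, ref_end = start, start + m
        if ref_end > len(search):
            return None
        ov_read = read_or
    else:
        ref_start = max(0, start)
        ref_end = min(L, start + m)
        if ref_end - ref_start < 1:
            return None
        ov_read = read_or[ref_start - start: ref_end - start]
    window = search[ref_start:ref_end]
    if ov_read == window:
        ops = [(len(ov_read), "=")]
        mism, cols = 0, len(ov_read)
    else:
        pad = params.band_width
        w0 = max(0, ref_start - pad)
        w1 = min(len(search), ref_end + pad)
        res = edlib.align(ov_read, search[w0:w1], mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            return None
        loc = res["locations"][0]
        ops = _parse_cigar(res["cigar"], ov_read, search, 0, w0 + loc[0])
        mism, cols = _ops_stats(ops)
        ref_start = w0 + loc[0]
        ref_end = w0 + loc[1] + 1
    if circular:
        left_oh = right_oh = ""
    else:
        # overhangs only count at contig ends
        left_oh = read_or[: max(0, -start)] if ref_start == 0 and start < 0 else ""
        right_oh = (read_or[ref_end - start:]
                    if ref_end == L and start + m > L else "")
    return ops, mism, cols, ref_start, ref_end, left_oh, right_oh


def place_read(read: SeqRecord, assembly, params: MappingParams | None = None,
               max_mismatch_frac: float | None = None) -> Placement | Rejection:
    """Place a read on the best-scoring contig of ``assembly``.

    ``assembly`` is any object with a ``contigs`` sequence (id, seq,
    circular). Acceptance requires mismatches <= floor(frac * overlap
    columns) and, for reads overhanging a contig end, an edge overlap of at
    least ``min_edge_overlap`` bases. Ties go to the lowest contig index,
    then lower start, then the + strand. Rejections carry a reason.
    """
    params = params or MappingParams()
    frac = params.max_mismatch_frac if max_mismatch_frac is None else max_mismatch_frac
    contigs = assembly.contigs if hasattr(assembly, "contigs") else assembly
    best: Placement | None = None
    fail_reason = "no_anchor"
    oriented = {"+": read.seq, "-": reverse_complement(read.seq)}
    for ci, contig in enumerate(contigs):
        L = len(contig.seq)
        circular = bool(getattr(contig, "circular", False))
        if params.anchor_k <= len(read.seq):
            kmap = _contig_kmap(contig, params.anchor_k)
            cands = anchor_candidates(read.seq, kmap, params.anchor_k)
        else:
            cands = []
        if not cands and len(read.seq) * L <= params.dp_limit:
            aln = align_overlap(read.seq, contig.seq, params.band_width)
            if aln is None:
                fail_reason = "no_alignment"
                continue
            cands = [(aln.ref_start - aln.read_start, aln.strand)]
        for start, strand in cands:
            got = _verify_candidate(oriented[strand], contig.seq, L, circular,
                                    start, params)
            if got is None:
                continue
            ops, mism, cols, ref_start, ref_end, loh, roh = got
            if mism > int(frac * cols):
                fail_reason = "too_many_mismatches"
                continue
            if (loh or roh) and cols < params.min_edge_overlap:
                fail_reason = "short_edge_overlap"
                continue
            score = (cols - mism) - mism
            cand = Placement(read.id, contig.id, ref_start, ref_end, strand,
                             ops, mism, cols, loh, roh, oriented[strand],
                             score, ci)
            if best is None or cand.score > best.score or (
                cand.score == best.score
                and (cand.contig_index, cand.ref_start, cand.strand)
                < (best.contig_index, best.ref_start, best.strand)
            ):
                best = cand
    if best is None:
        return Rejection(read.id, fail_reason)
    assert best.mismatches <= best.overlap_len * frac + 1e-9
    return best


def placements_to_tsv(results: Sequence[Placement | Rejection], path) -> None:
    """Write placements/rejections as TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("read_id\tcontig_id\tstart\tend\tstrand\tmismatches\t"
                 "overlap_len\taccepted\treason\n")
        for r in results:
            if isinstance(r, Placement):
                fh.write(f"{r.read_id}\t{r.contig_id}\t{r.ref_start + 1}\t"
                         f"{r.ref_end}\t{r.strand}\t{r.mismatches}\t"
                         f"{r.overlap_len}\ttrue\t.\n")
            else:
                fh.write(f"{r.read_id}\t.\t.\t.\t.\t.\t.\tfalse\t{r.reason}\n")
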