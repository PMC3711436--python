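"""Consensus construction, a greedy verification assembler, and circularity.

``build_consensus`` turns accepted placements into a new reference: columns
are called by majority vote over the placed read bases (the previous
reference base never votes, so distant-reference sequence cannot leak into
the output), uncovered columns are excised and split the contig, and
accepted edge overhangs extend the contig outward.

``greedy_assemble`` is a small overlap-layout-consensus assembler used in
de-novo verification mode: it repeatedly merges the best suffix-prefix
overlap until none qualifies. Candidate overlaps are seeded by an exact
prefix gram, so with error-free reads it is complete; overlaps whose
seed region itself is mutated can be missed (acceptable for a
verification-mode assembler at mitogenome scale).

``detect_circularity`` trims the duplicated terminal overlap a linear
assembly of a circular genome accumulates, and flags the contig circular.
"""

from __future__ import annotations

import heapq
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from .mapping import Placement
from .seq_io import ReadPool, SeqRecord, reverse_complement

log = logging.getLogger(__name__)

__all__ = [
    "Contig",
    "Assembly",
    "build_consensus",
    "greedy_assemble",
    "detect_circularity",
]

_BASES = "ACGT-"
_BASE_ROW = {b: i for i, b in enumerate(_BASES)}


@dataclass
class Contig:
    id: str
    seq: str
    coverage: np.ndarray | None = None
    circular: bool = False

    def __post_init__(self) -> None:
        if self.coverage is None:
            self.coverage = np.zeros(len(self.seq), dtype=np.int32)
        elif len(self.coverage) != len(self.seq):
            raise ValueError(f"contig {self.id}: coverage length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    """Ordered contigs representing the current (possibly gapped) reference."""

    contigs: list[Contig] = field(default_factory=list)
    recruited_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contig ids")

    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def records(self) -> list[SeqRecord]:
        return [SeqRecord(c.id, c.seq) for c in self.contigs]


def _majority_base(counts: np.ndarray) -> str:
    """Column call: argmax over A,C,G,T,'-'; ties prefer a base (row order)
    and, among bases, the alphabetically first."""
    return _BASES[int(np.argmax(counts))]


def build_consensus(placements: Sequence[Placement], assembly: Assembly,
                    min_cov: int = 1) -> Assembly:
    """Majority-vote consensus over placed reads, with extension and splitting.

    Columns with read coverage below ``min_cov`` are excised and split the
    contig (the new reference may be gapped). Edge overhangs of accepted
    placements are appended as extensions with their own coverage.
    Insertions/deletions supported by a strict majority of covering reads
    are incorporated. Contig order follows the input assembly.
    """
    if not placements:
        log.warning("no placements: assembly returned unchanged")
        return assembly
    by_contig: dict[str, list[Placement]] = {}
    for p in placements:
        by_contig.setdefault(p.contig_id, []).append(p)

    new_contigs: list[Contig] = []
    placed_ids = {p.read_id for p in placements}
    for contig in assembly.contigs:
        plist = by_contig.get(contig.id, [])
        if not plist:
            new_contigs.append(contig)
            continue
        L = len(contig.seq)
        counts = np.zeros((5, L), dtype=np.int32)
        ins_votes: Counter = Counter()  # (column, inserted seq) -> support
        left_ext: dict[int, Counter] = {}
        right_ext: dict[int, Counter] = {}
        for p in plist:
            qi = len(p.left_overhang)
            ti = p.ref_start
            if len(p.ops) == 1 and p.ops[0][1] == "=":  # exact fast path
                n = p.ops[0][0]
                cols = np.arange(ti, ti + n)
                if contig.circular:
                    cols %= L
                codes = np.frombuffer(
                    p.read_seq[qi:qi + n].encode(), dtype=np.uint8)
                rows = np.empty(n, dtype=np.int64)
                for b, r in (("A", 0), ("C", 1), ("G", 2), ("T", 3), ("N", 0)):
                    rows[codes == ord(b)] = r
                np.add.at(counts, (rows, cols), 1)
            else:
                pend_ins = ""
                for cnt, op in p.ops:
                    for _ in range(cnt):
                        if op in "=X":
                            if pend_ins:
                                ins_votes[(ti % L if contig.circular else ti,
                                           pend_ins)] += 1
                                pend_ins = ""
                            col = ti % L if contig.circular else ti
                            counts[_BASE_ROW.get(p.read_seq[qi], 0), col] += 1
                            qi += 1
                            ti += 1
                        elif op == "I":
                            pend_ins += p.read_seq[qi]
                            qi += 1
                        elif op == "D":
                            col = ti % L if contig.circular else ti
                            counts[4, col] += 1
                            ti += 1
            if p.left_overhang:
                for d in range(1, len(p.left_overhang) + 1):
                    left_ext.setdefault(d, Counter())[p.left_overhang[-d]] += 1
            if p.right_overhang:
                for d in range(1, len(p.right_overhang) + 1):
                    right_ext.setdefault(d, Counter())[p.right_overhang[d - 1]] += 1

        cov = counts.sum(axis=0)
        committed_ins: dict[int, tuple[str, int]] = {}
        for (col, seq), support in ins_votes.items():
            if 2 * support > cov[col] and (
                col not in committed_ins or support > committed_ins[col][1]
            ):
                committed_ins[col] = (seq, support)

        # assemble consensus segments, splitting at under-covered columns
        segments: list[tuple[list[str], list[int]]] = []
        cur_seq: list[str] = []
        cur_cov: list[int] = []
        for j in range(L):
            if cov[j] < min_cov:
                if cur_seq:
                    segments.append((cur_seq, cur_cov))
                cur_seq, cur_cov = [], []
                continue
            if j in committed_ins and cur_seq:
                iseq, isup = committed_ins[j]
                for c in iseq:
                    cur_seq.append(c)
                    cur_cov.append(isup)
            base = _majority_base(counts[:, j])
            if base != "-":
                cur_seq.append(base)
                cur_cov.append(int(cov[j]))
        if cur_seq:
            segments.append((cur_seq, cur_cov))

        def _extension(votes: dict[int, Counter]) -> tuple[str, list[int]]:
            out, ocov = [], []
            for d in range(1, len(votes) + 1):
                c = votes.get(d)
                if not c or sum(c.values()) < min_cov:
                    break
                base = min(sorted(c), key=lambda b: (-c[b], b))
                out.append(base)
                ocov.append(c[base])
            return "".join(out), ocov

        if segments and not contig.circular:
            lext, lcov = _extension(left_ext)
            if lext:
                s0, c0 = segments[0]
                segments[0] = (list(lext[::-1]) + s0, lcov[::-1] + c0)
            rext, rcov = _extension(right_ext)
            if rext:
                s1, c1 = segments[-1]
                segments[-1] = (s1 + list(rext), c1 + rcov)

        if not segments:
            log.warning("contig %s lost all coverage; dropped", contig.id)
            continue
        for si, (sseq, scov) in enumerate(segments):
            cid = contig.id if len(segments) == 1 else f"{contig.id}.{si + 1}"
            new_contigs.append(Contig(cid, "".join(sseq),
                                      np.asarray(scov, dtype=np.int32),
                                      circular=contig.circular and len(segments) == 1))
    return Assembly(new_contigs, set(assembly.recruited_ids) | placed_ids)


# ---------------------------------------------------------------------------
# greedy de-novo assembler (verification mode)


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def greedy_assemble(pool: ReadPool | Sequence[SeqRecord], min_overlap: int = 30,
                    max_mismatch_frac: float = 0.0) -> list[Contig]:
    """Greedy overlap-layout-consensus assembly of a small read pool.

    Repeatedly merges the highest-scoring suffix-prefix overlap (score =
    overlap - 2*mismatches, ungapped) of length >= ``min_overlap`` and
    within ``max_mismatch_frac``, with majority consensus weighted by
    accumulated coverage, until no merge qualifies. Both orientations are
    considered; contained sequences are absorbed. Deterministic tie-break:
    longer merged length, then lexicographically smaller id pair.
    """
    records = list(pool.records) if isinstance(pool, ReadPool) else list(pool)
    if len(records) > 100_000:
        raise ValueError("greedy_assemble is meant for reduced (mitogenome-scale) pools")
    g = max(8, min(20, min_overlap))

    seqs: dict[int, str] = {}
    covs: dict[int, np.ndarray] = {}
    names: dict[int, str] = {}
    arrays: dict[tuple[int, str], np.ndarray] = {}

    def _arr(idx: int, orient: str) -> np.ndarray:
        key = (idx, orient)
        if key not in arrays:
            s = seqs[idx] if orient == "+" else reverse_complement(seqs[idx])
            arrays[key] = np.frombuffer(s.encode(), dtype=np.uint8)
        return arrays[key]

    gram_index: dict[str, list[tuple[int, str, int]]] = {}
    prefix_map: dict[str, list[tuple[int, str]]] = {}
    heap: list = []
    counter = 0

    def _oriented(idx: int, orient: str) -> str:
        return seqs[idx] if orient == "+" else reverse_complement(seqs[idx])

    def _push(score, merged_len, ia, oa, ib, ob, o, mm):
        nonlocal counter
        heapq.heappush(heap, (-score, -merged_len, names[ia], names[ib],
                              oa, ob, counter, ia, ib, o, mm))
        counter += 1

    def _try_candidate(ia, oa, pa, ib, ob):
        """a = oriented(ia, oa) provides the suffix at gram position pa;
        b = oriented(ib, ob) provides the prefix."""
        if ia == ib:
            return
        la, lb = len(seqs[ia]), len(seqs[ib])
        o = la - pa
        if o < min_overlap:
            return
        a = _arr(ia, oa)
        b = _arr(ib, ob)
        if o > lb:  # containment: b inside a
            if pa + lb > la:
                return
            mm = _hamming(a[pa:pa + lb], b)
            if mm <= max_mismatch_frac * lb:
                _push(lb - 2 * mm, la, ia, oa, ib, ob, -1, mm)
            return
        mm = _hamming(a[la - o:], b[:o])
        if mm <= max_mismatch_frac * o:
            _push(o - 2 * mm, la + lb - o, ia, oa, ib, ob, o, mm)

    def _add_seq(idx: int) -> None:
        """Index grams of both orientations and discover candidates."""
        s = seqs[idx]
        for orient in "+-":
            so = s if orient == "+" else reverse_complement(s)
            for p in range(0, len(so) - g + 1):
                gram = so[p:p + g]
                gram_index.setdefault(gram, []).append((idx, orient, p))
                # new seq as 'a': existing prefixes matching this gram
                for jb, ob in prefix_map.get(gram, ()):  # noqa: B023
                    if jb in seqs:
                        _try_candidate(idx, orient, p, jb, ob)
            pref = so[:g]
            if len(so) >= g:
                prefix_map.setdefault(pref, []).append((idx, orient))
                # new seq as 'b': existing grams matching its prefix
                for ja, oa, pa in gram_index.get(pref, ()):
                    if ja in seqs:
                        _try_candidate(ja, oa, pa, idx, orient)

    for i, rec in enumerate(records):
        seqs[i] = rec.seq
        covs[i] = np.ones(len(rec.seq), dtype=np.int32)
        names[i] = rec.id
    next_idx = len(records)
    for i in range(len(records)):
        _add_seq(i)

    while heap:
        (_nscore, _nlen, _na, _nb, oa, ob, _c, ia, ib, o, mm) = heapq.heappop(heap)
        if ia not in seqs or ib not in seqs:
            continue
        a = _oriented(ia, oa)
        b = _oriented(ib, ob)
        cov_a = covs[ia] if oa == "+" else covs[ia][::-1]
        cov_b = covs[ib] if ob == "+" else covs[ib][::-1]
        if o < 0:  # containment: add b's votes onto a
            # position of b inside a was la - o at push time; recompute
            res = edlib.align(b, a, mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            p0 = res["locations"][0][0]
            merged_seq = a
            merged_cov = cov_a.copy()
            span = min(len(b), len(a) - p0)
            merged_cov[p0:p0 + span] += cov_b[:span]
        else:
            la = len(a)
            ov_a = np.frombuffer(a[la - o:].encode(), dtype=np.uint8)
            ov_b = np.frombuffer(b[:o].encode(), dtype=np.uint8)
            wa, wb = cov_a[la - o:], cov_b[:o]
            take_b = (ov_a != ov_b) & (
                (wb > wa) | ((wb == wa) & (ov_b < ov_a))
            )
            ov = np.where(take_b, ov_b, ov_a)
            merged_seq = a[:la - o] + ov.tobytes().decode() + b[o:]
            merged_cov = np.concatenate([cov_a[:la - o], wa + wb, cov_b[o:]])
        for dead in (ia, ib):
            del seqs[dead], covs[dead], names[dead]
        arrays.pop((ia, "+"), None)
        arrays.pop((ia, "-"), None)
        arrays.pop((ib, "+"), None)
        arrays.pop((ib, "-"), None)
        seqs[next_idx] = merged_seq
        covs[next_idx] = merged_cov
        names[next_idx] = min(_na, _nb)
        _add_seq(next_idx)
        next_idx += 1

    out = []
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), names[i]))
    for rank, idx in enumerate(order, 1):
        out.append(Contig(f"contig_{rank}", seqs[idx], covs[idx]))
    return out


def detect_circularity(contig: Contig, min_overlap: int = 100,
                       min_identity: float = 0.95) -> Contig:
    """Trim the duplicated terminal overlap of a circular assembly.

    If a suffix of length >= ``min_overlap`` matches the prefix with
    identity >= ``min_identity``, the suffix copy is removed and the contig
    flagged circular; otherwise the contig is returned unchanged. Candidate
    overlap lengths are located with an exact seed from the contig prefix.
    """
    if contig.circular:
        return contig
    L = len(contig.seq)
    if L < 2 * min_overlap:
        return contig
    seed_len = min(21, min_overlap)
    seed = contig.seq[:seed_len]
    pos = contig.seq.find(seed, L // 2)
    while pos != -1:
        o = L - pos
        if o >= min_overlap:
            suffix = contig.seq[pos:]
            prefix = contig.seq[:o]
            res = edlib.align(suffix, prefix, mode="NW", task="distance")
            dist = res["editDistance"]
            if dist >= 0 and 1 - dist / o >= min_identity:
                return Contig(contig.id, contig.seq[:pos],
                              contig.coverage[:pos].copy(), circular=True)
        pos = contig.seq.find(seed, pos + 1)
    return contig
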