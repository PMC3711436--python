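"""Scoring reconstructions and k-mer-spectrum summaries.

``compare_assemblies`` aligns a reconstructed contig to its truth (rotating
and/or reverse-complementing the truth first for circular genomes) and
reports substitutions, indel events and percent identity in the
conventional "subs/indels (identity%)" style, plus the fraction of the
truth length recovered. ``recruitment_metrics`` uses read provenance labels
to quantify target-read recovery and the false-positive (heterospecific)
fraction of a recruited readpool. ``kmer_spectrum_stats`` estimates genome
size and relative organelle copy number from k-mer multiplicity
histograms. ``kimura2p`` is the two-parameter nucleotide distance.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import edlib

from .baiting import iter_kmers
from .mapping import _parse_cigar, _ops_stats
from .seq_io import ReadPool, SeqRecord, reverse_complement
from .assembly import Contig

log = logging.getLogger(__name__)

__all__ = [
    "DiffReport",
    "RecruitmentReport",
    "SpectrumReport",
    "compare_assemblies",
    "recruitment_metrics",
    "kmer_spectrum_stats",
    "copy_ratio",
    "kimura2p",
    "longest_shared_run",
]


@dataclass
class DiffReport:
    substitutions: int
    indels: int  # indel events (one contiguous gap = one event)
    identity_pct: float
    length_pct: float
    circular_confirmed: bool = False
    credible: bool = True

    def __str__(self) -> str:
        s = f"{self.substitutions}/{self.indels} ({self.identity_pct:.2f}%)"
        return s if self.credible else s + " [no credible match]"


@dataclass
class RecruitmentReport:
    reads_pct: float
    fp_pct: float
    n_recruited: int


@dataclass
class SpectrumReport:
    k: int
    histogram: dict[int, int]  # multiplicity -> number of distinct k-mers
    peak_cov: int
    genome_size_est: float
    copy_ratio: float | None = None


def _hw_align(query: str, target: str):
    res = edlib.align(query, target, mode="HW", task="path")
    return res


def compare_assemblies(asm: Contig | SeqRecord, truth: SeqRecord,
                       circular: bool = False) -> DiffReport:
    """Score a reconstruction against the true genome.

    For circular genomes the truth is doubled so every rotation of the
    assembly matches contiguously, and both strands are tried. Substitutions
    and indel events come from the optimal alignment; identity is matching
    columns over alignment columns; length is the aligned truth span over
    the truth length. Identity below 50% flags the report as not credible.
    """
    a = asm.seq
    t = truth.seq
    if not a or not t:
        raise ValueError("empty sequence")
    target = t + t if circular else t
    best = None
    for strand in "+-":
        q = a if strand == "+" else reverse_complement(a)
        if len(q) <= len(target):
            res = _hw_align(q, target)
            flip = False
        else:  # assembly longer than (doubled) truth: align truth into assembly
            res = _hw_align(target, q)
            flip = True
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[0]["editDistance"]:
            best = (res, q, flip)
    if best is None:
        return DiffReport(0, 0, 0.0, 0.0, credible=False)
    res, q, flip = best
    loc = res["locations"][0]
    query, targ = (target, q) if flip else (q, target)
    ops = _parse_cigar(res["cigar"], query, targ, 0, loc[0])
    mism, cols = _ops_stats(ops)
    subs = sum(c for c, op in ops if op == "X")
    indel_events = sum(1 for _, op in ops if op in "ID")
    matches = cols - mism
    identity = 100.0 * matches / cols if cols else 0.0
    # span of the truth consumed by the alignment
    if flip:
        truth_span = sum(c for c, op in ops if op in "=XI")
    else:
        truth_span = loc[1] - loc[0] + 1
    length_pct = 100.0 * min(truth_span, len(t)) / len(t)
    return DiffReport(
        substitutions=subs,
        indels=indel_events,
        identity_pct=identity,
        length_pct=length_pct,
        circular_confirmed=bool(getattr(asm, "circular", False)),
        credible=identity >= 50.0,
    )


def recruitment_metrics(recruited: ReadPool | set[str], provenance: dict[str, str],
                        target_label: str) -> RecruitmentReport:
    """Target-read recovery and false-positive fraction of a recruited pool.

    ``reads_pct`` is the fraction of all target-origin reads present in the
    recruited pool; ``fp_pct`` the fraction of recruited reads whose
    provenance differs from the target.
    """
    rec_ids = (set(r.id for r in recruited.records)
               if isinstance(recruited, ReadPool) else set(recruited))
    missing = rec_ids - set(provenance)
    if missing:
        raise ValueError(f"{len(missing)} recruited read(s) lack provenance")
    target_ids = {i for i, src in provenance.items() if src == target_label}
    if not rec_ids:
        log.warning("empty recruited pool")
        return RecruitmentReport(0.0, 0.0, 0)
    tp = len(rec_ids & target_ids)
    fp = len(rec_ids - target_ids)
    reads_pct = 100.0 * tp / len(target_ids) if target_ids else 0.0
    fp_pct = 100.0 * fp / len(rec_ids)
    return RecruitmentReport(reads_pct, fp_pct, len(rec_ids))


def kmer_spectrum_stats(pool: ReadPool, k: int = 20,
                        noise_cutoff: int = 3) -> SpectrumReport:
    """k-mer multiplicity spectrum, coverage peak and genome-size estimate.

    The histogram counts distinct canonical k-mers per multiplicity; the
    peak is the histogram mode above ``noise_cutoff`` (low-multiplicity
    k-mers are sequencing-error noise); the genome size estimate is the
    total number of above-noise k-mer instances divided by the peak.
    """
    if not pool.records:
        raise ValueError("empty read pool")
    counts: Counter = Counter()
    for rec in pool.records:
        for _, canon, _ in iter_kmers(rec.seq, k):
            counts[canon] += 1
    histogram: Counter = Counter(counts.values())
    above = {m: c for m, c in histogram.items() if m > noise_cutoff}
    if not above:
        raise ValueError("spectrum peak indistinguishable from noise")
    peak_cov = max(above, key=lambda m: (above[m], -m))
    total_instances = sum(m * c for m, c in above.items())
    genome_size = total_instances / peak_cov
    return SpectrumReport(k, dict(histogram), int(peak_cov), genome_size)


def copy_ratio(high: SpectrumReport | float, low: SpectrumReport | float) -> float:
    """Relative copy number from two spectrum peaks (e.g. organelle readpool
    peak over whole-dataset nuclear peak)."""
    a = high.peak_cov if isinstance(high, SpectrumReport) else float(high)
    b = low.peak_cov if isinstance(low, SpectrumReport) else float(low)
    if b <= 0:
        raise ValueError("denominator peak must be positive")
    return a / b


_PURINES = frozenset("AG")


def kimura2p(a: SeqRecord | str, b: SeqRecord | str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) with P the transition and Q the
    transversion fraction over compared columns; gapped or N columns are
    excluded pairwise. Saturated inputs (log argument <= 0) raise.
    """
    sa = a.seq if isinstance(a, SeqRecord) else a
    sb = b.seq if isinstance(b, SeqRecord) else b
    if len(sa) != len(sb):
        raise ValueError("sequences must be aligned to equal length")
    n = ts = tv = 0
    for x, y in zip(sa, sb):
        if x in "-N" or y in "-N":
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable columns")
    P, Q = ts / n, tv / n
    arg1 = 1 - 2 * P - Q
    arg2 = 1 - 2 * Q
    if arg1 <= 0 or arg2 <= 0:
        raise ValueError("distance undefined (saturation)")
    return -0.5 * math.log(arg1 * math.sqrt(arg2))


def longest_shared_run(a: SeqRecord | str, b: SeqRecord | str, k: int = 31) -> int:
    """Length (bp) of the longest identical co-linear run shared by two
    sequences, found by chaining exact shared k-mers on common diagonals.

    Runs shorter than k are not detected (reported as 0); this is used to
    check that simulated genomes share no conserved identical block longer
    than the sequencing insert size.
    """
    sa = a.seq if isinstance(a, SeqRecord) else a
    sb = b.seq if isinstance(b, SeqRecord) else b
    pos_b: dict[int, list[int]] = {}
    for p, _canon, fwd in iter_kmers(sb, k):
        pos_b.setdefault(fwd, []).append(p)
    matches: dict[int, list[int]] = {}  # diagonal -> sorted positions in a
    for p, _canon, fwd in iter_kmers(sa, k):
        for q in pos_b.get(fwd, ()):
            matches.setdefault(p - q, []).append(p)
    best = 0
    for positions in matches.values():
        positions.sort()
        run_start = prev = positions[0]
        for p in positions[1:] + [None]:
            if p is not None and p == prev + 1:
                prev = p
                continue
            best = max(best, prev - run_start + k)
            if p is not None:
                run_start = prev = p
    return best
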