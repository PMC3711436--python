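"""Orchestration of the iterative bait -> map -> consensus loop.

Starting from a seed (a distant reference mitogenome or a short barcode),
each iteration (i) baits the full original read pool against the current
reference by exact canonical k-mers, accumulating recruited reads by
union, and (ii) rebuilds the reference from the recruited reads — by
mapping consensus, by a greedy de-novo assembly of the recruited pool, or
by the paired-end proofreading extension for pooled/mixed samples. The
loop stops when the recruited read count (and the reference) become
stationary, or at ``max_iterations``.

Proofreading mode (single-barcode seed, fully paired pool): a read pair
joins the readpool only if at least one mate matches the current trusted
reference with 100% identity over its full length; the other mate may
reach past the reference end and nominates extension bases. A column is
committed only when all nominated bases agree; where two independently
supported extensions conflict (a conserved block shared with another
species reaching beyond the insert size), extension on that side halts
rather than risk a chimeric consensus.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assembly import Assembly, Contig, build_consensus, detect_circularity, greedy_assemble
from .baiting import BaitParams, PoolKmerLookup, build_kmer_index, bait_reads, canonical_kmers
from .mapping import MappingParams, Placement, anchor_candidates, kmer_pos_map, place_read
from .seq_io import ReadPool, SeqRecord, reverse_complement, unpaired_ids, write_sequences

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "IterationState",
    "RunReport",
    "initial_reference",
    "run_iterations",
    "proofread_extend",
    "write_run_outputs",
]


@dataclass
class RunConfig:
    mode: str = "mapping"  # "mapping" | "denovo"
    quick: bool = False
    proofread: bool = False
    bait: BaitParams = field(default_factory=BaitParams)
    map: MappingParams = field(default_factory=MappingParams)
    max_iterations: int = 200
    convergence_window: int = 1
    seed_rng: int = 0
    initial_strict: bool = False
    min_cov: int = 1
    circ_min_overlap: int = 100
    circ_min_identity: float = 0.95

    def __post_init__(self) -> None:
        if self.mode not in ("mapping", "denovo"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class IterationState:
    iteration: int
    assembly: Assembly
    recruited_ids: set[str] = field(default_factory=set)
    count_history: list[int] = field(default_factory=list)
    trusted_mask: list[np.ndarray] | None = None
    cache: dict = field(default_factory=dict, repr=False, compare=False)


@dataclass
class RunReport:
    iterations_used: int
    converged: bool
    assembly: Assembly
    n_recruited: int
    count_history: list[int]
    length_history: list[int]
    notes: list[str] = field(default_factory=list)
    fp_avoided: int = 0
    halted: bool = False
    seed_rng: int = 0

    @property
    def recruited_ids(self) -> set[str]:
        return self.assembly.recruited_ids


def _ref_kmers(assembly: Assembly, k: int) -> set[int]:
    """Canonical k-mers of the whole reference; circular contigs also
    contribute the k-1 windows spanning the origin."""
    kmers: set[int] = set()
    for c in assembly.contigs:
        seq = c.seq + c.seq[: k - 1] if c.circular and len(c.seq) >= k else c.seq
        kmers |= canonical_kmers(seq, k)
    return kmers


def _bait_ids(pool: ReadPool, assembly: Assembly, config: RunConfig,
              lookup: PoolKmerLookup | None, cache: dict) -> set[str]:
    """Ids recruited by baiting the full pool against the current reference.

    With a ``PoolKmerLookup`` only reference k-mers not queried before are
    looked up (the recruited set is accumulated by union anyway)."""
    kmers = _ref_kmers(assembly, config.bait.k)
    if lookup is None:
        index = build_kmer_index(assembly.records(), config.bait.k)
        sub = bait_reads(pool, index, config.bait)
        return {r.id for r in sub.records}
    ids = cache.setdefault("baited_ids", set())
    queried = cache.setdefault("queried_kmers", set())
    if config.bait.n == 1:
        new = kmers - queried
        if new:
            idxs = lookup.reads_matching(new, n=1)
            ids |= {pool.records[i].id for i in idxs}
            queried |= new
    else:
        idxs = lookup.reads_matching(kmers, n=config.bait.n)
        ids |= {pool.records[i].id for i in idxs}
    if config.bait.pair_rescue or config.mode == "denovo":
        mates = cache.setdefault("mate_map", pool.mate_map())
        ids |= {mates[i] for i in set(ids) if i in mates}
    return set(ids)


def initial_reference(pool: ReadPool, distant_ref: SeqRecord,
                      config: RunConfig | None = None) -> IterationState:
    """Step one: map the pool onto a distant reference and keep only the
    conserved, read-covered parts as the iteration-0 reference.

    With ``config.quick`` the pool is first reduced by baiting against the
    reference before mapping (cheaper, slightly less sensitive). With
    ``config.initial_strict`` the high-stringency mismatch fraction is used
    to avoid spurious conserved-looking placements. Reference bases never
    reach the output consensus: uncovered columns are excised, which may
    split the reference into several contigs.
    """
    config = config or RunConfig()
    base = Assembly([Contig("ref0", distant_ref.seq)])
    working = pool
    if config.quick:
        index = build_kmer_index([distant_ref], config.bait.k)
        working = bait_reads(pool, index, config.bait)
    frac = config.map.strict_frac if config.initial_strict else config.map.max_mismatch_frac
    placements = []
    for rec in working.records:
        res = place_read(rec, base, config.map, max_mismatch_frac=frac)
        if isinstance(res, Placement):
            placements.append(res)
    if not placements:
        raise ValueError(
            "seed too distant: no reads place on the reference "
            "(try quick=False or a conspecific barcode seed)")
    assembly = build_consensus(placements, base, config.min_cov)
    recruited = {p.read_id for p in placements}
    assembly.recruited_ids = set(recruited)
    return IterationState(0, assembly, recruited, [len(recruited)])


def _stationary(counts: list[int], lengths: list[int], window: int) -> bool:
    need = window + 1
    if len(counts) < need:
        return False
    return (len(set(counts[-need:])) == 1 and len(set(lengths[-need:])) == 1)


def run_iterations(pool: ReadPool, seed, config: RunConfig | None = None,
                   pool_lookup: PoolKmerLookup | None = None) -> RunReport:
    """Iterate bait -> rebuild -> circularity check until stationarity.

    ``seed`` is a barcode/genome :class:`SeqRecord` (used directly as the
    iteration-0 reference) or an :class:`IterationState` from
    :func:`initial_reference`. Stationarity = recruited read count and
    total reference length unchanged across ``convergence_window``
    successive iterations.
    """
    config = config or RunConfig()
    if isinstance(seed, IterationState):
        state = seed
    else:
        state = IterationState(0, Assembly([Contig("seed", seed.seq)]))
    if config.proofread:
        return _run_proofread(pool, state, config, pool_lookup)

    cache: dict = {}
    recruited: set[str] = set(state.recruited_ids)
    counts = list(state.count_history)
    lengths = [state.assembly.total_length()] * len(counts)
    assembly = state.assembly
    by_id = pool.by_id()
    it = 0
    converged = False
    for it in range(1, config.max_iterations + 1):
        recruited |= _bait_ids(pool, assembly, config, pool_lookup, cache)
        sub_records = [by_id[i] for i in sorted(recruited)]
        if config.mode == "mapping":
            placements = []
            for rec in sub_records:
                res = place_read(rec, assembly, config.map)
                if isinstance(res, Placement):
                    placements.append(res)
            assembly = build_consensus(placements, assembly, config.min_cov)
        else:
            contigs = greedy_assemble(sub_records, config.map.min_edge_overlap,
                                      config.map.max_mismatch_frac)
            assembly = Assembly(contigs, set(recruited))
        assembly.contigs = [
            detect_circularity(c, config.circ_min_overlap, config.circ_min_identity)
            for c in assembly.contigs
        ]
        assembly.recruited_ids = set(recruited)
        counts.append(len(recruited))
        lengths.append(assembly.total_length())
        if _stationary(counts, lengths, config.convergence_window):
            converged = True
            break
    notes = [] if converged else ["max_iterations reached without stationarity"]
    return RunReport(it, converged, assembly, len(recruited), counts, lengths,
                     notes, seed_rng=config.seed_rng)


# ---------------------------------------------------------------------------
# proofreading mode


class _ProofreadEngine:
    """Iterative perfect-anchor extension for pooled paired-end data."""

    def __init__(self, pool: ReadPool, seed_seq: str, config: RunConfig,
                 lookup: PoolKmerLookup | None = None):
        if not pool.pairing:
            raise ValueError("proofreading requires a paired read pool")
        loose = unpaired_ids(pool)
        if loose:
            raise ValueError(
                f"proofreading requires a fully paired pool ({len(loose)} unpaired reads)")
        self.config = config
        self.records = pool.records
        self.id_of = [r.id for r in self.records]
        idx_of = {r.id: i for i, r in enumerate(self.records)}
        self.pairs: list[tuple[int, int]] = []
        self.pair_of: dict[int, int] = {}
        for pid in sorted(pool.pairing):
            f, r = pool.pairing[pid]
            p = len(self.pairs)
            self.pairs.append((idx_of[f], idx_of[r]))
            self.pair_of[idx_of[f]] = p
            self.pair_of[idx_of[r]] = p
        self.k = config.bait.k
        self.min_edge = config.map.min_edge_overlap
        self.lookup = lookup if lookup is not None else PoolKmerLookup(
            self.records, self.k)
        self.ref = seed_seq
        self.circular = False
        self.queried: set[int] = set()
        self.candidates: set[int] = set()
        self.incorporated: set[int] = set()
        self.rejected: set[int] = set()
        self.pending: set[int] = set()   # mates of incorporated pairs, not yet placeable
        self.edge_reads: set[int] = set()
        self.fp_avoided = 0
        self.conflict_events = 0
        self.halted_left = False
        self.halted_right = False
        self._rc_cache: dict[int, str] = {}

    # -- placement -----------------------------------------------------

    def _oriented(self, ridx: int, strand: str) -> str:
        if strand == "+":
            return self.records[ridx].seq
        got = self._rc_cache.get(ridx)
        if got is None:
            got = reverse_complement(self.records[ridx].seq)
            self._rc_cache[ridx] = got
        return got

    def _place(self, ridx: int, kmap) -> tuple[str, int, str, str]:
        """Classify one read against the trusted reference.

        Returns (kind, start, strand, oriented) with kind in:
        'interior' — 100% identity over the full read, inside the reference
        (anchor quality); 'edge' — 100% identity over a >=min_edge overlap
        with an overhang past an end (extension candidate); 'imperfect' —
        overlaps but mismatches somewhere (never trusted); 'none' — no
        exact k-mer anchor or unusable overlap.
        """
        seq = self.records[ridx].seq
        m = len(seq)
        L = len(self.ref)
        cands = anchor_candidates(seq, kmap, self.k)
        if not cands:
            return ("none", 0, "+", "")
        search = self.ref + self.ref if self.circular else self.ref
        saw_mismatch = False
        edge_hit = None
        for start, strand in cands:
            oriented = self._oriented(ridx, strand)
            if self.circular:
                s = start % L
                if s + m <= len(search) and oriented == search[s:s + m]:
                    return ("interior", s, strand, oriented)
                saw_mismatch = True
                continue
            ref_start = max(0, start)
            ref_end = min(L, start + m)
            ov = ref_end - ref_start
            if ov < 1:
                continue
            if oriented[ref_start - start: ref_end - start] == self.ref[ref_start:ref_end]:
                if start >= 0 and start + m <= L:
                    return ("interior", start, strand, oriented)
                if ov >= self.min_edge and edge_hit is None:
                    edge_hit = ("edge", start, strand, oriented)
            else:
                saw_mismatch = True
        if edge_hit is not None:
            return edge_hit
        return ("imperfect" if saw_mismatch else "none", 0, "+", "")

    # -- one iteration --------------------------------------------------

    def step(self) -> None:
        L = len(self.ref)
        kmap_src = self.ref + self.ref if self.circular else self.ref
        kmap = kmer_pos_map(kmap_src, self.k)

        bait_src = self.ref + self.ref[: self.k - 1] if self.circular else self.ref
        new_kmers = canonical_kmers(bait_src, self.k) - self.queried
        if new_kmers:
            for i in self.lookup.reads_matching(new_kmers):
                p = self.pair_of[i]
                if p not in self.incorporated and p not in self.rejected:
                    self.candidates.add(p)
            self.queried |= new_kmers

        # incorporate pairs with a perfect interior anchor
        for p in list(self.candidates):
            i, j = self.pairs[p]
            ri = self._place(i, kmap)
            rj = self._place(j, kmap)
            if ri[0] != "interior" and rj[0] != "interior":
                continue  # stays a candidate; the reference may grow to it
            anchor_i, other_i = (i, j) if ri[0] == "interior" else (j, i)
            other = rj if anchor_i == i else ri
            self.candidates.discard(p)
            if other[0] == "imperfect":
                # perfectly anchored but the mate conflicts with the trusted
                # consensus: a heterospecific pair straddling a conserved
                # block — excluded (an avoided false positive)
                self.rejected.add(p)
                self.fp_avoided += 1
                continue
            self.incorporated.add(p)
            if other[0] == "edge":
                self.edge_reads.add(other_i)
            elif other[0] == "none":
                self.pending.add(other_i)

        # collect unanimous extension evidence from perfectly anchored mates
        left_c: dict[int, Counter] = {}
        right_c: dict[int, Counter] = {}
        for ridx in list(self.edge_reads | self.pending):
            kind, start, _strand, oriented = self._place(ridx, kmap)
            if kind == "interior":
                self.edge_reads.discard(ridx)
                self.pending.discard(ridx)
                continue
            if kind == "edge":
                self.pending.discard(ridx)
                self.edge_reads.add(ridx)
                m = len(oriented)
                if start < 0:
                    for d in range(1, -start + 1):
                        left_c.setdefault(d, Counter())[oriented[-start - d]] += 1
                if start + m > L:
                    over = start + m - L
                    for d in range(1, over + 1):
                        right_c.setdefault(d, Counter())[oriented[m - over + d - 1]] += 1
            elif kind == "imperfect" and ridx in self.pending:
                self.pending.discard(ridx)
                self.conflict_events += 1

        if not self.circular:
            if not self.halted_right:
                ext, halt = self._commit(right_c)
                self.ref = self.ref + ext
                self.halted_right |= halt
            if not self.halted_left:
                ext, halt = self._commit(left_c)
                self.ref = ext[::-1] + self.ref
                self.halted_left |= halt
            if len(self.ref) >= 2 * self.config.circ_min_overlap:
                c = detect_circularity(Contig("ref", self.ref),
                                       self.config.circ_min_overlap,
                                       self.config.circ_min_identity)
                if c.circular:
                    self.ref = c.seq
                    self.circular = True
                    self.edge_reads.clear()

    @staticmethod
    def _commit(cands: dict[int, Counter]) -> tuple[str, bool]:
        """Commit outward columns while the evidence is unanimous.

        Two conflicting variants each supported by >=2 reads signal a
        genuine bifurcation (reads of another species extending a shared
        block): extension on this side halts permanently."""
        out: list[str] = []
        for d in range(1, len(cands) + 1):
            c = cands.get(d)
            if not c:
                break
            if len(c) == 1:
                out.append(next(iter(c)))
            else:
                top = c.most_common(2)
                return "".join(out), top[0][1] >= 2 and top[1][1] >= 2
        return "".join(out), False

    # -- reporting -------------------------------------------------------

    def recruited_read_ids(self) -> set[str]:
        ids: set[str] = set()
        for p in self.incorporated:
            i, j = self.pairs[p]
            ids.add(self.id_of[i])
            ids.add(self.id_of[j])
        return ids

    def assembly(self) -> Assembly:
        contig = Contig("mt_proofread", self.ref, circular=self.circular)
        return Assembly([contig], self.recruited_read_ids())


def proofread_extend(state: IterationState, pool: ReadPool,
                     config: RunConfig) -> IterationState:
    """One proofreading iteration (bait, perfect-anchor incorporation,
    unanimous extension, circularity check) on ``state``.

    The state must hold a single-contig reference seeded from one barcode
    and the pool must be fully paired."""
    engine: _ProofreadEngine | None = state.cache.get("proofread_engine")
    if engine is None:
        if len(state.assembly.contigs) != 1:
            raise ValueError("proofreading requires a single-contig reference")
        engine = _ProofreadEngine(pool, state.assembly.contigs[0].seq, config,
                                  state.cache.get("pool_lookup"))
        state.cache["proofread_engine"] = engine
    engine.step()
    asm = engine.assembly()
    return IterationState(
        state.iteration + 1,
        asm,
        engine.recruited_read_ids(),
        state.count_history + [2 * len(engine.incorporated)],
        trusted_mask=[np.ones(len(c.seq), dtype=bool) for c in asm.contigs],
        cache=state.cache,
    )


def _run_proofread(pool: ReadPool, state: IterationState, config: RunConfig,
                   lookup: PoolKmerLookup | None) -> RunReport:
    if len(state.assembly.contigs) != 1:
        raise ValueError("proofreading requires a single seed sequence")
    if lookup is not None:
        state.cache["pool_lookup"] = lookup
    counts: list[int] = []
    lengths: list[int] = []
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        state = proofread_extend(state, pool, config)
        counts.append(state.count_history[-1])
        lengths.append(state.assembly.total_length())
        if _stationary(counts, lengths, config.convergence_window):
            converged = True
            break
    engine: _ProofreadEngine = state.cache["proofread_engine"]
    notes = []
    if engine.halted_left or engine.halted_right:
        notes.append("extension halted at a conflicting conserved block")
    if engine.circular:
        notes.append("circularity detected and trimmed")
    if not converged:
        notes.append("max_iterations reached without stationarity")
    return RunReport(it, converged, engine.assembly(), counts[-1] if counts else 0,
                     counts, lengths, notes, fp_avoided=engine.fp_avoided,
                     halted=engine.halted_left or engine.halted_right,
                     seed_rng=config.seed_rng)


def write_run_outputs(report: RunReport, pool: ReadPool, outdir) -> None:
    """Write final contigs (FASTA), recruited reads (FASTQ), per-iteration
    TSV and a key=value run summary under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    descs = {
        c.id: f"circular={'true' if c.circular else 'false'} "
              f"mean_cov={float(np.mean(c.coverage)) if len(c.coverage) else 0:.1f}"
        for c in report.assembly.contigs
    }
    write_sequences(report.assembly.records(), outdir / "final.fasta",
                    "fasta", descriptions=descs)
    by_id = pool.by_id()
    recruited = [by_id[i] for i in sorted(report.recruited_ids) if i in by_id]
    write_sequences(recruited, outdir / "recruited.fastq", "fastq")
    with open(outdir / "iterations.tsv", "w") as fh:
        fh.write("iteration\trecruited\ttotal_length\n")
        for i, (c, l) in enumerate(zip(report.count_history, report.length_history), 1):
            fh.write(f"{i}\t{c}\t{l}\n")
    with open(outdir / "report.txt", "w") as fh:
        fh.write(f"iterations_used={report.iterations_used}\n")
        fh.write(f"converged={str(report.converged).lower()}\n")
        fh.write(f"n_recruited={report.n_recruited}\n")
        fh.write(f"n_contigs={len(report.assembly.contigs)}\n")
        fh.write(f"total_length={report.assembly.total_length()}\n")
        fh.write(f"seed_rng={report.seed_rng}\n")
        for note in report.notes:
            fh.write(f"note={note}\n")
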