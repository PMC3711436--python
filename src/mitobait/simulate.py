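"""Synthetic circular mitogenomes and paired-end shotgun reads.

The generator emulates the pooled-sample benchmark the assembler is
designed for: several related circular genomes of ~16.6 kb derived from a
common ancestor at a controlled Kimura-2-parameter divergence, each
sequenced as error-free 150 bp paired-end reads with insert 300 +/- 50 bp
to ~50x (6000 reads per genome), then pooled with per-read provenance
labels. Optionally an AT-rich composition and a 750-800 bp non-coding
tandem repeat can be included to emulate repeat-bearing flatworm-like
mitogenomes.

Everything is reproducible from the supplied integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .seq_io import ReadPool, SeqRecord, reverse_complement

__all__ = [
    "GenomeSpec",
    "SimConfig",
    "simulate_ancestor",
    "evolve_genome",
    "simulate_reads",
    "pool_readsets",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeSpec:
    """Composition of one synthetic circular genome."""

    length: int = 16600
    at_content: float = 0.55
    repeat_unit: int | None = None  # e.g. 780 (bp), the non-coding repeat unit
    repeat_copies: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError("genome length must be >= 1000")
        if not 0 < self.at_content < 1:
            raise ValueError("at_content must be in (0,1)")
        if self.repeat_unit is not None:
            if self.repeat_unit < 1 or self.repeat_copies < 2:
                raise ValueError("repeat needs unit_length >= 1 and copies >= 2")
            if self.repeat_unit * self.repeat_copies >= self.length:
                raise ValueError("repeat total length must be < genome length")


@dataclass
class SimConfig:
    """Paired-end read simulation parameters (defaults: the pooled benchmark)."""

    read_length: int = 150
    insert_mean: int = 300
    insert_sd: int = 50
    n_reads: int = 6000
    error_rate: float = 0.0
    linear: bool = False  # sample fragments from a linear (uncircularised) template
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be >= read_length")
        if self.n_reads % 2:
            raise ValueError("n_reads must be even (two reads per fragment)")


def _random_bases(rng: np.random.Generator, n: int, at: float) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


def simulate_ancestor(spec: GenomeSpec) -> SeqRecord:
    """One circular genome: i.i.d. bases with P(A)=P(T)=at_content/2, plus an
    optional tandem repeat of a single random unit at a random position.

    The repeat is inserted into a correspondingly shorter backbone so the
    total length equals ``spec.length`` exactly.
    """
    rng = np.random.default_rng(spec.rng_seed)
    rep_total = (spec.repeat_unit * spec.repeat_copies) if spec.repeat_unit else 0
    backbone = _random_bases(rng, spec.length - rep_total, spec.at_content)
    if rep_total:
        unit = _random_bases(rng, spec.repeat_unit, spec.at_content)
        pos = int(rng.integers(0, len(backbone) + 1))
        backbone = backbone[:pos] + unit * spec.repeat_copies + backbone[pos:]
    return SeqRecord(f"ancestor_{spec.rng_seed}", backbone)


def _substitution_prob(divergence: float) -> float:
    """Per-site substitution probability giving the requested expected K2P
    distance under equal-weight substitution to the three other bases.

    With uniform substitution the expected transition fraction is p/3 and
    transversion fraction 2p/3, so the K2P distance reduces to
    -(3/4) ln(1 - 4p/3); this is inverted for p.
    """
    if divergence == 0:
        return 0.0
    if not 0 <= divergence <= 0.75:
        raise ValueError("divergence must be in [0, 0.75]")
    return float(brentq(lambda p: -0.75 * np.log1p(-4 * p / 3) - divergence,
                        0.0, 0.7499))


def evolve_genome(ancestor: SeqRecord, divergence: float, rng_seed: int,
                  new_id: str | None = None) -> SeqRecord:
    """Substitute sites i.i.d. so the expected K2P distance to the ancestor
    is ~``divergence`` (length-preserving, transitions and transversions
    equally weighted)."""
    p = _substitution_prob(divergence)
    rng = np.random.default_rng(rng_seed)
    arr = np.frombuffer(ancestor.seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < p
    idx = np.nonzero(hit)[0]
    if idx.size:
        # replace by one of the three other bases, uniformly
        codes = np.zeros(arr.size, dtype=np.int8)
        for b, c in zip(b"ACGT", range(4)):
            codes[arr == b] = c
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(codes[idx] + shift) % 4]
    return SeqRecord(new_id or f"{ancestor.id}_d{divergence}_{rng_seed}",
                     arr.tobytes().decode())


def simulate_reads(genome: SeqRecord, config: SimConfig) -> ReadPool:
    """Error-free-by-default paired reads from a circular genome.

    Fragment starts are uniform on the circle (reads may span the origin)
    unless ``config.linear``, which reproduces the end-coverage deficit of
    simulating from a linearised template. Insert lengths are
    normal(mean, sd) truncated to >= read_length. The forward mate is the
    fragment's + strand 5' end; the reverse mate is the reverse complement
    of its 3' end. Substitution errors are applied at ``error_rate``.
    Provenance of every read is the genome id.
    """
    L = len(genome.seq)
    rl = config.read_length
    if not config.linear and L <= config.insert_mean + 4 * config.insert_sd:
        raise ValueError("genome too short for the insert distribution")
    rng = np.random.default_rng(config.rng_seed)
    n_pairs = config.n_reads // 2
    inserts = np.rint(rng.normal(config.insert_mean, config.insert_sd,
                                 size=n_pairs)).astype(int)
    for _ in range(100):  # truncate by resampling
        bad = inserts < rl
        if not bad.any():
            break
        inserts[bad] = np.rint(rng.normal(config.insert_mean, config.insert_sd,
                                          size=int(bad.sum()))).astype(int)
    inserts = np.clip(inserts, rl, L)
    if config.linear:
        starts = np.array([int(rng.integers(0, max(1, L - ins + 1)))
                           for ins in inserts])
        template = genome.seq
    else:
        starts = rng.integers(0, L, size=n_pairs)
        template = genome.seq + genome.seq  # fragments may span the origin

    records: list[SeqRecord] = []
    pairing: dict[str, tuple[str, str]] = {}
    provenance: dict[str, str] = {}
    for i, (s, ins) in enumerate(zip(starts, inserts)):
        frag = template[s:s + ins]
        fwd_seq = frag[:rl]
        rev_seq = reverse_complement(frag[-rl:])
        if config.error_rate > 0:
            fwd_seq = _add_errors(fwd_seq, config.error_rate, rng)
            rev_seq = _add_errors(rev_seq, config.error_rate, rng)
        pid = f"{genome.id}_p{i}"
        f = SeqRecord(f"{pid}/1", fwd_seq)
        r = SeqRecord(f"{pid}/2", rev_seq)
        records += [f, r]
        pairing[pid] = (f.id, r.id)
        provenance[f.id] = genome.id
        provenance[r.id] = genome.id
    return ReadPool(records, pairing, provenance)


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.nonzero(rng.random(arr.size) < rate)[0]
    if idx.size:
        codes = np.zeros(arr.size, dtype=np.int8)
        for b, c in zip(b"ACGT", range(4)):
            codes[arr == b] = c
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(codes[idx] + shift) % 4]
    return arr.tobytes().decode()


def pool_readsets(pools: Sequence[ReadPool]) -> ReadPool:
    """Concatenate read pools, preserving pairing and provenance.

    Read ids must be unique across pools (the simulator prefixes ids with
    the genome id, which guarantees this for distinct genomes)."""
    records: list[SeqRecord] = []
    pairing: dict[str, tuple[str, str]] = {}
    provenance: dict[str, str] = {}
    seen: set[str] = set()
    for pool in pools:
        for rec in pool.records:
            if rec.id in seen:
                raise ValueError(f"read id collision while pooling: {rec.id}")
            seen.add(rec.id)
            records.append(rec)
        for pid, pr in (pool.pairing or {}).items():
            if pid in pairing:
                raise ValueError(f"pair id collision while pooling: {pid}")
            pairing[pid] = pr
        provenance.update(pool.provenance or {})
    return ReadPool(records, pairing, provenance)
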