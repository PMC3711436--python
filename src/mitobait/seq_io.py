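"""Sequence input/output and paired-end read handling.

All downstream modules operate on :class:`SeqRecord` and :class:`ReadPool`.
FASTA/FASTQ parsing and writing is delegated to Biopython; this module adds
the alphabet normalisation the assembler needs (uppercase, ``U`` -> ``T``,
IUPAC ambiguity codes other than ``N`` collapsed to ``N``) and the pairing
conventions for paired-end libraries (``/1``-``/2`` id suffixes or
interleaved order).

Coordinates are 0-based half-open everywhere inside the package; only
human-facing reports use 1-based inclusive positions.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger(__name__)

__all__ = [
    "SeqRecord",
    "ReadPair",
    "ReadPool",
    "ParseError",
    "parse_sequences",
    "write_sequences",
    "pair_reads",
    "reverse_complement",
]


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ input."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_CHARS = frozenset("ACGTN")
# IUPAC ambiguity codes other than N; collapsed to N so that k-mer hashing
# and identity rules operate over an unambiguous 4+N alphabet.
_AMBIGUOUS = frozenset("RYSWKMBDHV")


@dataclass
class SeqRecord:
    """One named nucleotide sequence with optional per-base qualities."""

    id: str
    seq: str
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id {self.id!r} is empty or contains whitespace")
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, new_id: str | None = None) -> "SeqRecord":
        qual = None if self.qual is None else self.qual[::-1]
        return SeqRecord(new_id or self.id, reverse_complement(self.seq), qual)


@dataclass
class ReadPair:
    """A forward/reverse mate pair sharing one pair id."""

    fwd: SeqRecord
    rev: SeqRecord
    pair_id: str

    def __post_init__(self) -> None:
        if self.fwd.id == self.rev.id:
            raise ValueError(f"pair {self.pair_id}: mates share id {self.fwd.id}")


@dataclass
class ReadPool:
    """A set of reads with optional pairing and provenance annotation.

    ``pairing`` maps pair_id -> (fwd id, rev id); ``provenance`` maps read id
    -> source label (populated by the simulator for pooled read sets).
    """

    records: list[SeqRecord] = field(default_factory=list)
    pairing: dict[str, tuple[str, str]] | None = None
    provenance: dict[str, str] | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate read id {dup!r} in pool")
        if self.pairing:
            known = set(ids)
            for pid, (f, r) in self.pairing.items():
                if f not in known or r not in known:
                    raise ValueError(f"pairing entry {pid} references unknown reads")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.records)

    def by_id(self) -> dict[str, SeqRecord]:
        return {r.id: r for r in self.records}

    def mate_map(self) -> dict[str, str]:
        """Map every paired read id to its mate's id."""
        mates: dict[str, str] = {}
        for f, r in (self.pairing or {}).values():
            mates[f] = r
            mates[r] = f
        return mates

    def subset(self, ids: Iterable[str]) -> "ReadPool":
        """Restrict to ``ids``, keeping pairing entries with both mates present."""
        keep = set(ids)
        records = [r for r in self.records if r.id in keep]
        pairing = None
        if self.pairing is not None:
            pairing = {
                pid: (f, r)
                for pid, (f, r) in self.pairing.items()
                if f in keep and r in keep
            }
        provenance = None
        if self.provenance is not None:
            provenance = {i: s for i, s in self.provenance.items() if i in keep}
        return ReadPool(records, pairing, provenance)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N is self-complementary)."""
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(f"non-DNA character(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def _clean_seq(raw: str, rec_id: str, approx_line: int | None = None) -> str:
    seq = raw.upper().replace("U", "T")
    if set(seq) <= _VALID_CHARS:
        return seq
    out = []
    n_ambig = 0
    for c in seq:
        if c in _VALID_CHARS:
            out.append(c)
        elif c in _AMBIGUOUS:
            out.append("N")
            n_ambig += 1
        else:
            where = f" (near line {approx_line})" if approx_line else ""
            raise ParseError(f"record {rec_id}{where}: invalid character {c!r}")
    log.warning(
        "record %s: %d IUPAC ambiguity code(s) replaced by N", rec_id, n_ambig
    )
    return "".join(out)


def _open_source(source, fmt: str):
    """Resolve a path (possibly gzipped) or literal record text to a handle."""
    if hasattr(source, "read"):
        return source
    text = str(source)
    if os.path.exists(text):
        if text.endswith(".gz"):
            return gzip.open(text, "rt")
        return open(text)
    lead = text.lstrip()[:1]
    if (fmt == "fasta" and lead == ">") or (fmt == "fastq" and lead == "@"):
        return StringIO(text)
    raise FileNotFoundError(f"no such file: {text}")


def parse_sequences(source, format: str = "fasta") -> list[SeqRecord]:
    """Parse FASTA or FASTQ (Sanger quality) into a list of :class:`SeqRecord`.

    ``source`` may be a path (gzip accepted), an open handle, or the literal
    record text. Sequences are uppercased, U mapped to T and IUPAC ambiguity
    codes other than N replaced by N with a logged warning. An empty file
    yields an empty list.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    handle = _open_source(source, format)
    records: list[SeqRecord] = []
    lines_per_rec = 4 if format == "fastq" else None
    it = _BioSeqIO.parse(handle, format)
    idx = 0
    while True:
        approx_line = idx * lines_per_rec + 1 if lines_per_rec else None
        try:
            rec = next(it)
        except StopIteration:
            break
        except ValueError as exc:
            where = f" near line {approx_line}" if approx_line else ""
            raise ParseError(f"malformed {format} record #{idx + 1}{where}: {exc}") from exc
        qual = rec.letter_annotations.get("phred_quality")
        records.append(
            SeqRecord(
                rec.id,
                _clean_seq(str(rec.seq), rec.id, approx_line),
                list(qual) if qual is not None else None,
            )
        )
        idx += 1
    return records


def write_sequences(records: Iterable[SeqRecord], path, format: str = "fasta",
                    descriptions: dict[str, str] | None = None) -> None:
    """Write records as FASTA/FASTQ; ``.gz`` suffix triggers gzip output.

    FASTQ output substitutes a constant placeholder quality (40) for records
    without qualities.
    """
    path = Path(path)
    bio_records = []
    for r in records:
        br = _BioSeqRecord(_BioSeq(r.seq), id=r.id, description="")
        if descriptions and r.id in descriptions:
            br.description = descriptions[r.id]
        if format == "fastq":
            br.letter_annotations["phred_quality"] = (
                r.qual if r.qual is not None else [40] * len(r.seq)
            )
        bio_records.append(br)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        _BioSeqIO.write(bio_records, fh, format)


def _strip_pair_suffix(read_id: str) -> tuple[str, int | None]:
    if len(read_id) > 2 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2], int(read_id[-1])
    return read_id, None


def pair_reads(pool: ReadPool, convention: str = "suffix_slash12") -> ReadPool:
    """Populate the pairing map of ``pool`` under a naming convention.

    ``suffix_slash12``: ids ``X/1`` and ``X/2`` pair as ``X``; a mate-less
    read is left unpaired with a logged warning. ``interleaved``: consecutive
    records pair in file order (fwd, rev).
    """
    pairing: dict[str, tuple[str, str]] = {}
    if convention == "suffix_slash12":
        halves: dict[str, dict[int, str]] = {}
        for rec in pool.records:
            base, mate = _strip_pair_suffix(rec.id)
            if mate is not None:
                halves.setdefault(base, {})[mate] = rec.id
        for base, d in halves.items():
            if 1 in d and 2 in d:
                pairing[base] = (d[1], d[2])
            else:
                log.warning("read %s lacks its mate; left unpaired", next(iter(d.values())))
    elif convention == "interleaved":
        if len(pool.records) % 2:
            log.warning("odd record count in interleaved pool; last read unpaired")
        for i in range(0, len(pool.records) - 1, 2):
            fwd, rev = pool.records[i], pool.records[i + 1]
            pid, _ = _strip_pair_suffix(fwd.id)
            if pid in pairing:
                pid = f"{pid}.{i // 2}"
            pairing[pid] = (fwd.id, rev.id)
    else:
        raise ValueError(f"unknown pairing convention {convention!r}")
    return ReadPool(pool.records, pairing, pool.provenance)


def unpaired_ids(pool: ReadPool) -> list[str]:
    """Ids of reads not covered by the pool's pairing map."""
    paired = {i for pr in (pool.pairing or {}).values() for i in pr}
    return [r.id for r in pool.records if r.id not in paired]
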