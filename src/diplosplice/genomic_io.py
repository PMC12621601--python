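"""Genome and annotation I/O plus the internal coordinate model.

All coordinates inside the package are 0-based half-open intervals on the
forward genomic strand; biological windows are only computed after orienting
to transcript direction. Two annotation dialects are supported: GTF
(1-based inclusive, feature type ``intron``) and BED6 (0-based half-open).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping

from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "IntronRecord",
    "DIALECTS",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_introns",
    "write_introns",
    "intron_sequence",
]

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Supported annotation dialects and their coordinate conventions.
DIALECTS = ("GTF", "BED")

FORWARD = "+"
REVERSE = "-"
UNDETERMINED = "."
STRANDS = (FORWARD, REVERSE, UNDETERMINED)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A genome as a mapping of contig id to upper-case DNA string."""

    contigs: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def contig_ids(self) -> List[str]:
        return list(self.contigs)


@dataclass(frozen=True, order=True)
class IntronRecord:
    """One intron feature on the forward genomic strand.

    ``start``/``end`` are 0-based half-open; ``strand`` is ``+``, ``-`` or
    ``.`` (undetermined); ``support`` is the split-read count backing the
    junction.
    """

    contig: str
    start: int
    end: int
    strand: str = FORWARD
    support: int = 0
    species: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"degenerate interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.support < 0:
            raise ValueError(f"negative support {self.support}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def with_strand(self, strand: str) -> "IntronRecord":
        return replace(self, strand=strand)


def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Load a multi-record FASTA into a :class:`GenomeSequence`.

    Sequences are upper-cased; duplicate ids, empty sequences and
    characters outside ``{A,C,G,T,N}`` are rejected.
    """
    contigs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_gtf_line(line: str, lineno: int, species: str) -> IntronRecord | None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 8:
        raise ValueError(f"line {lineno}: expected >=8 GTF columns, got {len(fields)}")
    contig, _source, feature, start, end, score, strand = fields[:7]
    if feature != "intron":
        return None
    start0 = int(start) - 1  # GTF is 1-based inclusive
    end0 = int(end)
    if end0 <= start0:
        raise ValueError(f"line {lineno}: degenerate interval {start}..{end}")
    support = 0 if score in (".", "") else int(float(score))
    return IntronRecord(contig, start0, end0, strand if strand in STRANDS else UNDETERMINED,
                        support, species)


def _parse_bed_line(line: str, lineno: int, species: str) -> IntronRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"line {lineno}: expected >=3 BED columns")
    contig, start, end = fields[:3]
    score = fields[4] if len(fields) > 4 else "0"
    strand = fields[5] if len(fields) > 5 else UNDETERMINED
    start0, end0 = int(start), int(end)
    if end0 <= start0:
        raise ValueError(f"line {lineno}: degenerate interval {start}..{end}")
    support = 0 if score in (".", "") else int(float(score))
    return IntronRecord(contig, start0, end0, strand if strand in STRANDS else UNDETERMINED,
                        support, species)


def read_introns(path: str | os.PathLike, dialect: str, species: str = "") -> List[IntronRecord]:
    """Read intron features under the declared coordinate ``dialect``.

    GTF start/end (1-based inclusive) are converted to the internal 0-based
    half-open convention; BED passes through. Strand ``.`` is kept as
    undetermined.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    records: List[IntronRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if dialect == "GTF":
                rec = _parse_gtf_line(line, lineno, species)
                if rec is None:
                    continue
            else:
                rec = _parse_bed_line(line, lineno, species)
            records.append(rec)
    return records


def write_introns(records: Iterable[IntronRecord], path: str | os.PathLike,
                  dialect: str) -> None:
    """Write intron records; read->write->read round-trips coordinates exactly."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            if dialect == "GTF":
                fh.write(
                    f"{rec.contig}\tdiplosplice\tintron\t{rec.start + 1}\t{rec.end}"
                    f"\t{rec.support}\t{rec.strand}\t.\t"
                    f'transcript_id "i{i}";\n'
                )
            else:
                fh.write(
                    f"{rec.contig}\t{rec.start}\t{rec.end}\ti{i}\t{rec.support}"
                    f"\t{rec.strand}\n"
                )


def intron_sequence(record: IntronRecord, genome: GenomeSequence) -> str:
    """Intron sequence in transcript orientation.

    Minus-strand introns are reverse complemented; undetermined strand is an
    error because no transcript orientation exists.
    """
    if record.strand == UNDETERMINED:
        raise ValueError("cannot orient an intron with undetermined strand")
    if record.contig not in genome:
        raise KeyError(f"unknown contig {record.contig!r}")
    if record.end > genome.length(record.contig):
        raise ValueError(
            f"interval [{record.start}, {record.end}) exceeds contig "
            f"{record.contig!r} length {genome.length(record.contig)}"
        )
    seq = genome[record.contig][record.start : record.end]
    return seq if record.strand == FORWARD else reverse_complement(seq)
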