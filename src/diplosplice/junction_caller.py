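"""Split-read junction calling from spliced SAM alignments.

Each ``N`` operation in an alignment CIGAR marks a skipped reference
interval — a candidate intron. Junctions are counted across reads, strand
is resolved from alignment strand tags (``XS``) or from the terminal
splice-site motif, and junctions are filtered on split-read support,
strand and length before overlapping calls are collapsed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import pysam

from .genomic_io import (
    FORWARD,
    REVERSE,
    UNDETERMINED,
    GenomeSequence,
    IntronRecord,
)

__all__ = [
    "JunctionFilterConfig",
    "Junction",
    "extract_junctions",
    "assign_strand",
    "filter_junctions",
    "resolve_overlaps",
    "call_introns",
]

logger = logging.getLogger(__name__)

# CIGAR operator codes (SAM spec): which consume reference positions.
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X
_SKIP = 3  # N


@dataclass(frozen=True)
class JunctionFilterConfig:
    """Support/length/strand gates applied to candidate junctions.

    ``min_support`` keeps junctions backed by at least that many split
    reads; ``min_intron``/``max_intron`` bound the skipped interval length
    at extraction time; ``require_strand`` drops junctions whose strand
    cannot be determined.
    """

    min_support: int = 15
    min_intron: int = 12
    max_intron: int = 10_000
    require_strand: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_intron < self.max_intron):
            raise ValueError(
                f"need 0 < min_intron < max_intron, got "
                f"({self.min_intron}, {self.max_intron})"
            )
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass
class Junction:
    """A skipped reference interval with its split-read evidence."""

    contig: str
    start: int
    end: int
    support: int = 0
    strand: str = UNDETERMINED
    strand_evidence: str = "ambiguous"  # tag | forward-motif | reverse-motif | ambiguous
    tag_counts: Counter = field(default_factory=Counter)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> Tuple[str, int, int]:
        return (self.contig, self.start, self.end)


def _iter_alignments(alignments) -> Iterable[pysam.AlignedSegment]:
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        with pysam.AlignmentFile(str(alignments), "r") as sam:
            yield from sam
    else:
        yield from alignments


def extract_junctions(
    alignments, config: JunctionFilterConfig | None = None
) -> Tuple[Dict[Tuple[str, int, int], Junction], Dict[str, int]]:
    """Count skipped intervals across spliced alignments.

    ``alignments`` is a SAM path or an iterable of ``pysam.AlignedSegment``.
    Every N operation yields one junction; support is the number of reads
    skipping exactly that interval. Intervals with length outside
    ``[min_intron, max_intron]`` are not emitted. Returns the junction map
    and a stats tally (reads seen / unmapped / malformed / N ops gated).

    The result is independent of input record order.
    """
    config = config or JunctionFilterConfig()
    junctions: Dict[Tuple[str, int, int], Junction] = {}
    stats = {"reads": 0, "unmapped": 0, "malformed": 0,
             "n_ops": 0, "n_ops_length_gated": 0}

    for aln in _iter_alignments(alignments):
        stats["reads"] += 1
        if aln.is_unmapped or aln.reference_name is None:
            stats["unmapped"] += 1
            continue
        cigar = aln.cigartuples
        if not cigar:
            stats["malformed"] += 1
            logger.warning("read %s: missing/malformed CIGAR, skipped", aln.query_name)
            continue
        try:
            tag = aln.get_tag("XS")
        except KeyError:
            tag = None
        pos = aln.reference_start  # 0-based
        for op, length in cigar:
            if op == _SKIP:
                stats["n_ops"] += 1
                if config.min_intron <= length <= config.max_intron:
                    key = (aln.reference_name, pos, pos + length)
                    junc = junctions.get(key)
                    if junc is None:
                        junc = Junction(*key)
                        junctions[key] = junc
                    junc.support += 1
                    if tag in (FORWARD, REVERSE):
                        junc.tag_counts[tag] += 1
                else:
                    stats["n_ops_length_gated"] += 1
            if op in _REF_CONSUMING:
                pos += length
    return junctions, stats


def assign_strand(
    junction: Junction, genome: GenomeSequence, tag_hint: str | None = None
) -> str:
    """Resolve a junction's strand.

    A strand tag wins when present; otherwise the terminal motif decides:
    ``GT...AG`` on the forward interval means ``+``, its reverse complement
    ``CT...AC`` means ``-``. Anything else is undetermined (a value, not an
    error) and is later excluded when ``require_strand`` is set.
    """
    if tag_hint in (FORWARD, REVERSE):
        junction.strand = tag_hint
        junction.strand_evidence = "tag"
        return tag_hint
    seq = genome[junction.contig][junction.start : junction.end]
    fwd = seq.startswith("GT") and seq.endswith("AG")
    rev = seq.startswith("CT") and seq.endswith("AC")
    if fwd and not rev:
        junction.strand, junction.strand_evidence = FORWARD, "forward-motif"
    elif rev and not fwd:
        junction.strand, junction.strand_evidence = REVERSE, "reverse-motif"
    else:
        junction.strand, junction.strand_evidence = UNDETERMINED, "ambiguous"
    return junction.strand


def _consensus_tag(junction: Junction) -> str | None:
    """Unanimous strand tag across supporting reads, if any."""
    tags = [s for s in (FORWARD, REVERSE) if junction.tag_counts.get(s)]
    return tags[0] if len(tags) == 1 else None


def filter_junctions(
    junctions: Iterable[Junction],
    config: JunctionFilterConfig | None = None,
    species: str = "",
) -> List[IntronRecord]:
    """Apply the support and strand gates; emit sorted intron records.

    A junction is kept iff ``support >= min_support`` and, when
    ``require_strand``, its strand is determined.
    """
    config = config or JunctionFilterConfig()
    kept: List[IntronRecord] = []
    for junc in junctions:
        if junc.support < config.min_support:
            continue
        if config.require_strand and junc.strand not in (FORWARD, REVERSE):
            continue
        kept.append(
            IntronRecord(junc.contig, junc.start, junc.end, junc.strand,
                         junc.support, species)
        )
    kept.sort(key=lambda r: (r.contig, r.start, r.end))
    return kept


def resolve_overlaps(introns: List[IntronRecord]) -> List[IntronRecord]:
    """Collapse overlapping same-strand introns to the best-supported call.

    Identical intervals are first deduplicated with supports summed. Then,
    within each maximal cluster of transitively overlapping same-strand
    introns, only the record with highest support is retained; ties break
    by longer length, then smaller start.
    """
    merged: Dict[Tuple[str, int, int, str], int] = {}
    species = ""
    for rec in introns:
        key = (rec.contig, rec.start, rec.end, rec.strand)
        merged[key] = merged.get(key, 0) + rec.support
        species = rec.species or species
    records = sorted(
        IntronRecord(c, s, e, st, sup, species)
        for (c, s, e, st), sup in merged.items()
    )

    out: List[IntronRecord] = []
    by_group: Dict[Tuple[str, str], List[IntronRecord]] = {}
    for rec in records:
        by_group.setdefault((rec.contig, rec.strand), []).append(rec)

    def best(cluster: List[IntronRecord]) -> IntronRecord:
        return max(cluster, key=lambda r: (r.support, r.length, -r.start))

    for group in by_group.values():
        cluster: List[IntronRecord] = []
        cluster_end = -1
        for rec in group:  # already sorted by (contig, start, end)
            if cluster and rec.start >= cluster_end:
                out.append(best(cluster))
                cluster = []
                cluster_end = -1
            cluster.append(rec)
            cluster_end = max(cluster_end, rec.end)
        if cluster:
            out.append(best(cluster))
    out.sort(key=lambda r: (r.contig, r.start, r.end))
    return out


def call_introns(
    alignments,
    genome: GenomeSequence,
    config: JunctionFilterConfig | None = None,
    species: str = "",
) -> Tuple[List[IntronRecord], Dict[str, int]]:
    """Full junction-calling stage: extract, strand, filter, de-overlap."""
    config = config or JunctionFilterConfig()
    junctions, stats = extract_junctions(alignments, config)
    for junc in junctions.values():
        assign_strand(junc, genome, tag_hint=_consensus_tag(junc))
    introns = filter_junctions(junctions.values(), config, species=species)
    introns = resolve_overlaps(introns)
    stats["introns_kept"] = len(introns)
    return introns, stats
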