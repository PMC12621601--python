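"""Synthetic genomes, intron annotations and spliced reads.

Two archetypes are generated. *Canonical-mode* species emulate a
diplonemid-like intron landscape: ~98% GT..AG introns with a GTATG-like
donor consensus, a C-rich polypyrimidine tract ending in CAG, and a
configurable branch-point implantation rate. *Hemistasiid-mode* species
invert the picture: ~97% noncanonical introns whose terminal dinucleotides
are drawn from a CT-CG / TG-GC / CG-AG / GC-CA-enriched spectrum, with
GC-rich bodies and (by default) 3' ends that are a lightly mutated reverse
complement of the 5' end — the inverted-repeat structure that gives these
introns their high end base-pairing.

Genes are laid out one per contig as alternating exons and introns;
spliced reads are emitted directly as aligned SAM records (CIGARs skipping
each intron, strand tags always present) so the unit under test is
junction counting and filtering, not alignment. A single seed controls all
randomness and regeneration is byte-identical.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .genomic_io import (
    FORWARD,
    REVERSE,
    GenomeSequence,
    IntronRecord,
    reverse_complement,
    write_fasta,
    write_introns,
)
from .splice_sites import CANONICAL, NONCANONICAL

__all__ = [
    "SpeciesSpec",
    "SpeciesBundle",
    "canonical_species",
    "hemistasiid_species",
    "default_cohort_specs",
    "sample_intron",
    "build_species",
    "build_cohort",
]

BASES = "ACGT"

#: canonical donor consensus for intronic positions +3..+5 (after GT),
#: mimicking a GTATG-like 5'ss
_DONOR_CONSENSUS = (
    {"A": 0.7, "C": 0.1, "G": 0.1, "T": 0.1},
    {"T": 0.7, "A": 0.1, "C": 0.1, "G": 0.1},
    {"G": 0.7, "A": 0.1, "C": 0.1, "T": 0.1},
)

#: default C-rich polypyrimidine-tract composition
_PPT_WEIGHTS = {"A": 0.10, "C": 0.45, "G": 0.10, "T": 0.35}

#: A-rich PPT variant (the unusual poly(A)-tract mode)
_PPT_WEIGHTS_A_RICH = {"A": 0.40, "C": 0.25, "G": 0.10, "T": 0.25}

#: noncanonical terminal dinucleotide spectrum, enriched for the common
#: hemistasiid combinations; the remainder spreads over other pairs
_NONCANONICAL_DINUCS = {
    ("CT", "CG"): 0.22,
    ("TG", "GC"): 0.18,
    ("CG", "AG"): 0.16,
    ("GC", "CA"): 0.12,
    ("CC", "GG"): 0.08,
    ("GG", "CC"): 0.08,
    ("CA", "TG"): 0.06,
    ("AC", "GT"): 0.05,
    ("TC", "GA"): 0.05,
}


@dataclass(frozen=True)
class SpeciesSpec:
    """Generator parameters for one synthetic species."""

    name: str
    n_genes: int = 100
    introns_per_gene: int = 4
    canonical_fraction: float = 0.98
    length_log_mu: float = math.log(60.0)  # log-normal location: median length
    length_log_sigma: float = 0.45
    min_len: int = 20
    max_len: int = 2000
    donor_consensus: Tuple[Dict[str, float], ...] = _DONOR_CONSENSUS
    ppt_weights: Dict[str, float] = field(default_factory=lambda: dict(_PPT_WEIGHTS))
    noncanonical_dinuc_weights: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(_NONCANONICAL_DINUCS)
    )
    intron_gc: float = 0.5
    revcomp_end_prob: float = 0.9
    revcomp_mutation_rate: float = 0.1
    branchpoint_rate: float = 0.15
    exon_gc: float = 0.5
    exon_len: int = 100
    depth_mean: float = 30.0
    depth_dispersion: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for prob in (self.canonical_fraction, self.revcomp_end_prob,
                     self.revcomp_mutation_rate, self.branchpoint_rate,
                     self.intron_gc, self.exon_gc):
            if not (0.0 <= prob <= 1.0):
                raise ValueError(f"probability {prob} outside [0, 1]")
        if self.min_len < 4:
            raise ValueError("min_len must be >= 4")
        if self.depth_mean < 0:
            raise ValueError("read depth must be >= 0")


def canonical_species(name: str, seed: int, median_len: float = 60.0,
                      **overrides) -> SpeciesSpec:
    """A diplonemid-like species: dominated by canonical GT..AG introns."""
    return SpeciesSpec(
        name=name, seed=seed, canonical_fraction=0.98,
        length_log_mu=math.log(median_len), intron_gc=0.5,
        revcomp_end_prob=0.0, branchpoint_rate=0.15, **overrides,
    )


def hemistasiid_species(name: str, seed: int, median_len: float = 60.0,
                        **overrides) -> SpeciesSpec:
    """A hemistasiid-like species: noncanonical introns dominate, bodies
    are GC-rich and the intron ends are reverse complementary."""
    return SpeciesSpec(
        name=name, seed=seed, canonical_fraction=0.03,
        length_log_mu=math.log(median_len), intron_gc=0.65,
        revcomp_end_prob=0.9, revcomp_mutation_rate=0.1,
        branchpoint_rate=0.05, **overrides,
    )


def default_cohort_specs(seed: int = 17, n_genes: int = 100,
                         introns_per_gene: int = 4) -> List[SpeciesSpec]:
    """The default six-species cohort: four canonical-mode species with
    median intron lengths 41/42/74/107 nt and two hemistasiid-mode species
    with medians 37/91 nt."""
    specs = [
        hemistasiid_species("hemi_A", seed * 7 + 1, median_len=37.0,
                            n_genes=n_genes, introns_per_gene=introns_per_gene),
        hemistasiid_species("hemi_B", seed * 7 + 2, median_len=91.0,
                            n_genes=n_genes, introns_per_gene=introns_per_gene),
        canonical_species("cano_C", seed * 7 + 3, median_len=41.0,
                          n_genes=n_genes, introns_per_gene=introns_per_gene),
        canonical_species("cano_D", seed * 7 + 4, median_len=42.0,
                          n_genes=n_genes, introns_per_gene=introns_per_gene),
        canonical_species("cano_E", seed * 7 + 5, median_len=74.0,
                          n_genes=n_genes, introns_per_gene=introns_per_gene),
        canonical_species("cano_F", seed * 7 + 6, median_len=107.0,
                          n_genes=n_genes, introns_per_gene=introns_per_gene),
    ]
    return specs


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=probs)])


def _weighted_base(rng: np.random.Generator, weights: Dict[str, float]) -> str:
    bases = sorted(weights)
    probs = np.array([weights[b] for b in bases], dtype=float)
    probs /= probs.sum()
    return bases[rng.choice(len(bases), p=probs)]


def _sample_length(spec: SpeciesSpec, rng: np.random.Generator) -> int:
    for _ in range(200):
        length = int(round(rng.lognormal(spec.length_log_mu, spec.length_log_sigma)))
        if spec.min_len <= length <= spec.max_len:
            return length
    return int(np.clip(length, spec.min_len, spec.max_len))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = BASES[rng.integers(4)]
    return "".join(out)


def _implant_branchpoint(
    seq: List[str], rng: np.random.Generator, protect_tail: int
) -> Optional[int]:
    """Implant a YTRAY realization at a uniform legal offset.

    The legal window keeps every pentamer base >5 and <50 nt upstream of
    the 3' end; offsets are further restricted to start at index >= 9 and
    to leave the last ``protect_tail`` nt untouched, so implantation can
    never clobber the donor consensus, terminal dinucleotides or
    reverse-complementary end regions that the ground truth records.
    Returns the offset, or None when the window is empty.
    """
    L = len(seq)
    lo = max(9, L - 49)
    hi = min(L - 10, L - protect_tail - 5)
    if hi < lo:
        return None
    offset = int(rng.integers(lo, hi + 1))
    y1 = "CT"[rng.integers(2)]
    r = "AG"[rng.integers(2)]
    y2 = "CT"[rng.integers(2)]
    seq[offset : offset + 5] = list(y1 + "T" + r + "A" + y2)
    return offset


def sample_intron(spec: SpeciesSpec, rng: np.random.Generator) -> Tuple[str, Dict]:
    """Draw one intron sequence plus its ground-truth record."""
    length = _sample_length(spec, rng)
    is_canonical = rng.random() < spec.canonical_fraction
    seq = list(_random_dna(rng, length, spec.intron_gc))

    revcomp_ends = False
    if is_canonical:
        dinuc5, dinuc3 = "GT", "AG"
        seq[0:2] = "GT"
        for i, weights in enumerate(spec.donor_consensus):
            if 2 + i < length - 2:
                seq[2 + i] = _weighted_base(rng, weights)
        # polypyrimidine tract over the last 20 intronic nt, ending CAG
        ppt_len = min(20, length - 5)
        for i in range(length - ppt_len - 3, length - 3):
            if i >= 5:
                seq[i] = _weighted_base(rng, spec.ppt_weights)
        seq[length - 3 :] = "CAG"
    else:
        pairs = sorted(spec.noncanonical_dinuc_weights)
        probs = np.array(
            [spec.noncanonical_dinuc_weights[p] for p in pairs], dtype=float
        )
        probs /= probs.sum()
        dinuc5, dinuc3 = pairs[rng.choice(len(pairs), p=probs)]
        if length >= 18 and rng.random() < spec.revcomp_end_prob:
            revcomp_ends = True
            head = "".join(seq[:9])
            tail = _mutate(reverse_complement(head), spec.revcomp_mutation_rate, rng)
            seq[-9:] = list(tail)
        seq[0:2] = list(dinuc5)
        seq[-2:] = list(dinuc3)

    bp_offset: Optional[int] = None
    if rng.random() < spec.branchpoint_rate:
        protect_tail = 9 if revcomp_ends else 3
        bp_offset = _implant_branchpoint(seq, rng, protect_tail)

    truth = {
        "klass": CANONICAL if is_canonical else NONCANONICAL,
        "dinuc5": dinuc5,
        "dinuc3": dinuc3,
        "bp_implanted": bp_offset is not None,
        "bp_offset": -1 if bp_offset is None else bp_offset,
        "revcomp_ends": revcomp_ends,
    }
    return "".join(seq), truth


@dataclass
class SpeciesBundle:
    """In-memory view of one generated species plus its file paths."""

    spec: SpeciesSpec
    genome: GenomeSequence
    introns: List[IntronRecord]
    truth: pd.DataFrame
    fasta_path: Optional[Path] = None
    gtf_path: Optional[Path] = None
    sam_path: Optional[Path] = None
    truth_path: Optional[Path] = None
    sam_text: Optional[str] = None  # populated when no outdir is given


def _sample_depth(spec: SpeciesSpec, rng: np.random.Generator) -> int:
    if spec.depth_dispersion <= 0:
        return int(round(spec.depth_mean))
    r = spec.depth_dispersion
    p = r / (r + spec.depth_mean)
    return int(rng.negative_binomial(r, p))


_READ_ANCHOR = 30  # exonic nt aligned on each side of a junction


def build_species(spec: SpeciesSpec, outdir: str | os.PathLike | None = None,
                  constant_depth: Optional[int] = None) -> SpeciesBundle:
    """Generate one species: FASTA genome, truth introns (GTF), spliced SAM
    reads and a ground-truth table, all seeded from ``spec.seed``.

    Genes are alternately plus- and minus-strand; minus genes are built in
    transcript orientation and embedded reverse complemented, so genomic
    coordinates exercise both orientations. ``constant_depth`` overrides
    the negative-binomial read depth model with a fixed per-intron count.
    """
    rng = np.random.default_rng(spec.seed)
    contigs: Dict[str, str] = {}
    introns: List[IntronRecord] = []
    truth_rows: List[Dict] = []
    reads: List[Tuple[str, int, str, str, str]] = []  # contig, pos0, cigar, seq, strand

    for g in range(spec.n_genes):
        strand = FORWARD if g % 2 == 0 else REVERSE
        contig_name = f"{spec.name}_g{g:04d}"
        parts: List[str] = []
        intron_spans: List[Tuple[int, int, Dict]] = []
        pos = 0
        for k in range(spec.introns_per_gene + 1):
            exon = _random_dna(rng, spec.exon_len, spec.exon_gc)
            parts.append(exon)
            pos += spec.exon_len
            if k < spec.introns_per_gene:
                intron_seq, truth = sample_intron(spec, rng)
                parts.append(intron_seq)
                intron_spans.append((pos, pos + len(intron_seq), truth))
                pos += len(intron_seq)
        transcript_oriented = "".join(parts)
        total = len(transcript_oriented)
        if strand == FORWARD:
            contig = transcript_oriented
            spans = [(s, e, t) for s, e, t in intron_spans]
        else:
            contig = reverse_complement(transcript_oriented)
            spans = [(total - e, total - s, t) for s, e, t in intron_spans]
        contigs[contig_name] = contig

        for s, e, truth in spans:
            depth = (constant_depth if constant_depth is not None
                     else _sample_depth(spec, rng))
            rec = IntronRecord(contig_name, s, e, strand, depth, spec.name)
            introns.append(rec)
            row = {"contig": contig_name, "start": s, "end": e,
                   "strand": strand, "support": depth, **truth}
            truth_rows.append(row)
            cigar = f"{_READ_ANCHOR}M{e - s}N{_READ_ANCHOR}M"
            read_seq = contig[s - _READ_ANCHOR : s] + contig[e : e + _READ_ANCHOR]
            for _ in range(depth):
                reads.append((contig_name, s - _READ_ANCHOR, cigar, read_seq, strand))

    genome = GenomeSequence(contigs)
    introns.sort(key=lambda r: (r.contig, r.start, r.end))
    truth = pd.DataFrame(truth_rows).sort_values(
        ["contig", "start", "end"], ignore_index=True
    )

    bundle = SpeciesBundle(spec=spec, genome=genome, introns=introns, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bundle.fasta_path = outdir / f"{spec.name}.fasta"
        bundle.gtf_path = outdir / f"{spec.name}.gtf"
        bundle.sam_path = outdir / f"{spec.name}.sam"
        bundle.truth_path = outdir / f"{spec.name}.truth.tsv"
        write_fasta(genome, bundle.fasta_path)
        write_introns(introns, bundle.gtf_path, "GTF")
        _write_sam(bundle.sam_path, genome, reads)
        truth.to_csv(bundle.truth_path, sep="\t", index=False)
    else:
        bundle.sam_text = _sam_text(genome, reads)
    return bundle


def _sam_text(genome: GenomeSequence, reads) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name in genome.contig_ids:
        lines.append(f"@SQ\tSN:{name}\tLN:{genome.length(name)}")
    for i, (contig, pos0, cigar, seq, strand) in enumerate(reads):
        lines.append(
            f"r{i:07d}\t0\t{contig}\t{pos0 + 1}\t255\t{cigar}\t*\t0\t0\t{seq}"
            f"\t*\tXS:A:{strand}"
        )
    return "\n".join(lines) + "\n"


def _write_sam(path: Path, genome: GenomeSequence, reads) -> None:
    path.write_text(_sam_text(genome, reads))


def build_cohort(
    specs: Sequence[SpeciesSpec], outdir: str | os.PathLike,
    constant_depth: Optional[int] = None,
) -> Dict[str, SpeciesBundle]:
    """Generate every species and a YAML manifest listing files and seeds."""
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate species names in cohort: {names}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundles: Dict[str, SpeciesBundle] = {}
    manifest = {"species": {}}
    for spec in specs:
        bundle = build_species(spec, outdir, constant_depth=constant_depth)
        bundles[spec.name] = bundle
        manifest["species"][spec.name] = {
            "seed": spec.seed,
            "fasta": bundle.fasta_path.name,
            "gtf": bundle.gtf_path.name,
            "sam": bundle.sam_path.name,
            "truth": bundle.truth_path.name,
            "n_introns": len(bundle.introns),
        }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return bundles
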