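"""Splice-site characterization: classification, windows, PWMs, logos,
branch points, polypyrimidine-tract composition and length statistics.

Introns beginning ``GT`` and ending ``AG`` (transcript orientation) are
canonical; everything else is noncanonical. Splice-site windows come in two
layouts: *logo* mode (donor 3 exonic + 6 intronic nt, acceptor 20 intronic
+ 3 exonic nt) and *phylo* mode (donor 3 exonic + 9 intronic nt, same
acceptor) used for PWM-based clustering. Branch points are pentamer YTRAY
matches whose every base lies strictly more than 5 and strictly fewer than
50 nt upstream of the intron 3' end.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomic_io import (
    FORWARD,
    REVERSE,
    GenomeSequence,
    IntronRecord,
    reverse_complement,
)

__all__ = [
    "CANONICAL",
    "NONCANONICAL",
    "BASES",
    "SpliceSiteWindows",
    "PWM",
    "BranchPointConfig",
    "WindowSkip",
    "classify_intron",
    "dinucleotide_spectrum",
    "extract_windows",
    "collect_windows",
    "build_pwm",
    "logo_matrix",
    "scan_branchpoint",
    "branchpoint_fraction",
    "length_stats",
    "ppt_composition",
]

BASES = "ACGT"
CANONICAL = "canonical"
NONCANONICAL = "noncanonical"

#: donor window layout per mode: (exonic nt, intronic nt)
DONOR_LAYOUT = {"logo": (3, 6), "phylo": (3, 9)}
#: acceptor layout is shared: 20 intronic + 3 exonic nt
ACCEPTOR_LAYOUT = (20, 3)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


class WindowSkip(Exception):
    """Raised when a splice-site window cannot be extracted; carries a reason
    used for per-analysis tallies (``short_intron``, ``contig_edge``,
    ``ambiguous``)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class SpliceSiteWindows:
    """Donor and acceptor windows in transcript orientation."""

    donor: str
    acceptor: str
    mode: str

    def __post_init__(self) -> None:
        exonic, intronic = DONOR_LAYOUT[self.mode]
        if len(self.donor) != exonic + intronic:
            raise ValueError(
                f"donor length {len(self.donor)} != {exonic + intronic} for "
                f"{self.mode} mode"
            )
        if len(self.acceptor) != sum(ACCEPTOR_LAYOUT):
            raise ValueError(f"acceptor length {len(self.acceptor)} != 23")


@dataclass(frozen=True)
class PWM:
    """Per-position nucleotide frequency matrix (rows A, C, G, T)."""

    matrix: np.ndarray  # shape (4, L)
    n_sequences: int
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != 4:
            raise ValueError(f"PWM matrix must be 4 x L, got {m.shape}")
        if (m < 0).any():
            raise ValueError("PWM entries must be non-negative")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def slice(self, columns: slice | Sequence[int]) -> "PWM":
        return PWM(np.ascontiguousarray(self.matrix[:, columns]),
                   self.n_sequences, self.pseudocount)


@dataclass(frozen=True)
class BranchPointConfig:
    """YTRAY scan parameters.

    Every base of a hit must lie strictly more than ``min_upstream`` and
    strictly fewer than ``max_upstream`` nt upstream of the 3' end of the
    intron (the base adjacent to the 3' boundary is 1 nt upstream).
    """

    motif: str = "YTRAY"
    min_upstream: int = 5
    max_upstream: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.min_upstream < self.max_upstream):
            raise ValueError("need 0 < min_upstream < max_upstream")
        for ch in self.motif:
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r} in motif")


def classify_intron(intron_seq: str) -> str:
    """``canonical`` iff the intron starts GT and ends AG; else ``noncanonical``."""
    if len(intron_seq) < 4:
        raise ValueError(f"intron too short to classify ({len(intron_seq)} nt)")
    if intron_seq[:2] == "GT" and intron_seq[-2:] == "AG":
        return CANONICAL
    return NONCANONICAL


def dinucleotide_spectrum(
    introns: Iterable[IntronRecord], genome: GenomeSequence
) -> pd.DataFrame:
    """Counts and fractions of terminal 5'/3' dinucleotide combinations.

    Dinucleotides are read in transcript orientation, so minus-strand
    introns contribute the reverse complement of their genomic termini.
    Fractions sum to 1 over observed combinations.
    """
    counts: Counter = Counter()
    for rec in introns:
        from .genomic_io import intron_sequence

        seq = intron_sequence(rec, genome)
        counts[(seq[:2], seq[-2:])] += 1
    total = sum(counts.values())
    rows = [
        {"dinuc5": d5, "dinuc3": d3, "count": n, "fraction": n / total}
        for (d5, d3), n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["dinuc5", "dinuc3", "count", "fraction"])


def extract_windows(
    intron: IntronRecord, genome: GenomeSequence, mode: str = "logo"
) -> SpliceSiteWindows:
    """Extract donor/acceptor windows in transcript orientation.

    Raises :class:`WindowSkip` when the intron is too short for the
    intronic parts of the windows, sits at a contig edge, or a window
    contains N.
    """
    if mode not in DONOR_LAYOUT:
        raise ValueError(f"unknown mode {mode!r}")
    exonic, intronic = DONOR_LAYOUT[mode]
    acc_in, acc_ex = ACCEPTOR_LAYOUT
    if intron.length < max(intronic, acc_in):
        raise WindowSkip("short_intron")
    contig = genome[intron.contig]
    s, e = intron.start, intron.end
    if intron.strand == FORWARD:
        if s - exonic < 0 or e + acc_ex > len(contig):
            raise WindowSkip("contig_edge")
        donor = contig[s - exonic : s + intronic]
        acceptor = contig[e - acc_in : e + acc_ex]
    elif intron.strand == REVERSE:
        if e + exonic > len(contig) or s - acc_ex < 0:
            raise WindowSkip("contig_edge")
        donor = reverse_complement(contig[e - intronic : e + exonic])
        acceptor = reverse_complement(contig[s - acc_ex : s + acc_in])
    else:
        raise ValueError("cannot extract windows for undetermined strand")
    if "N" in donor or "N" in acceptor:
        raise WindowSkip("ambiguous")
    return SpliceSiteWindows(donor, acceptor, mode)


def collect_windows(
    introns: Iterable[IntronRecord], genome: GenomeSequence, mode: str = "logo"
) -> Tuple[List[SpliceSiteWindows], Dict[str, int]]:
    """Windows for every eligible intron plus a tally of skip reasons."""
    windows: List[SpliceSiteWindows] = []
    tally = {"short_intron": 0, "contig_edge": 0, "ambiguous": 0}
    for rec in introns:
        try:
            windows.append(extract_windows(rec, genome, mode))
        except WindowSkip as skip:
            tally[skip.reason] += 1
    return windows, tally


def build_pwm(window_seqs: Sequence[str], pseudocount: float = 0.0) -> PWM:
    """Column frequencies ``(count + pseudocount) / (n + 4*pseudocount)``."""
    if not window_seqs:
        raise ValueError("cannot build a PWM from an empty sequence set")
    length = len(window_seqs[0])
    if any(len(s) != length for s in window_seqs):
        raise ValueError("ragged window lengths")
    counts = np.zeros((4, length))
    index = {b: i for i, b in enumerate(BASES)}
    for seq in window_seqs:
        for j, base in enumerate(seq):
            try:
                counts[index[base], j] += 1
            except KeyError:
                raise ValueError(f"invalid base {base!r} in window {seq!r}") from None
    n = len(window_seqs)
    freqs = (counts + pseudocount) / (n + 4 * pseudocount)
    return PWM(freqs, n, pseudocount)


def logo_matrix(pwm: PWM, small_sample_correction: bool = False) -> pd.DataFrame:
    """Per-column information content and letter heights.

    ``IC_j = 2 - H_j`` with ``H_j`` the Shannon entropy in bits
    (0*log 0 := 0); letter height is ``p_bj * IC_j``. The optional
    small-sample correction subtracts ``3 / (2 ln2 n)``, floored at 0.
    """
    p = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -terms.sum(axis=0)
    ic = 2.0 - entropy
    if small_sample_correction and pwm.n_sequences > 0:
        ic = np.maximum(ic - 3.0 / (2.0 * np.log(2) * pwm.n_sequences), 0.0)
    heights = p * ic
    df = pd.DataFrame(heights.T, columns=list(BASES))
    df.insert(0, "position", np.arange(pwm.length))
    df["ic"] = ic
    return df


def _matches_iupac(seq: str, motif: str) -> bool:
    return all(base in IUPAC[code] for base, code in zip(seq, motif))


def scan_branchpoint(
    intron_seq: str, config: BranchPointConfig | None = None
) -> List[int]:
    """0-based start offsets of motif hits inside the legal window.

    A base at index ``i`` of an intron of length ``L`` lies ``L - i`` nt
    upstream of the 3' end; every base of the pentamer must satisfy
    ``min_upstream < L - i < max_upstream``.
    """
    config = config or BranchPointConfig()
    L = len(intron_seq)
    m = len(config.motif)
    if L < m:
        return []
    lo = max(0, L - config.max_upstream + 1)  # L - i < max  =>  i >= L - max + 1
    hi = L - config.min_upstream - m          # L - (s+m-1) > min  =>  s <= L - min - m
    hits = []
    for s in range(lo, hi + 1):
        if _matches_iupac(intron_seq[s : s + m], config.motif):
            hits.append(s)
    return hits


def branchpoint_fraction(
    intron_seqs: Sequence[str], config: BranchPointConfig | None = None
) -> Tuple[float, int]:
    """Fraction of introns with at least one motif hit, with denominator."""
    if not intron_seqs:
        raise ValueError("empty intron set")
    n_hit = sum(1 for seq in intron_seqs if scan_branchpoint(seq, config))
    return n_hit / len(intron_seqs), len(intron_seqs)


def length_stats(introns: Sequence[IntronRecord]) -> Dict[str, float]:
    """Median, quartiles and count of intron lengths."""
    if not introns:
        raise ValueError("empty intron set")
    lengths = np.array([rec.length for rec in introns], dtype=float)
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "n": len(introns)}


def ppt_composition(acceptor_windows: Sequence[str]) -> pd.DataFrame:
    """Per-position base frequencies over the 20 intronic acceptor columns.

    Equivalent to a PWM restricted to the intronic part of the acceptor
    window; this is where the polypyrimidine tract lives.
    """
    if not acceptor_windows:
        raise ValueError("empty window set")
    acc_in, _ = ACCEPTOR_LAYOUT
    pwm = build_pwm([w[:acc_in] for w in acceptor_windows])
    df = pd.DataFrame(pwm.matrix.T, columns=list(BASES))
    # positions -20 .. -1 relative to the intron 3' end
    df.insert(0, "position", np.arange(-acc_in, 0))
    return df
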