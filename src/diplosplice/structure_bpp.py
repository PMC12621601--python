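"""Intron-end base-pairing statistic.

The 9-nt 5' and 3' ends of each intron (or of its flanking exons) are
concatenated into an 18-mer and folded with a maximum base-pairing dynamic
program (nested structures, Watson-Crick plus GU wobble, minimum hairpin
loop of 3 by default). The base-pairing propensity (BPP) is the number of
paired nucleotides divided by 18. High complementarity between intron ends
— the hallmark of hemistasiid-like noncanonical introns — therefore shows
up as a high BPP.

The maximizing-pair count is exactly testable against exhaustive
enumeration; an external thermodynamic folder can be substituted through
the ``engine`` hook of :class:`FoldConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Tuple

import numpy as np

from .genomic_io import (
    FORWARD,
    REVERSE,
    GenomeSequence,
    IntronRecord,
    intron_sequence,
    reverse_complement,
)

__all__ = [
    "FoldConfig",
    "BPPResult",
    "concat_ends",
    "max_pairing_fold",
    "intron_bpp",
    "exon_flank_bpp",
    "bpp_distribution",
]

DEFAULT_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})


@dataclass(frozen=True)
class FoldConfig:
    """Parameters of the end-pairing computation.

    ``k`` is the end length (9 nt on each side), ``min_loop`` the minimum
    number of unpaired bases enclosed by a pair, ``allowed_pairs`` the base
    pairs permitted, and ``engine`` either the built-in ``max-pairing`` DP
    or a callable ``seq -> (structure, paired_nt)`` for an external folder.
    """

    k: int = 9
    min_loop: int = 3
    allowed_pairs: frozenset = DEFAULT_PAIRS
    engine: str | Callable[[str], Tuple[str, int]] = "max-pairing"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")


@dataclass(frozen=True)
class BPPResult:
    """Per-intron pairing outcome for one 9+9 concatenation."""

    intron_id: str
    end5: str
    end3: str
    structure: str
    paired_nt: int
    bpp: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.bpp <= 1.0):
            raise ValueError(f"bpp {self.bpp} outside [0, 1]")
        if self.paired_nt % 2:
            raise ValueError("paired_nt must be even")


def concat_ends(intron_seq: str, k: int = 9) -> Optional[str]:
    """First ``k`` plus last ``k`` nt as RNA (T -> U), transcript orientation.

    Returns ``None`` for introns shorter than ``2k`` (the ends would
    overlap); callers tally these skips.
    """
    if len(intron_seq) < 2 * k:
        return None
    return (intron_seq[:k] + intron_seq[-k:]).replace("T", "U")


def max_pairing_fold(seq: str, config: FoldConfig | None = None) -> Tuple[str, int]:
    """Maximum base-pairing fold of an RNA string (Nussinov-style DP).

    Returns one maximizing nested structure in dot-bracket notation and
    the number of paired nucleotides (2x the number of pairs). Pairs are
    restricted to ``allowed_pairs`` and must enclose more than
    ``min_loop`` positions (``j - i > min_loop``).
    """
    config = config or FoldConfig()
    if callable(config.engine):
        return config.engine(seq)
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    n = len(seq)
    if n == 0:
        return "", 0
    pairs = config.allowed_pairs
    loop = config.min_loop
    best = np.zeros((n + 1, n + 1), dtype=np.int32)  # best[i][j] over seq[i..j]

    for span in range(loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            value = best[i + 1][j]  # i unpaired
            for k in range(i + loop + 1, j + 1):
                if seq[i] + seq[k] in pairs:
                    inner = best[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    rest = best[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + rest
                    if cand > value:
                        value = cand
            best[i][j] = value

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            if best[i][j] == (best[i + 1][j] if i + 1 <= j else 0):
                i += 1
                continue
            for k in range(i + loop + 1, j + 1):
                if seq[i] + seq[k] in pairs:
                    inner = best[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    rest = best[k + 1][j] if k + 1 <= j else 0
                    if best[i][j] == 1 + inner + rest:
                        structure[i], structure[k] = "(", ")"
                        traceback(i + 1, k - 1)
                        i, j = k + 1, j
                        break
            else:  # pragma: no cover - DP/traceback mismatch would be a bug
                raise AssertionError("traceback failed")

    traceback(0, n - 1)
    return "".join(structure), int(2 * best[0][n - 1])


def _fold_concat(intron_id: str, end5: str, end3: str,
                 config: FoldConfig) -> BPPResult:
    seq = (end5 + end3).replace("T", "U")
    structure, paired = max_pairing_fold(seq, config)
    return BPPResult(intron_id, end5, end3, structure, paired,
                     paired / len(seq))


def _intron_id(rec: IntronRecord) -> str:
    return f"{rec.contig}:{rec.start}-{rec.end}({rec.strand})"


def intron_bpp(
    intron: IntronRecord, genome: GenomeSequence, config: FoldConfig | None = None
) -> Optional[BPPResult]:
    """BPP of the intron's own 9+9 nt ends; ``None`` when too short."""
    config = config or FoldConfig()
    seq = intron_sequence(intron, genome)
    rna = concat_ends(seq, config.k)
    if rna is None:
        return None
    return _fold_concat(_intron_id(intron), seq[: config.k], seq[-config.k :], config)


def exon_flank_bpp(
    intron: IntronRecord, genome: GenomeSequence, config: FoldConfig | None = None
) -> Optional[BPPResult]:
    """BPP of the exonic flanks: the ``k`` nt of upstream exon just before
    the 5' splice site and the ``k`` nt of downstream exon just after the
    3' splice site, in transcript orientation. ``None`` at contig edges."""
    config = config or FoldConfig()
    contig = genome[intron.contig]
    k = config.k
    s, e = intron.start, intron.end
    if intron.strand == FORWARD:
        if s - k < 0 or e + k > len(contig):
            return None
        up, down = contig[s - k : s], contig[e : e + k]
    elif intron.strand == REVERSE:
        if e + k > len(contig) or s - k < 0:
            return None
        up = reverse_complement(contig[e : e + k])
        down = reverse_complement(contig[s - k : s])
    else:
        raise ValueError("cannot orient flanks for undetermined strand")
    if "N" in up or "N" in down:
        return None
    return _fold_concat(_intron_id(intron), up, down, config)


def bpp_distribution(
    introns: Iterable[IntronRecord],
    genome: GenomeSequence,
    config: FoldConfig | None = None,
    flank: str = "intron",
) -> Dict[str, float]:
    """Per-species BPP summary: median, quartiles, notch CI, n, skipped.

    The notch interval follows the standard box-plot rule
    ``median +/- 1.58 * IQR / sqrt(n)``.
    """
    config = config or FoldConfig()
    compute = intron_bpp if flank == "intron" else exon_flank_bpp
    values: List[float] = []
    skipped = 0
    for rec in introns:
        result = compute(rec, genome, config)
        if result is None:
            skipped += 1
        else:
            values.append(result.bpp)
    if not values:
        raise ValueError("no introns yielded a BPP value")
    arr = np.asarray(values)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    notch = 1.58 * iqr / math.sqrt(len(arr))
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "notch_lo": float(med - notch), "notch_hi": float(med + notch),
        "n": len(arr), "skipped": skipped,
    }
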