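"""Independent oracles used by the test suite.

Each oracle deliberately takes a different route than the implementation
it checks: exhaustive recursion instead of dynamic programming, a regular
expression instead of the IUPAC scanner, scipy's linkage instead of the
in-package UPGMA, and plain text splitting instead of pysam.
"""

from __future__ import annotations

import re
from typing import Dict, List, Tuple

ALLOWED_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}


def enum_max_pairs(seq: str, min_loop: int = 3,
                   pairs=frozenset(ALLOWED_PAIRS)) -> int:
    """Maximum paired-nucleotide count by exhaustive recursion over all
    nested structures (no memoization)."""

    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        value = best(i + 1, j)  # leave i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if seq[i] + seq[k] in pairs:
                value = max(value, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return value

    return 2 * best(0, len(seq) - 1) if seq else 0


_BP_RE = re.compile(r"(?=([CT]T[AG]A[CT]))")


def regex_branchpoints(seq: str, min_up: int = 5, max_up: int = 50) -> List[int]:
    """YTRAY hits whose every base is strictly >min_up and <max_up nt
    upstream of the 3' end, found with a regular expression."""
    L = len(seq)
    hits = []
    for m in _BP_RE.finditer(seq):
        s = m.start()
        if all(min_up < L - i < max_up for i in range(s, s + 5)):
            hits.append(s)
    return hits


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def recount_sam_junctions(
    sam_text: str, min_intron: int, max_intron: int
) -> Dict[Tuple[str, int, int], int]:
    """Brute-force recount of N-operation skipped intervals from SAM text."""
    counts: Dict[Tuple[str, int, int], int] = {}
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        flag = int(fields[1])
        if flag & 4:  # unmapped
            continue
        contig, pos, cigar = fields[2], int(fields[3]) - 1, fields[5]
        ref = pos
        for length, op in _CIGAR_RE.findall(cigar):
            length = int(length)
            if op == "N":
                if min_intron <= length <= max_intron:
                    key = (contig, ref, ref + length)
                    counts[key] = counts.get(key, 0) + 1
                ref += length
            elif op in "MD=X":
                ref += length
    return counts


def naive_upgma_heights(dist, labels=None) -> List[float]:
    """Merge heights from scipy's average linkage (UPGMA heights are half
    the merge distances)."""
    import numpy as np
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(np.asarray(dist)), method="average")
    return sorted(float(h) / 2.0 for h in Z[:, 2])


def scipy_cophenetic(dist):
    """Cophenetic distance matrix under average linkage via scipy."""
    import numpy as np
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(np.asarray(dist)), method="average")
    return squareform(cophenet(Z))
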