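# Methods

## Scope and model

`diplosplice` characterizes spliceosomal introns in draft genome
assemblies of diplonemid-like protists, where two intron landscapes
coexist: a *canonical* regime (GT..AG termini, GTATG-like donor, C-rich
polypyrimidine tract, CAG acceptor) typical of the family Diplonemidae,
and a *noncanonical* regime typical of Hemistasiidae, in which most
introns carry variable terminal dinucleotides (CT-CG, TG-GC, CG-AG,
GC-CA, ...), GC-rich bodies, and 5'/3' ends that are approximately
reverse complementary — inverted repeats that let the intron ends base
pair and fold back on themselves.

The pipeline runs in method order:

1. **Junction calling.** Spliced alignments (SAM) are scanned for CIGAR
   `N` operations; each skipped reference interval is a candidate intron,
   supported by the number of reads that skip exactly that interval.
   Intervals outside `[min_intron, max_intron] = [12, 10000]` are dropped
   at extraction. Strand comes from the alignment strand tag (`XS`) when
   all supporting reads agree, else from the terminal motif (GT..AG
   forward, CT..AC reverse); junctions that remain undetermined are
   excluded when `require_strand` is set (default). Junctions supported
   by fewer than `min_support = 15` split reads are discarded (the
   threshold is inclusive: 15 is kept). Finally, overlapping same-strand
   introns are collapsed: identical intervals merge with supports summed,
   then within each *transitive* overlap cluster only the
   highest-support record survives (ties: longer, then smaller start).
   Transitive clustering was chosen over pairwise comparison because it
   is order-independent and guarantees a non-overlapping output, which
   the pairwise reading does not.
2. **Classification and splice-site summaries.** An intron is canonical
   iff it begins GT and ends AG in transcript orientation. Windows:
   donor = 3 exonic + 6 intronic nt (logo mode) or 3 exonic + 9 intronic
   nt (phylo mode); acceptor = 20 intronic + 3 exonic nt. Both layouts
   are first-class modes. PWM entries are
   `(count + pseudocount) / (n + 4 * pseudocount)`; logo information
   content is `IC_j = 2 - H_j` bits with letter height `p_bj * IC_j`,
   without small-sample correction by default (available as an option).
   Branch points are YTRAY pentamers whose **every base** lies strictly
   more than 5 and strictly fewer than 50 nt upstream of the intron 3'
   end; the window rule is applied to the whole pentamer because a
   branch-point adenosine cannot act at the splice-site boundary itself,
   and the bounds are config-exposed.
3. **Intron-end base pairing (BPP).** The first and last 9 nt of each
   intron (or the 9 nt exon flanks) are concatenated into an 18-mer
   (T→U) and folded with a maximum base-pairing dynamic program
   (Nussinov-style): nested structures only, Watson-Crick + GU wobble
   pairs, minimum hairpin loop 3. BPP = paired nucleotides / 18. A
   thermodynamic folder can be substituted through the `engine` callable
   in `FoldConfig`; the max-pairing engine is the default because it is
   self-contained and exactly testable against exhaustive enumeration,
   while preserving the qualitative contrast that matters here (high end
   complementarity ⇒ high BPP). Note that under `min_loop = 3` an
   18-mer can reach at most 14 paired nucleotides (7 pairs), so BPP
   saturates at 14/18 ≈ 0.78. Introns shorter than 18 nt are skipped
   and tallied rather than folded with overlapping ends.
4. **PWM clustering.** Per-species, per-class PWMs are built from
   phylo-mode windows with the terminal dinucleotide columns removed
   (5'ss: intronic +1,+2; 3'ss: intronic −2,−1) so the invariant termini
   do not mask the informative positions. The pairwise distance is the
   Frobenius norm of the PWM difference (parameter-free and a true
   metric; per-column Jensen-Shannon is available), clustered with UPGMA
   (merge height = half the size-weighted average inter-cluster
   distance; ties break by lexicographically smallest member label;
   single/complete linkage available). Classes with fewer than 50
   windows are excluded — a species with ~2% noncanonical introns would
   otherwise contribute a noise-dominated PWM leaf.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open on the forward genomic strand; GTF
  input/output converts at the boundary. Windows containing `N`, introns
  at contig edges, and introns too short for a window are skipped per
  analysis and counted in a `skipped`/tally field, never padded.
- The DP traceback returns one maximizing structure (left-most
  decomposition); only the paired count is used downstream.
- Pairing symmetries: the paired count is invariant under sequence
  reversal. It is *not* invariant under reverse-complement-plus-swap
  when GU wobble is allowed (the complement of a GU pair is AC); that
  symmetry holds only for Watson-Crick-only configurations, and the
  tests assert exactly that.
- Box-plot notches use the standard rule `median ± 1.58·IQR/√n`.
- UPGMA child order and tie-breaks are fully deterministic, so newick
  output is byte-stable across runs.

## The synthetic cohort

The generator emulates per-species intron landscapes so every stage is
testable without external data. Defaults per archetype:

| parameter | canonical-mode | hemistasiid-mode |
|---|---|---|
| canonical fraction | 0.98 | 0.03 |
| intron length | log-normal, median 41/42/74/107 nt, σ=0.45, truncated [20, 2000] | medians 37/91 nt |
| intron GC | 0.50 | 0.65 |
| revcomp ends (noncanonical) | — | prob 0.9, mutation rate 0.1 |
| branch-point implantation | 0.15 | 0.05 |
| read depth | negative binomial, mean 30, dispersion 6 | same |

The default cohort is four canonical-mode plus two hemistasiid-mode
species, 100 genes × 4 introns each (400 introns/species) — enough for
stable PWMs (several hundred windows per retained class) while keeping
the full pipeline run in seconds on one core. Terminal dinucleotides
overwrite the revcomp-generated ends so the dinucleotide spectrum and end
complementarity are controllable independently. Branch-point implantation
is restricted to offsets that cannot clobber the terminal dinucleotides,
donor consensus or revcomp end regions, so the ground-truth flag always
matches the emitted sequence; introns with an empty legal window are
recorded as not implanted. Reads are emitted directly as aligned SAM with
strand tags and 30-nt exonic anchors — no sequencing-error model and no
aligner, because the unit under test is junction counting and filtering.

What the generator does **not** emulate: alignment ambiguity and mapping
error, assembly gaps, repetitive DNA, transcript-level expression
structure, trans-splicing and RNA editing. Passing tests therefore
demonstrate correctness of the analysis logic under controlled
conditions, not robustness to real alignment artifacts.

Two statistical notes. First, YTRAY is a weak motif: in random or
PPT-biased intron bodies the background hit probability inside the 5-50
nt window is substantial (tens of percent), so the observed hit fraction
overstates the implantation rate. Rate recovery therefore uses the
background-corrected estimator `r̂ = (f − b̂)/(1 − b̂)` with `b̂`
measured on a rate-0 cohort, and its tolerance is three standard errors
of that estimator (binomial errors propagated through the correction).
Second, length-median recovery is checked at a median where truncation
at 20 nt is negligible; for the shortest-median species truncation
biases the sample median upward by a few percent, which is visible in
the cohort summaries and expected.

## Known limitations

- The max-pairing engine maximizes pair count, not free energy; absolute
  BPP values differ from thermodynamic folding (typically exceeding MFE
  pair counts), so BPP should be compared within, not across, engines.
- Strand inference without tags cannot rescue noncanonical junctions;
  callers that need them must provide strand tags (the generator always
  does).
- The support threshold is applied per junction; no transcript-model
  aggregation is attempted.
- UPGMA assumes a constant divergence rate across leaves; the trees are
  phenetic clusterings of motif composition, not substitution-model
  phylogenies.
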