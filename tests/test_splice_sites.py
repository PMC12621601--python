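"""Classification, windows, PWMs, logos, branch points and summaries."""

import numpy as np
import pytest

from _oracles import regex_branchpoints
from conftest import random_dna
from diplosplice import (
    BranchPointConfig,
    GenomeSequence,
    IntronRecord,
    branchpoint_fraction,
    build_pwm,
    classify_intron,
    collect_windows,
    dinucleotide_spectrum,
    extract_windows,
    length_stats,
    logo_matrix,
    ppt_composition,
    reverse_complement,
    scan_branchpoint,
)
from diplosplice.splice_sites import WindowSkip


class TestClassify:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GTAAGTCCCCCTCAG", "canonical"),
            ("GC" + "A" * 10 + "AG", "noncanonical"),
            ("CT" + "A" * 10 + "CG", "noncanonical"),
            ("GTAG", "canonical"),
        ],
    )
    def test_terminal_dinucleotide_rule(self, seq, expected):
        assert classify_intron(seq) == expected

    def test_too_short(self):
        with pytest.raises(ValueError):
            classify_intron("GTA")

    def test_partition_is_exact(self, rng):
        seqs = [random_dna(rng, int(rng.integers(4, 50))) for _ in range(500)]
        classes = [classify_intron(s) for s in seqs]
        frac_canonical = classes.count("canonical") / len(classes)
        frac_noncanonical = classes.count("noncanonical") / len(classes)
        assert frac_canonical + frac_noncanonical == 1.0


class TestDinucleotideSpectrum:
    def test_counts_and_fractions(self):
        genome = GenomeSequence({
            "c1": "GT" + "A" * 20 + "AG",
            "c2": "CT" + "A" * 20 + "CG",
        })
        introns = [
            IntronRecord("c1", 0, 24, "+"),
            IntronRecord("c1", 0, 24, "+"),
            IntronRecord("c2", 0, 24, "+"),
        ]
        table = dinucleotide_spectrum(introns, genome)
        rows = {(r.dinuc5, r.dinuc3): r.fraction for r in table.itertuples()}
        assert rows == {("GT", "AG"): pytest.approx(2 / 3),
                        ("CT", "CG"): pytest.approx(1 / 3)}
        assert table["fraction"].sum() == pytest.approx(1.0)

    def test_minus_strand_counted_in_transcript_orientation(self):
        plus_interval = "GT" + "C" * 20 + "AG"
        genome = GenomeSequence({
            "p": plus_interval, "m": reverse_complement(plus_interval),
        })
        plus = IntronRecord("p", 0, 24, "+")
        minus = IntronRecord("m", 0, 24, "-")
        t1 = dinucleotide_spectrum([plus], genome)
        t2 = dinucleotide_spectrum([minus], genome)
        assert t1.equals(t2)

    def test_empty_set(self):
        genome = GenomeSequence({"c": "ACGT"})
        assert dinucleotide_spectrum([], genome).empty


class TestExtractWindows:
    def layout_genome(self):
        # 200 nt contig; intron at [100, 150)
        rng = np.random.default_rng(7)
        seq = random_dna(rng, 200)
        return GenomeSequence({"c": seq}), seq

    def test_plus_strand_coordinates(self):
        genome, seq = self.layout_genome()
        rec = IntronRecord("c", 100, 150, "+")
        w = extract_windows(rec, genome, "logo")
        assert w.donor == seq[97:106]
        assert w.acceptor == seq[130:153]
        w9 = extract_windows(rec, genome, "phylo")
        assert w9.donor == seq[97:109]

    def test_minus_strand_is_mirror(self):
        genome, seq = self.layout_genome()
        mirrored = GenomeSequence({"c": reverse_complement(seq)})
        plus = extract_windows(IntronRecord("c", 100, 150, "+"), genome, "logo")
        minus = extract_windows(IntronRecord("c", 50, 100, "-"), mirrored, "logo")
        assert minus.donor == plus.donor
        assert minus.acceptor == plus.acceptor

    def test_short_intron_and_edges_are_skipped_with_tally(self):
        genome, _ = self.layout_genome()
        short = IntronRecord("c", 100, 110, "+")  # too short for 20-nt acceptor
        with pytest.raises(WindowSkip):
            extract_windows(short, genome, "logo")
        edge = IntronRecord("c", 1, 40, "+")  # no room for 3 exonic nt
        windows, tally = collect_windows([short, edge], genome, "logo")
        assert windows == []
        assert tally == {"short_intron": 1, "contig_edge": 1, "ambiguous": 0}

    def test_ambiguous_window_skipped(self):
        seq = "A" * 97 + "NNN" + "A" * 100
        genome = GenomeSequence({"c": seq})
        _, tally = collect_windows([IntronRecord("c", 100, 150, "+")], genome)
        assert tally["ambiguous"] == 1


class TestBuildPwm:
    def test_one_hot_and_mixed_columns(self):
        pwm = build_pwm(["GT", "GT"])
        np.testing.assert_allclose(pwm.matrix[:, 0], [0, 0, 1, 0])
        np.testing.assert_allclose(pwm.matrix[:, 1], [0, 0, 0, 1])
        mixed = build_pwm(["GA", "GC"])
        np.testing.assert_allclose(mixed.matrix[:, 1], [0.5, 0.5, 0, 0])

    def test_pseudocount_formula(self):
        pwm = build_pwm(["A"], pseudocount=1)
        np.testing.assert_allclose(pwm.matrix[:, 0], [2 / 5, 1 / 5, 1 / 5, 1 / 5])

    def test_errors(self):
        with pytest.raises(ValueError):
            build_pwm([])
        with pytest.raises(ValueError):
            build_pwm(["AC", "A"])
        with pytest.raises(ValueError):
            build_pwm(["AN"])

    def test_columns_sum_to_one_and_orientation_consistency(self, rng):
        seqs = [random_dna(rng, 12) for _ in range(50)]
        pwm = build_pwm(seqs)
        np.testing.assert_allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-9)
        # PWM of reverse-complemented windows is the reversed, base-swapped PWM
        rc = build_pwm([reverse_complement(s) for s in seqs])
        np.testing.assert_allclose(rc.matrix, pwm.matrix[::-1, ::-1])


class TestLogoMatrix:
    @pytest.mark.parametrize(
        "column,expected_ic",
        [
            ([0.25, 0.25, 0.25, 0.25], 0.0),
            ([1.0, 0.0, 0.0, 0.0], 2.0),
            ([0.5, 0.5, 0.0, 0.0], 1.0),
        ],
    )
    def test_information_content(self, column, expected_ic):
        from diplosplice.splice_sites import PWM

        pwm = PWM(np.array(column).reshape(4, 1), n_sequences=4)
        df = logo_matrix(pwm)
        assert df["ic"].iloc[0] == pytest.approx(expected_ic)
        heights = df[list("ACGT")].iloc[0].to_numpy()
        np.testing.assert_allclose(heights, np.array(column) * expected_ic)


class TestScanBranchpoint:
    def test_hit_inside_window(self):
        # 60-nt intron, CTAAC with last base 20 nt upstream of the 3' end
        L = 60
        s = L - 20 - 4  # last base index i has L - i = 20
        seq = "A" * s + "CTAAC" + "A" * (L - s - 5)
        assert scan_branchpoint(seq) == [s]

    def test_hit_too_close_to_end(self):
        L = 60
        s = L - 3 - 4  # last base 3 nt from the end: outside window
        seq = "G" * s + "CTAAC" + "G" * (L - s - 5)
        assert scan_branchpoint(seq) == []

    @pytest.mark.parametrize("pentamer,matches", [("CTGAC", True), ("CTGGC", False)])
    def test_iupac_r_position_and_required_a(self, pentamer, matches):
        # YTRAY: position 3 is R (A/G), position 4 must be A, position 5 is Y
        seq = "G" * 30 + pentamer + "G" * 25
        assert bool(scan_branchpoint(seq)) == matches

    def test_agrees_with_regex_oracle(self, rng):
        for _ in range(1000):
            L = int(rng.integers(10, 200))
            seq = random_dna(rng, L)
            assert scan_branchpoint(seq) == regex_branchpoints(seq), seq

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            BranchPointConfig(min_upstream=50, max_upstream=5)
        with pytest.raises(ValueError):
            BranchPointConfig(motif="YTZAY")


class TestBranchpointFraction:
    def test_counting(self):
        hit = "A" * 30 + "CTAAC" + "A" * 25
        miss = "A" * 60
        frac, n = branchpoint_fraction([hit, hit, miss, miss])
        assert (frac, n) == (0.5, 4)
        assert branchpoint_fraction([miss])[0] == 0.0

    def test_empty_set(self):
        with pytest.raises(ValueError):
            branchpoint_fraction([])


class TestLengthStats:
    def test_median_definitions(self):
        recs = [IntronRecord("c", 0, n, "+") for n in (37, 91, 41)]
        assert length_stats(recs)["median"] == 41
        two = [IntronRecord("c", 0, n, "+") for n in (10, 20)]
        assert length_stats(two)["median"] == 15

    def test_lognormal_median_recovery(self, rng):
        """Sample median within 5% of exp(mu) for a log-normal length model."""
        from diplosplice.synthetic_data import SpeciesSpec, _sample_length
        import math

        spec = SpeciesSpec("x", length_log_mu=math.log(60), length_log_sigma=0.45)
        lengths = [_sample_length(spec, rng) for _ in range(10_000)]
        assert abs(np.median(lengths) - 60) / 60 < 0.05

    def test_empty(self):
        with pytest.raises(ValueError):
            length_stats([])


class TestPptComposition:
    def test_all_c_tract(self):
        windows = ["C" * 20 + "CAG"] * 5
        df = ppt_composition(windows)
        assert df.shape == (20, 5)
        np.testing.assert_allclose(df["C"], 1.0)
        assert list(df["position"]) == list(range(-20, 0))

    def test_recovers_generator_composition(self, rng):
        """P(A) = 0.4 in the tract is recovered within 3 binomial SE."""
        p_a = 0.4
        bases = np.array(list("ACGT"))
        probs = [p_a, 0.3, 0.1, 0.2]
        windows = [
            "".join(bases[rng.choice(4, size=20, p=probs)]) + "CAG"
            for _ in range(5000)
        ]
        df = ppt_composition(windows)
        se = np.sqrt(p_a * (1 - p_a) / 5000)
        assert (np.abs(df["A"] - p_a) < 3 * se).all()

    def test_empty(self):
        with pytest.raises(ValueError):
            ppt_composition([])
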