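"""Conserved elements, exact PWM p-values, window identity and homology."""

import itertools

import numpy as np
import pytest

from paracis import conserved, synth
from paracis.conserved import PWM, ConservedElement
from paracis.msa import MultipleAlignment


class TestColumnIdentity:
    def test_nine_of_ten_matching_rows(self):
        rows = tuple((f"p{i}", "A") for i in range(9)) + (("p9", "C"),)
        profile = conserved.column_identity(MultipleAlignment(rows))
        assert profile.frequency[0] == pytest.approx(0.9)
        assert profile.modal[0] == "A"

    def test_gap_counts_in_denominator_but_never_wins(self):
        rows = tuple((f"p{i}", "A") for i in range(9)) + (("p9", "-"),)
        profile = conserved.column_identity(MultipleAlignment(rows))
        assert profile.frequency[0] == pytest.approx(0.9)
        # even a majority of gaps cannot become the conserved character
        rows = (("p0", "A"),) + tuple((f"p{i}", "-") for i in range(1, 10))
        profile = conserved.column_identity(MultipleAlignment(rows))
        assert profile.modal[0] == "A"
        assert profile.frequency[0] == pytest.approx(0.1)

    def test_identical_column_scores_one(self):
        profile = conserved.column_identity(
            MultipleAlignment((("a", "G"), ("b", "G"), ("c", "G")))
        )
        assert profile.frequency[0] == 1.0


class TestConservedRuns:
    def run_profile(self, passing_lengths, gap=1):
        """Frequency vector with alternating passing runs and failing gaps."""
        freq = []
        for i, L in enumerate(passing_lengths):
            if i:
                freq.extend([0.5] * gap)
            freq.extend([0.95] * L)
        return conserved.ColumnIdentityProfile(
            modal=np.array(["A"] * len(freq)), frequency=np.array(freq)
        )

    def test_long_run_reported_once(self):
        runs = conserved.conserved_runs(self.run_profile([12]))
        assert runs == [ConservedElement(0, 12)]

    def test_nine_column_run_too_short(self):
        assert conserved.conserved_runs(self.run_profile([9])) == []

    def test_exactly_ten_columns_is_inclusive(self):
        assert conserved.conserved_runs(self.run_profile([10])) == [
            ConservedElement(0, 10)
        ]

    def test_multiple_runs_split_by_failing_columns(self):
        runs = conserved.conserved_runs(self.run_profile([10, 15]))
        assert runs == [ConservedElement(0, 10), ConservedElement(11, 26)]

    def test_planted_fully_conserved_element_recovered_exactly(self):
        cfg = synth.SimulationConfig(
            seed=13, n_paralogs=16, ancestor_length=600,
            substitution_rate=0.5, indel_rate=0.0,
        )
        fam = synth.generate_paralog_family(cfg)
        element = "ACGTTGCAACGGATTACGGATCCAGTTGCAACGGATTACG"  # 40 bp
        fam = synth.plant_conserved_element(fam, element, carriers=fam.names, rng=3)
        e = fam.planted_elements[0]
        profile = conserved.column_identity(fam.paralog_msa)
        runs = conserved.conserved_runs(profile)
        assert runs == [ConservedElement(*e.column_interval)]
        assert conserved.element_consensus(fam.paralog_msa, runs[0]) == element


class TestPwmScan:
    def test_dinucleotide_worked_example_p_is_one_sixteenth(self):
        pwm = PWM.from_counts("AC", np.array([[100, 0, 0, 0], [0, 100, 0, 0]]))
        hits = conserved.pwm_scan("AC", pwm, p_cutoff=1.0, both_strands=False)
        assert len(hits) == 1
        assert hits[0].p_value == pytest.approx(1 / 16)

    def test_p_value_non_increasing_in_score(self):
        pwm = PWM.from_counts(
            "m", np.array([[8, 1, 1, 0], [0, 6, 2, 2], [5, 5, 0, 0]])
        )
        grid, dist = conserved.score_distribution(pwm)
        tail = np.cumsum(dist[::-1])[::-1]
        assert np.all(np.diff(tail) <= 1e-12)

    @pytest.mark.parametrize("k", [2, 4, 6])
    def test_dp_null_distribution_matches_full_enumeration(self, rng, k):
        counts = rng.integers(0, 20, size=(k, 4))
        pwm = PWM.from_counts("m", counts)
        gran = 1e-3
        ints = np.round(pwm.log_odds / gran).astype(np.int64)
        # exhaustive 4^k enumeration with background probabilities
        enum = {}
        for kmer in itertools.product(range(4), repeat=k):
            s = int(sum(ints[i, b] for i, b in enumerate(kmer)))
            p = float(np.prod([pwm.background[b] for b in kmer]))
            enum[s] = enum.get(s, 0.0) + p
        grid, dist = conserved.score_distribution(pwm, gran)
        for s, p in enum.items():
            assert dist[s - grid[0]] == pytest.approx(p, rel=1e-9)
        # tail p-values agree too
        tail = np.cumsum(dist[::-1])[::-1]
        for s in enum:
            p_enum = sum(pp for ss, pp in enum.items() if ss >= s)
            assert tail[s - grid[0]] == pytest.approx(p_enum, rel=1e-9)

    def test_reverse_strand_hit_found_only_with_both_strands(self):
        pwm = PWM.from_counts(
            "m",
            np.array([[99, 0, 0, 0], [99, 0, 0, 0], [0, 0, 99, 0], [0, 99, 0, 0]]),
        )  # motif AAGC; reverse complement GCTT
        seq = "TTTTGCTTTTTT"
        assert conserved.pwm_scan(seq, pwm, both_strands=False) == []
        hits = conserved.pwm_scan(seq, pwm, both_strands=True)
        assert [(h.offset, h.strand) for h in hits] == [(4, "-")]

    def test_sequence_shorter_than_motif_gives_no_hits(self):
        pwm = PWM.from_counts("m", np.array([[9, 0, 0, 0]] * 5))
        assert conserved.pwm_scan("ACG", pwm) == []


class TestWindowIdentity:
    def pairwise(self, a, b):
        return MultipleAlignment((("a", a), ("b", b)))

    def test_identical_pair_is_100_everywhere_with_one_region(self):
        aln = self.pairwise("ACGT" * 50, "ACGT" * 50)
        pct, regions = conserved.window_identity(aln)
        assert np.all(pct == 100.0)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 200)

    def test_window_fraction_counts_mismatches(self):
        a = "A" * 100
        b = "A" * 80 + "C" * 20
        pct, _ = conserved.window_identity(self.pairwise(a, b), window=100)
        assert pct[0] == pytest.approx(80.0)

    def test_exactly_seventy_percent_not_highlighted(self):
        a = "A" * 200
        b = ("A" * 7 + "C" * 3) * 20  # 70% identity in every window
        pct, regions = conserved.window_identity(self.pairwise(a, b), window=100)
        assert np.allclose(pct, 70.0)
        assert regions == []

    def test_gaps_count_as_mismatches(self):
        a = "ACGT" * 25
        b = "-" * 100
        pct, _ = conserved.window_identity(self.pairwise(a, b), window=100)
        assert np.all(pct == 0.0)

    def test_short_alignment_uses_whole_length_window(self):
        with pytest.warns(UserWarning):
            pct, _ = conserved.window_identity(self.pairwise("ACGT", "ACGA"), window=100)
        assert np.allclose(pct, 75.0)

    def test_self_identity_is_always_100(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        pct, _ = conserved.window_identity(self.pairwise(seq, seq))
        assert np.all(pct == 100.0)


def mutate(seq, rate, rng):
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


class TestHomologySearch:
    def test_planted_direct_segment_detected(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=1000))
        segment = a[400:520]  # 120 bp
        decayed = mutate(segment, 0.35, rng)
        b = (
            "".join(rng.choice(list("ACGT"), size=300))
            + decayed
            + "".join(rng.choice(list("ACGT"), size=300))
        )
        regions = conserved.homology_search(a, b, min_len=100, min_identity=0.60)
        direct = [r for r in regions if r.strand == "+"]
        assert any(
            r.a_start < 460 < r.a_end and r.b_start < 360 < r.b_end for r in direct
        )

    def test_inverted_segment_needs_inverted_search(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=800))
        segment = conserved.reverse_complement(a[300:420])
        b = (
            "".join(rng.choice(list("ACGT"), size=200))
            + segment
            + "".join(rng.choice(list("ACGT"), size=200))
        )
        without = conserved.homology_search(a, b, search_inverted=False)
        with_inv = conserved.homology_search(a, b, search_inverted=True)
        assert not any(r.length >= 100 for r in without)
        inverted = [r for r in with_inv if r.strand == "-"]
        assert len(inverted) == 1
        assert inverted[0].identity >= 0.9
        # coordinates reported on b's original strand; a few bp of
        # chance-matching flank may attach to the planted segment
        assert inverted[0].b_start <= 200 and inverted[0].b_end >= 320
        assert inverted[0].length <= 130

    def test_unrelated_sequences_yield_nothing_at_threshold(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=1000))
        b = "".join(rng.choice(list("ACGT"), size=1000))
        regions = conserved.homology_search(a, b, min_len=100, min_identity=0.60)
        assert regions == []

    def test_search_is_symmetric_on_planted_truth(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=600))
        shared = a[200:330]
        b = "".join(rng.choice(list("ACGT"), size=150)) + shared + "".join(
            rng.choice(list("ACGT"), size=150)
        )
        ab = conserved.homology_search(a, b, search_inverted=False)
        ba = conserved.homology_search(b, a, search_inverted=False)
        assert len(ab) == len(ba) == 1
        assert (ab[0].a_start, ab[0].a_end) == (ba[0].b_start, ba[0].b_end)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            conserved.homology_search("", "ACGT")

    def test_short_threshold_variant_finds_shorter_segments(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=400))
        segment = a[100:140]  # 40 bp, too short at min_len=100
        b = "".join(rng.choice(list("ACGT"), size=100)) + segment + "".join(
            rng.choice(list("ACGT"), size=100)
        )
        assert conserved.homology_search(a, b, min_len=100) == []
        short = conserved.homology_search(a, b, min_len=35)
        assert any(r.length >= 35 for r in short)
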