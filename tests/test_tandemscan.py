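"""Self-alignment scanner and repeat callers, checked against brute force."""

import numpy as np
import pytest

from macrosat import seqsim, tandemscan
from macrosat._seq import random_dna, revcomp
from macrosat.tandemscan import self_matches


# --- independent oracle: full all-pairs substring comparison ----------------


def brute_force_self_matches(seq: str, k: int, min_segment: int):
    """Compare every position pair directly (no index); returns the same
    canonical (q_start, q_end, t_start, t_end, strand) tuples."""
    n = len(seq)
    subs = [seq[i : i + k] for i in range(n - k + 1)]

    def runs_from_pairs(pairs):
        by_diag = {}
        for i, j in pairs:
            by_diag.setdefault(j - i, []).append(i)
        out = []
        for d, starts in by_diag.items():
            starts.sort()
            s = prev = starts[0]
            for i in starts[1:]:
                if i > prev + 1:
                    out.append((s, d, prev + k - s))
                    s = i
                prev = i
            out.append((s, d, prev + k - s))
        return [(s, d, ln) for s, d, ln in out if ln >= min_segment]

    fwd_pairs = [
        (i, j)
        for i in range(len(subs))
        for j in range(i + 1, len(subs))
        if subs[i] == subs[j]
    ]
    result = {
        (s, s + ln, s + d, s + d + ln, "forward")
        for s, d, ln in runs_from_pairs(fwd_pairs)
    }

    rc = revcomp(seq)
    subs_rc = [rc[i : i + k] for i in range(n - k + 1)]
    rev_pairs = [
        (i, j)
        for i in range(len(subs))
        for j in range(len(subs_rc))
        if subs[i] == subs_rc[j]
    ]
    for s, d, ln in runs_from_pairs(rev_pairs):
        q = (s, s + ln)
        t = (n - (s + d) - ln, n - (s + d))
        lo, hi = sorted([q, t])
        result.add((lo[0], lo[1], hi[0], hi[1], "reverse"))
    return result


def as_tuples(segments):
    return {(s.q_start, s.q_end, s.t_start, s.t_end, s.strand) for s in segments}


class TestSelfMatches:
    def test_hand_enumerable_example(self):
        segs = self_matches("ACGTACGT", k=4, min_segment=4)
        fwd = [s for s in segs if s.strand == "forward"]
        assert [(s.q_start, s.q_end, s.t_start, s.t_end) for s in fwd] == [(0, 4, 4, 8)]

    def test_planted_palindrome_links_the_halves(self):
        rng = np.random.default_rng(0)
        s = random_dna(1000, rng)
        seq = s + revcomp(s)
        segs = self_matches(seq, k=15, min_segment=25)
        rev = [s for s in segs if s.strand == "reverse"]
        assert max(s.length for s in rev) >= 1000 - 15 + 1

    def test_random_sequence_has_no_off_diagonal_matches(self):
        rng = np.random.default_rng(1)
        assert self_matches(random_dna(10_000, rng), k=15, min_segment=25) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle_equivalence(self, seed):
        # random 2 kb with a planted duplication and a planted inversion so
        # the comparison is non-vacuous
        rng = np.random.default_rng(seed)
        s = list(random_dna(2000, rng))
        s[600:900] = s[100:400]  # direct repeat
        s[1500:1700] = list(revcomp("".join(s[1000:1200])))  # inverted repeat
        seq = "".join(s)
        assert as_tuples(self_matches(seq, k=13, min_segment=25)) == (
            brute_force_self_matches(seq, k=13, min_segment=25)
        )

    def test_strand_symmetry(self):
        """Reverse self-segments equal forward matches against the reverse
        complement, mapped back into sequence coordinates."""
        rng = np.random.default_rng(2)
        s = list(random_dna(1500, rng))
        s[1000:1200] = list(revcomp("".join(s[200:400])))
        seq = "".join(s)
        n = len(seq)
        rev = {
            (x.q_start, x.q_end, x.t_start, x.t_end)
            for x in self_matches(seq, k=13, min_segment=25)
            if x.strand == "reverse"
        }
        mapped = set()
        for q, t, ln in tandemscan.exact_match_runs(seq, revcomp(seq), 13, 25):
            a, b = (q, q + ln), (n - t - ln, n - t)
            lo, hi = sorted([a, b])
            mapped.add((lo[0], lo[1], hi[0], hi[1]))
        assert rev == mapped

    def test_k_validation(self):
        with pytest.raises(ValueError, match="k="):
            self_matches("ACGTACGTACGT", k=3)
        with pytest.raises(ValueError, match="length"):
            self_matches("ACGT", k=8)


class TestCallTandemArrays:
    def test_exact_five_copy_array(self):
        rng = np.random.default_rng(3)
        unit = random_dna(1000, rng)
        segs = self_matches(unit * 5, k=13, min_segment=25)
        calls = tandemscan.call_tandem_arrays(segs, min_span=4000, min_copies=3)
        assert len(calls) == 1
        call = calls[0]
        assert call.period_stats[1] == 1000
        assert round(call.copy_estimate) == 5

    def test_planted_array_recovery(self, planted_locus):
        genome, truth, spec = planted_locus
        segs = self_matches(genome)
        calls = tandemscan.call_tandem_arrays(segs)
        assert len(calls) == 1
        call = calls[0]
        assert abs(call.interval[0] - truth.array_interval[0]) <= 500
        assert abs(call.interval[1] - truth.array_interval[1]) <= 500
        lo, med, hi = call.period_stats
        assert 3300 <= lo <= med <= hi <= 6300
        assert round(call.copy_estimate) == 7

    def test_background_only_is_silent(self):
        genome = random_dna(200_000, np.random.default_rng(7))
        segs = self_matches(genome)
        assert [c for c in tandemscan.call_tandem_arrays(segs) if c.span >= 10_000] == []

    def test_empty_input_empty_output(self):
        assert tandemscan.call_tandem_arrays([]) == []


class TestCallInvertedRepeats:
    def test_planted_palindrome_recovered(self):
        ir, arms = seqsim.generate_inverted_repeat(2000, 500, seed=11)
        genome, _ = seqsim.plant_features(50_000, [(ir, 20_000)], seed=12)
        segs = self_matches(genome)
        calls = tandemscan.call_inverted_repeats(segs, min_arm=1000)
        assert len(calls) == 1
        call = calls[0]
        truth_left = (arms[0][0] + 20_000, arms[0][1] + 20_000)
        truth_right = (arms[1][0] + 20_000, arms[1][1] + 20_000)
        for got, want in ((call.left_arm, truth_left), (call.right_arm, truth_right)):
            assert abs(got[0] - want[0]) <= 25
            assert abs(got[1] - want[1]) <= 25
        assert abs(call.spacer - 500) <= 50

    def test_no_reverse_segments_empty(self):
        assert tandemscan.call_inverted_repeats([]) == []

    def test_direct_tandem_yields_no_inverted_calls(self):
        rng = np.random.default_rng(4)
        unit = random_dna(1000, rng)
        segs = self_matches(unit * 5, k=13, min_segment=25)
        assert tandemscan.call_inverted_repeats(segs, min_arm=100) == []


class TestSurvey:
    def test_only_windows_overlapping_planted_array_report_span(self):
        spec = seqsim.default_array_spec(seed=2)
        array, truth = seqsim.generate_array(spec)
        genome, _ = seqsim.plant_features(400_000, [(array, 150_000)], seed=21)
        rows = tandemscan.survey_chromosome(genome, window=100_000, step=50_000)
        for row in rows:
            overlap = min(row["window_end"], 150_000 + len(array)) - max(
                row["window_start"], 150_000
            )
            if overlap >= 0.5 * len(array):
                assert row["largest_span"] >= 10_000
            else:
                assert row["largest_span"] < 10_000

    def test_short_genome_single_row_with_warning(self):
        genome = random_dna(5_000, np.random.default_rng(5))
        rows = tandemscan.survey_chromosome(genome, window=100_000, step=50_000)
        assert len(rows) == 1
        assert rows[0]["window_end"] == 5_000

    def test_unique_genome_all_spans_zero(self):
        genome = random_dna(120_000, np.random.default_rng(6))
        rows = tandemscan.survey_chromosome(genome, window=60_000, step=30_000)
        assert all(r["largest_span"] == 0 for r in rows)


class TestIdempotence:
    def test_called_array_subsequence_redetects(self, planted_locus):
        genome, truth, spec = planted_locus
        call = tandemscan.call_tandem_arrays(self_matches(genome))[0]
        sub = genome[call.interval[0] : call.interval[1]]
        again = tandemscan.call_tandem_arrays(
            self_matches(sub), min_span=10_000, min_copies=3
        )
        assert len(again) == 1
        assert again[0].span >= 0.95 * call.span


def test_dotplot_shape_and_symmetry(planted_locus):
    genome, truth, spec = planted_locus
    sub = genome[80_000:90_000]
    segs = self_matches(sub)
    dp = tandemscan.build_dotplot(len(sub), segs, bin_size=500)
    assert dp.forward_counts.shape == (20, 20)
    assert (dp.forward_counts == dp.forward_counts.T).all()
    assert (dp.forward_counts >= 0).all()
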