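"""PWM construction, bits-suboptimal scanning, peak categorization and the
two-part motif spacing analysis."""

import numpy as np
import pandas as pd
import pytest

from ctcf_repeatscape import dna
from ctcf_repeatscape.motif_scan import (
    PWM,
    build_pwm,
    categorize_peaks_by_motif,
    closest_downstream_spacings,
    motif_center,
    scan,
    spacing_analysis,
)


def brute_force_scan(seq: str, pwm: PWM, cutoff: float) -> list[tuple[int, str, float]]:
    """Independent reference scanner: score every window on both strands."""
    out = []
    L = pwm.length
    lp = np.log2(pwm.probs)
    best = np.log2(pwm.probs.max(axis=1)).sum()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if any(b not in "ACGT" for b in window):
            continue
        for strand in "+-":
            w = window if strand == "+" else "".join(comp[b] for b in reversed(window))
            score = sum(lp[j, "ACGT".index(b)] for j, b in enumerate(w)) - best
            if score >= cutoff:
                out.append((i, strand, score))
    return out


class TestBuildPwm:
    def test_single_sequence_no_pseudocount(self):
        pwm = build_pwm(["ACGT"])
        assert pwm.length == 4
        np.testing.assert_allclose(pwm.probs, np.eye(4))
        np.testing.assert_allclose(pwm.ic, 2.0)

    def test_uniform_column_zero_ic(self):
        pwm = build_pwm(["A", "C", "G", "T"])
        assert pwm.ic[0] == pytest.approx(0.0, abs=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGT", "ACG"])

    def test_recovers_generating_matrix_from_samples(self):
        rng = np.random.default_rng(17)
        probs = rng.dirichlet(np.ones(4) * 2, size=8)
        true = PWM(probs)
        samples = [
            dna.decode(
                np.array([rng.choice(4, p=probs[i]) for i in range(8)], dtype=np.uint8)
            )
            for _ in range(1000)
        ]
        est = build_pwm(samples, pseudocount=0.0)
        assert np.max(np.abs(est.probs - true.probs)) < 0.05


class TestScan:
    def test_consensus_is_perfect_match(self):
        pwm = build_pwm(["ACGTAC", "ACGTAC", "ACGTCC"], pseudocount=0.1)
        hits = scan("TT" + pwm.consensus + "TT", pwm, cutoff=-1e-6, both_strands=False)
        assert len(hits) == 1
        assert hits.iloc[0]["start"] == 2
        assert hits.iloc[0]["score"] == pytest.approx(0.0, abs=1e-9)

    def test_reverse_strand_hit_same_score(self):
        pwm = build_pwm(["ACGGTC"], pseudocount=0.25)
        fwd = "AA" + pwm.consensus + "AA"
        rev = dna.decode(dna.revcomp(dna.encode(fwd)))
        h_fwd = scan(fwd, pwm, cutoff=-0.5)
        h_rev = scan(rev, pwm, cutoff=-0.5)
        plus = h_fwd[h_fwd["strand"] == "+"].iloc[0]
        minus = h_rev[h_rev["strand"] == "-"].iloc[0]
        assert minus["score"] == pytest.approx(plus["score"])
        assert minus["start"] == len(rev) - plus["end"]

    def test_short_sequence_returns_empty(self):
        pwm = build_pwm(["ACGTAC"], pseudocount=0.25)
        assert scan("ACG", pwm, cutoff=-10).empty

    def test_non_acgt_windows_skipped(self):
        pwm = build_pwm(["AAAA"], pseudocount=0.25)
        hits = scan("AAANAAAA", pwm, cutoff=-0.1)
        assert (hits["start"] >= 4).all()

    def test_matches_brute_force_on_random_sequence(self):
        """Exhaustive oracle equivalence: 5 kb random sequence, 6 bp PWM."""
        rng = np.random.default_rng(3)
        seq = dna.decode(dna.random_seq(5000, rng))
        pwm = PWM(rng.dirichlet(np.ones(4), size=6))
        cutoff = -6.0
        expected = brute_force_scan(seq, pwm, cutoff)
        got = scan(seq, pwm, cutoff)
        assert len(got) == len(expected)
        got_sorted = sorted(zip(got["start"], got["strand"], got["score"]))
        for (s1, st1, sc1), (s2, st2, sc2) in zip(got_sorted, sorted(expected)):
            assert (s1, st1) == (s2, st2)
            assert sc1 == pytest.approx(sc2, abs=1e-9)

    def test_positive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            scan("ACGT", build_pwm(["AC"], pseudocount=0.1), cutoff=0.5)

    def test_bed6_score_convention(self):
        from ctcf_repeatscape.motif_scan import hits_to_bed6

        pwm = build_pwm(["ACGTAC", "ACGTCC"], pseudocount=0.1)
        hits = scan("TT" + pwm.consensus + "TT", pwm, cutoff=-3.0, both_strands=False)
        bed = hits_to_bed6(hits)
        assert list(bed.columns) == ["chrom", "start", "end", "name", "score", "strand"]
        # a perfect match scores 0; suboptimal hits store round(-100 * bits)
        assert bed["score"].iloc[0] == round(-100 * hits["score"].iloc[0])
        assert (bed["score"] >= 0).all()


class TestMotifCenter:
    def test_strand_symmetric_for_even_length(self):
        # a 20 bp motif at [100, 120): center 110 on '+', 109 on '-'
        assert motif_center(100, 20, "+") == 110
        assert motif_center(100, 20, "-") == 109
        # odd length is strand-independent
        assert motif_center(100, 9, "+") == motif_center(100, 9, "-") == 104


def _hits(starts, strands, length):
    starts = np.asarray(starts)
    return pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + length, "strand": strands,
         "score": 0.0}
    )


class TestSpacing:
    def test_downstream_only_and_strand_resolved(self):
        m1 = _hits([100], ["+"], 20)
        # M2 center must be > M1 center on '+': one upstream, one downstream
        m2 = _hits([100 - 30, 100 + 10 + 20 - 4], ["+", "+"], 9)
        d = closest_downstream_spacings(m1, m2, 20, 9, (12, 42))
        assert d.tolist() == [20]

    def test_minus_strand_downstream_is_leftward(self):
        m1 = _hits([100], ["-"], 20)
        # '-' M1 center = 109; a same-strand M2 with center at 109 - 21
        m2_start = 109 - 21 - 4
        m2 = _hits([m2_start, 200], ["-", "-"], 9)
        d = closest_downstream_spacings(m1, m2, 20, 9, (12, 42))
        assert d.tolist() == [21]

    def test_no_m2_gives_all_zero_histogram(self):
        m1 = _hits([10, 200, 500], ["+", "+", "-"], 20)
        m2 = _hits([], [], 9)
        hist = spacing_analysis(m1, m2, 20, 9, sequence_length=1000, reps=5, seed=0)
        assert hist.counts.sum() == 0

    def test_planted_spacings_recovered_as_modes(self, study):
        """Sites planted with M2 at 20 and 21 bp in equal proportion give the
        two modal spacing bins 20 and 21."""
        from ctcf_repeatscape.cohort import M1_LENGTH, M2_LENGTH
        from ctcf_repeatscape.intervals import overlaps_any

        cohort, hits = study["cohort"], study["hits"]
        regions = cohort.bound_regions("human")
        m1 = hits["human"]["m1"]
        m1 = m1[
            overlaps_any(m1["start"].to_numpy(), m1["end"].to_numpy(),
                         regions["start"].to_numpy(), regions["end"].to_numpy())
        ]
        hist = spacing_analysis(
            m1, hits["human"]["m2"], M1_LENGTH, M2_LENGTH,
            cohort.genomes["human"].size, reps=25, seed=9,
        )
        assert hist.modes(2) == [20, 21]

    def test_uniform_m2_background_roughly_flat(self):
        rng = np.random.default_rng(8)
        L = 500_000
        m1 = _hits(np.sort(rng.integers(0, L - 20, 3000)), "+", 20)
        m2 = _hits(np.sort(rng.integers(0, L - 9, 3000)), "+", 9)
        hist = spacing_analysis(m1, m2, 20, 9, sequence_length=L, reps=30, seed=1)
        bg = hist.background
        assert bg.min() > 0
        assert bg.max() <= 2.0 * bg.mean()

    def test_bad_parameters(self):
        m1 = _hits([0], ["+"], 20)
        with pytest.raises(ValueError):
            spacing_analysis(m1, m1, 20, 9, 100, reps=0)
        with pytest.raises(ValueError):
            spacing_analysis(m1, m1, 20, 9, 100, window=(42, 12))


class TestCategorizePeaks:
    def _setup(self):
        peaks = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(200) * 1000, "end": np.arange(200) * 1000 + 400}
        )
        m1_starts, m2_starts = [], []
        for i in range(200):
            base = i * 1000 + 100
            if i < 180:  # 180 peaks carry an M1
                m1_starts.append(base)
            if i < 120:  # 120 of those also an M2 in the window
                spacing = 20 if i < 60 else 30
                m2_starts.append(base + 10 + spacing - 4)
        m1 = _hits(m1_starts, "+", 20)
        m2 = _hits(m2_starts, "+", 9)
        return peaks, m1, m2

    def test_nested_counts_on_planted_composition(self):
        peaks, m1, m2 = self._setup()
        counts = categorize_peaks_by_motif(peaks, m1, m2, 20, 9)
        assert counts == {
            "total": 200,
            "with_m1": 180,
            "with_m1_m2_window": 120,
            "with_m1_m2_preferred": 60,
        }

    def test_nesting_invariant_on_random_hits(self):
        rng = np.random.default_rng(4)
        peaks = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(50) * 500, "end": np.arange(50) * 500 + 300}
        )
        m1 = _hits(np.sort(rng.integers(0, 25_000, 60)), rng.choice(["+", "-"], 60), 20)
        m2 = _hits(np.sort(rng.integers(0, 25_000, 80)), rng.choice(["+", "-"], 80), 9)
        c = categorize_peaks_by_motif(peaks, m1, m2, 20, 9)
        assert c["total"] >= c["with_m1"] >= c["with_m1_m2_window"] >= c["with_m1_m2_preferred"]

    def test_peak_without_hits_counts_only_in_total(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [400]})
        c = categorize_peaks_by_motif(peaks, _hits([], [], 20), _hits([], [], 9), 20, 9)
        assert c == {"total": 1, "with_m1": 0, "with_m1_m2_window": 0, "with_m1_m2_preferred": 0}
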