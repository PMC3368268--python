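"""Motif-word extraction, nocc normalization, hierarchy, lineage-specific calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctcf_repeatscape import dna
from ctcf_repeatscape.cohort import (
    INFORMATIVE_POSITIONS,
    M1_LENGTH,
    SimulationConfig,
    simulate_cohort,
)
from ctcf_repeatscape.motif_scan import PWM, build_pwm, scan
from ctcf_repeatscape.motif_words import (
    WordTable,
    extract_words,
    hierarchy,
    informative_positions,
    lineage_specific_words,
    word_at_hit,
)


class TestInformativePositions:
    def test_all_positions_when_k_equals_length(self):
        pwm = build_pwm(["ACGTAA", "ACGTAC"], pseudocount=0.1)
        pos, frac = informative_positions(pwm, 6)
        assert pos.tolist() == [0, 1, 2, 3, 4, 5]
        assert frac == pytest.approx(1.0)

    def test_nonuniform_columns_selected(self):
        probs = np.full((20, 4), 0.25)
        informative = [0, 2, 3, 5, 7, 8, 9, 11, 12, 14, 15, 16, 17, 19]
        for p in informative:
            probs[p] = [0.9, 0.05, 0.03, 0.02]
        pos, frac = informative_positions(PWM(probs), 14)
        assert pos.tolist() == informative
        assert frac == pytest.approx(1.0)

    def test_top_k_matches_exhaustive_sort(self):
        rng = np.random.default_rng(2)
        pwm = PWM(rng.dirichlet(np.ones(4) * 0.7, size=12))
        pos, _ = informative_positions(pwm, 5)
        expected = np.sort(np.argsort(-pwm.ic, kind="stable")[:5])
        np.testing.assert_array_equal(pos, expected)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            informative_positions(build_pwm(["ACGT"]), 5)

    def test_generator_informative_positions_recovered(self, study):
        """The 14 highest-IC columns of the estimated matrix are the planted
        informative positions and capture >95% of the information content."""
        np.testing.assert_array_equal(study["positions"], INFORMATIVE_POSITIONS)
        assert study["captured"] > 0.95


class TestWordExtraction:
    def test_word_read_in_motif_orientation(self):
        genome = dna.encode("AAACGTACGTACGTACGTACGTAAA")
        positions = np.array([0, 2, 4])
        w_plus = word_at_hit(genome, 3, "+", positions, 6)
        assert w_plus == "CTC"  # window CGTACG at 3..9, positions 0,2,4
        # a '-' hit reads the reverse complement (CGTACG is its own revcomp)
        assert word_at_hit(genome, 3, "-", positions, 6) == "CTC"

    def test_same_site_both_strands_same_word_for_palindrome_positions(self):
        # plant a word and its reverse complement; extraction re-orients '-' hits
        word = "ACGGTC"
        genome = dna.encode("TT" + word + "TT")
        positions = np.arange(6)
        assert word_at_hit(genome, 2, "+", positions, 6) == word
        rc_genome = dna.revcomp(genome)
        assert word_at_hit(rc_genome, 2, "-", positions, 6) == word

    def test_non_acgt_hit_excluded(self):
        genome = dna.encode("AANCGT")
        assert word_at_hit(genome, 0, "+", np.arange(4), 4) is None

    def test_planted_words_recovered_from_cohort(self):
        """A cohort seeded from a small word pool, evolved without motif
        turnover, yields exactly the planted bound words (plus at most
        singleton background matches)."""
        config = SimulationConfig(
            seed=42,
            genome_length=400_000,
            n_sites=160,
            n_words=12,
            purifying_factor=0.0,
            peak_halfwidth=30,
            expansions=(),
            n_insulated_pairs=0,
            n_control_pairs=0,
            barrier_fraction=0.0,
            n_background_domains=0,
        )
        cohort = simulate_cohort(config)
        hits = {
            sp: scan(cohort.genomes[sp], cohort.m1_pwm, -10.0) for sp in cohort.species
        }
        table = extract_words(
            hits,
            cohort.genomes,
            INFORMATIVE_POSITIONS,
            {sp: cohort.bound_regions(sp) for sp in cohort.species},
            M1_LENGTH,
        )
        sites = cohort.truth.sites
        seeded = set(sites["word"])  # words realized at bound sites
        recovered = set(table.df.index)
        assert seeded <= recovered
        occ_cols = [f"occ_{sp}" for sp in cohort.species]
        extras = recovered - seeded
        for w in extras:  # background PWM matches can only be singletons
            assert table.df.loc[w, occ_cols].sum() <= 1
            assert w not in cohort.word_pool

    def test_nocc_identity_and_occ_bounded_by_genome(self, study):
        table = study["table"]
        for sp in table.species:
            occ = table.df[f"occ_{sp}"]
            recomputed = occ / table.factors[sp]
            pd.testing.assert_series_equal(
                table.df[f"nocc_{sp}"], recomputed, check_names=False
            )
            assert (occ <= table.df[f"genome_{sp}"]).all()


def make_table(occ: dict[str, list[int]], factors: dict[str, float]) -> WordTable:
    words = [f"w{i}" for i in range(len(next(iter(occ.values()))))]
    df = pd.DataFrame(index=pd.Index(words, name="word"))
    for sp, counts in occ.items():
        df[f"occ_{sp}"] = counts
        df[f"genome_{sp}"] = np.asarray(counts) * 10 + 1
        df[f"nocc_{sp}"] = df[f"occ_{sp}"] / factors[sp]
    return WordTable(df=df, factors=factors, species=tuple(occ))


class TestLineageSpecificWords:
    def test_threshold_examples(self):
        table = make_table(
            {"mouse": [9, 8, 20], "dog": [1, 0, 5]},
            {"mouse": 1.0, "dog": 1.0},
        )
        out = lineage_specific_words(table, ("mouse",), ("dog",))
        # ln(9/1)=2.197>2 and 9>8 -> in; 8 fails nocc>8; ln(20/5)=1.386 fails
        assert out == {"w0"}

    def test_absent_elsewhere_counts_as_specific(self):
        table = make_table({"mouse": [12], "dog": [0]}, {"mouse": 1.0, "dog": 1.0})
        assert lineage_specific_words(table, ("mouse",), ("dog",)) == {"w0"}

    def test_group_nocc_pools_occurrences_and_factors(self):
        table = make_table(
            {"mouse": [6], "rat": [6], "dog": [1], "human": [0]},
            {"mouse": 0.5, "rat": 0.5, "dog": 1.0, "human": 1.0},
        )
        # group S nocc = 12/1.0 = 12 > 8; nocc(R) = 1/2.0 = 0.5; ln(24) > 2
        assert lineage_specific_words(table, ("mouse", "rat"), ("dog", "human")) == {"w0"}

    def test_overlapping_groups_rejected(self):
        table = make_table({"mouse": [1], "dog": [1]}, {"mouse": 1.0, "dog": 1.0})
        with pytest.raises(ValueError):
            lineage_specific_words(table, ("mouse",), ("mouse", "dog"))

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(9)
        species = ("human", "macaque", "mouse", "rat", "dog", "opossum")
        occ = {sp: rng.integers(0, 30, 80).tolist() for sp in species}
        factors = {sp: float(rng.uniform(0.3, 2.0)) for sp in species}
        table = make_table(occ, factors)
        S, R = ("mouse", "rat"), ("human", "macaque", "dog", "opossum")
        expected = set()
        for i, w in enumerate(table.df.index):
            ns = sum(occ[sp][i] for sp in S) / sum(factors[sp] for sp in S)
            nr = sum(occ[sp][i] for sp in R) / sum(factors[sp] for sp in R)
            if ns > 8 and (nr == 0 or np.log(ns / nr) > 2):
                expected.add(w)
        assert lineage_specific_words(table, S, R) == expected


class TestHierarchy:
    def _event_words(self, words, rng, n=300):
        chosen = rng.choice(words, size=n)
        return pd.DataFrame(
            {
                "word": chosen,
                "score": rng.normal(10, 1, n),
                "code": rng.choice(["11111", "10000"], size=n),
            }
        )

    def test_identical_usage_gives_perfect_correlation(self):
        rng = np.random.default_rng(0)
        occ = rng.integers(5, 50, 40).tolist()
        table = make_table({"human": occ, "mouse": occ}, {"human": 1.0, "mouse": 1.0})
        hier = hierarchy(table, "human", self._event_words(table.df.index.to_numpy(), rng), n_bins=5)
        assert hier.correlations.loc["human", "mouse"] == pytest.approx(1.0)

    def test_permuted_usage_uncorrelated(self):
        rng = np.random.default_rng(1)
        occ_h = rng.integers(5, 200, 400)
        occ_m = rng.permutation(occ_h)
        table = make_table(
            {"human": occ_h.tolist(), "mouse": occ_m.tolist()},
            {"human": 1.0, "mouse": 1.0},
        )
        hier = hierarchy(table, "human", self._event_words(table.df.index.to_numpy(), rng), n_bins=10)
        assert abs(hier.correlations.loc["human", "mouse"]) < 0.2

    def test_five_way_fraction_decreases_across_bins(self, study):
        """Planted hierarchy: frequent words are more often conserved, so the
        five-way fraction falls from high-usage to low-usage bins."""
        from ctcf_repeatscape.pipeline import annotate_event_words

        cohort, table = study["cohort"], study["table"]
        ev = annotate_event_words(
            cohort.events["human"],
            study["hits"]["human"]["m1"],
            cohort.genomes["human"],
            study["positions"],
            study["codes"],
        )
        hier = hierarchy(table, "human", ev, min_bound=5, n_bins=10)
        frac = hier.bins.dropna(subset=["five_way_fraction"])
        rho = stats.spearmanr(frac["bin"], frac["five_way_fraction"]).statistic
        assert rho < -0.5

    def test_fewer_words_than_bins_reduces_bin_count(self):
        rng = np.random.default_rng(3)
        occ = [10, 20, 30]
        table = make_table({"human": occ, "mouse": occ}, {"human": 1.0, "mouse": 1.0})
        hier = hierarchy(table, "human", self._event_words(table.df.index.to_numpy(), rng), n_bins=25)
        assert len(hier.bins) == 3
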