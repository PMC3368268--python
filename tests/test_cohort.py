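"""Synthetic cohort generator: determinism, neutral divergence, purifying
selection, repeat expansion statistics, coordinate truth."""

import numpy as np
import pandas as pd
import pytest

from ctcf_repeatscape import dna
from ctcf_repeatscape.cohort import (
    CohortSizingError,
    M1_LENGTH,
    SimulationConfig,
    SpeciesTree,
    aligned_windows,
    default_tree,
    expand_repeat_family,
    simulate_cohort,
)


def neutral_config(**kw):
    base = dict(
        genome_length=100_000,
        n_sites=0,
        expansions=(),
        n_insulated_pairs=0,
        n_control_pairs=0,
        barrier_fraction=0.0,
        n_background_domains=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestTree:
    def test_default_tree_valid(self):
        tree = default_tree()
        assert tree.root == "root"
        assert set(tree.species) == {"human", "macaque", "mouse", "rat", "dog", "opossum"}
        # path human-macaque = two 0.04 branches
        assert tree.path_length("human", "macaque") == pytest.approx(0.08)
        assert tree.path_length("mouse", "rat") == pytest.approx(0.12)

    def test_two_roots_rejected(self):
        with pytest.raises(ValueError):
            SpeciesTree(
                species=("a", "b"),
                parents={"a": None, "b": None},
                branch_lengths={"a": 0.1, "b": 0.1},
            )


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        from ctcf_repeatscape.cohort import default_expansions, scaled_expansions

        cfg = SimulationConfig(
            seed=5, genome_length=400_000, n_sites=100,
            expansions=scaled_expansions(default_expansions(), 0.08),
            n_insulated_pairs=10, n_control_pairs=10,
        )
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for sp in a.species:
            np.testing.assert_array_equal(a.genomes[sp], b.genomes[sp])
            pd.testing.assert_frame_equal(a.events[sp], b.events[sp])
        pd.testing.assert_frame_equal(a.block_map.df, b.block_map.df)
        pd.testing.assert_frame_equal(a.truth.sites, b.truth.sites)
        pd.testing.assert_frame_equal(a.expression, b.expression)

    def test_different_seed_differs(self):
        a = simulate_cohort(neutral_config(seed=1))
        b = simulate_cohort(neutral_config(seed=2))
        assert not np.array_equal(a.genomes["human"], b.genomes["human"])

    def test_seed_mandatory(self):
        with pytest.raises((TypeError, ValueError)):
            SimulationConfig(seed=None)


class TestEvolution:
    def test_purifying_factor_zero_freezes_motif_columns(self):
        cfg = neutral_config(seed=9, n_sites=60, purifying_factor=0.0, genome_length=400_000)
        cohort = simulate_cohort(cfg)
        sites = cohort.truth.sites
        conserved = sites[sites["conserved"]]
        assert len(conserved) > 5
        for row in conserved.itertuples(index=False):
            # M1 occupies the 5' 20 bp of the footprint in motif orientation
            if row.strand == "+":
                sl = slice(row.pos_human, row.pos_human + M1_LENGTH)
            else:
                sl = slice(row.pos_human + row.footprint - M1_LENGTH, row.pos_human + row.footprint)
            ref = cohort.genomes["human"][sl]
            for sp in cohort.species:
                pos = getattr(row, f"pos_{sp}")
                if row.strand == "+":
                    other = cohort.genomes[sp][pos : pos + M1_LENGTH]
                else:
                    other = cohort.genomes[sp][pos + row.footprint - M1_LENGTH : pos + row.footprint]
                np.testing.assert_array_equal(ref, other)

    def test_neutral_divergence_matches_branch_lengths(self):
        """Jukes-Cantor-corrected leaf-leaf divergence equals the sum of
        connecting branch lengths within 3 standard errors at 100 kb."""
        cohort = simulate_cohort(neutral_config(seed=3))
        tree = cohort.config.tree
        for a, b in (("human", "macaque"), ("mouse", "rat"), ("human", "dog")):
            p_hat = float(np.mean(cohort.genomes[a] != cohort.genomes[b]))
            d_hat = -0.75 * np.log(1 - 4 * p_hat / 3)
            expected = tree.path_length(a, b)
            n = cohort.genomes[a].size
            se_p = np.sqrt(p_hat * (1 - p_hat) / n)
            se_d = se_p / (1 - 4 * p_hat / 3)
            assert abs(d_hat - expected) < 3 * se_d

    def test_purifying_raises_unchanged_base_frequency(self, small_cohort):
        """Motif columns of conserved sites change less than flanking columns."""
        sites = small_cohort.truth.sites
        conserved = sites[sites["conserved"] & (sites["strand"] == "+")]
        centers = conserved["pos_human"].to_numpy() + 10
        aln = aligned_windows(
            small_cohort, "human", centers, np.array(["+"] * len(conserved)), 40
        )
        anchor = aln[:, 0, :]
        others = aln[:, 1:, :]
        valid = (others != dna.INVALID) & (anchor[:, None, :] != dna.INVALID)
        unchanged = ((others == anchor[:, None, :]) & valid).sum(axis=(0, 1)) / valid.sum(axis=(0, 1))
        motif = unchanged[30:50].mean()  # the M1 window around the center
        flank = np.r_[unchanged[:20], unchanged[60:]].mean()
        assert motif > flank + 0.05


class TestSizingErrors:
    def test_too_many_sites_rejected(self):
        with pytest.raises(CohortSizingError):
            simulate_cohort(neutral_config(seed=1, genome_length=20_000, n_sites=100))

    def test_insufficient_gene_anchors_rejected(self):
        cfg = SimulationConfig(
            seed=1, genome_length=100_000, n_sites=20, expansions=(),
            n_insulated_pairs=500, n_control_pairs=0,
            barrier_fraction=0.0, n_background_domains=0,
        )
        with pytest.raises(CohortSizingError):
            simulate_cohort(cfg)


class TestExpandRepeatFamily:
    def test_zero_copies_leaves_genome_unchanged(self):
        rng = np.random.default_rng(0)
        genome = dna.random_seq(10_000, rng)
        out, copies = expand_repeat_family(genome, "ACGT" * 20, 0, 0.1, seed=1)
        np.testing.assert_array_equal(out, genome)
        assert copies.empty

    def test_zero_divergence_copies_equal_consensus(self):
        rng = np.random.default_rng(1)
        genome = dna.random_seq(50_000, rng)
        consensus = "ACGTTGCA" * 10
        out, copies = expand_repeat_family(genome, consensus, 20, 0.0, seed=2)
        assert out.size == genome.size + 20 * len(consensus)
        for row in copies.itertuples(index=False):
            assert dna.decode(out[row.start : row.end]) == consensus
            assert row.substitutions == 0

    def test_mean_divergence_matches_binomial_expectation(self):
        rng = np.random.default_rng(2)
        genome = dna.random_seq(500_000, rng)
        d, n, L = 0.08, 200, 190
        _, copies = expand_repeat_family(genome, dna.decode(dna.random_seq(L, rng)), n, d, seed=3)
        frac = (copies["substitutions"] / L).mean()
        se = np.sqrt(d * (1 - d) / (n * L))
        assert abs(frac - d) < 3 * se

    def test_insufficient_space_raises(self):
        genome = dna.random_seq(2_000, np.random.default_rng(0))
        with pytest.raises(CohortSizingError):
            expand_repeat_family(genome, "A" * 500, 50, 0.0, seed=1, min_separation=500)


class TestTruthTables:
    def test_truth_coordinates_are_valid_and_words_match_genome(self, small_cohort):
        sites = small_cohort.truth.sites
        from ctcf_repeatscape.cohort import INFORMATIVE_POSITIONS

        cfg = small_cohort.config
        for row in sites.head(60).itertuples(index=False):
            g = small_cohort.genomes["human"]
            assert 0 <= row.pos_human < g.size - row.footprint
        # words were planted before evolution; verify on a purifying-free cohort
        frozen = simulate_cohort(
            SimulationConfig(
                seed=13, genome_length=300_000, n_sites=80, purifying_factor=0.0,
                expansions=(), n_insulated_pairs=0, n_control_pairs=0,
                barrier_fraction=0.0, n_background_domains=0,
            )
        )
        for row in frozen.truth.sites[frozen.truth.sites["conserved"]].itertuples(index=False):
            g = frozen.genomes["mouse"]
            if row.strand == "+":
                m1 = g[row.pos_mouse : row.pos_mouse + M1_LENGTH]
            else:
                m1 = dna.revcomp(g[row.pos_mouse + row.footprint - M1_LENGTH : row.pos_mouse + row.footprint])
            assert dna.decode(m1[INFORMATIVE_POSITIONS]) == row.word

    def test_repeat_truth_counts_substitutions_against_consensus(self, small_cohort):
        reps = small_cohort.repeats["mouse"]
        assert (reps["substitutions"] <= reps["consensus_length"]).all()
        assert (reps["end"] - reps["start"] == reps["consensus_length"]).all()

    def test_events_carry_scores_and_sorted_coordinates(self, small_cohort):
        for sp in small_cohort.species:
            ev = small_cohort.events[sp]
            assert (ev["start"].diff().dropna() >= 0).all()
            assert ev["score"].notna().all()
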