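"""Shared fixtures: the full-size study cohort (built once per session) and a
small cohort for cheap unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from ctcf_repeatscape.cohort import (
    M1_LENGTH,
    RepeatExpansionSpec,
    SimulationConfig,
    simulate_cohort,
)
from ctcf_repeatscape.motif_words import extract_words, informative_positions
from ctcf_repeatscape.ortho_sharing import sharing_codes
from ctcf_repeatscape.pipeline import estimate_pwms, scan_genomes

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    """Default-condition cohort (5 Mb x 6 species, 2,000 sites, 300-copy
    expansions) with the scan/share/word stages precomputed."""
    config = SimulationConfig(seed=STUDY_SEED)
    cohort = simulate_cohort(config)
    m1_pwm, m2_pwm = estimate_pwms(cohort, "human")
    hits = scan_genomes(cohort, m1_pwm, m2_pwm, -10.0, -6.0)
    positions, captured = informative_positions(m1_pwm, 14)
    table = extract_words(
        {sp: hits[sp]["m1"] for sp in cohort.species},
        cohort.genomes,
        positions,
        {sp: cohort.bound_regions(sp) for sp in cohort.species},
        M1_LENGTH,
    )
    codes = sharing_codes(cohort.events["human"], cohort.events, cohort.block_map, "human")
    return {
        "config": config,
        "cohort": cohort,
        "m1_pwm": m1_pwm,
        "m2_pwm": m2_pwm,
        "hits": hits,
        "positions": positions,
        "captured": captured,
        "table": table,
        "codes": codes,
    }


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap cohort: 600 kb, 250 sites, one shared expansion, no genes/domains."""
    expansions = (
        RepeatExpansionSpec(
            name="B2_Mm1", family="B2", repeat_class="SINE",
            species=("mouse", "rat"), n_copies=30, divergence_mean=0.05,
            with_m2=True, m2_spacing=20, word_substitutions=((0, 1),),
        ),
        RepeatExpansionSpec(
            name="MmOnly", family="B2", repeat_class="SINE",
            species=("mouse",), n_copies=20, divergence_mean=0.03,
            with_m2=True, m2_spacing=20, word_substitutions=((0, 1),),
        ),
    )
    config = SimulationConfig(
        seed=33,
        genome_length=600_000,
        n_sites=250,
        expansions=expansions,
        n_insulated_pairs=0,
        n_control_pairs=0,
        barrier_fraction=0.0,
        n_background_domains=0,
    )
    return simulate_cohort(config)
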