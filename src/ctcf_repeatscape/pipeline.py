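"""End-to-end pipeline driver: simulate -> scan -> share -> words -> repeats
-> barriers -> insulate -> conserve.

Stage parameters default to the published analysis constants (scan cutoffs
-10 bits for bound motif instances and -15 for conservation profiling, 12-42
bp spacing window, 14-mer words, >= 5 bound occurrences for the hierarchy,
ln-ratio 2 and nocc 8 for lineage words, 1 kb barrier cap, 10 kb tandem gap,
clock rates 2.2e-9 and 4.5e-9 /bp/yr).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dna, io
from .chromatin_barriers import barrier_fractions, oriented_signal_matrix
from .cohort import (
    M1_LENGTH,
    M2_LENGTH,
    Cohort,
    SimulationConfig,
    aligned_windows,
    event_category,
    simulate_cohort,
)
from .conservation_profile import obs_exp_profile, unchanged_base_pwm
from .expression_insulation import (
    categorize_pairs,
    compare_categories,
    expression_divergence,
    find_tandem_pairs,
)
from .motif_scan import PWM, build_pwm, hits_to_bed6, scan, spacing_analysis
from .motif_words import (
    WordTable,
    extract_words,
    hierarchy,
    informative_positions,
    lineage_specific_words,
    words_for_hits,
)
from .ortho_sharing import CODE_SPECIES, five_way_fraction, sharing_codes
from .repeat_evolution import (
    MAMMAL_RATE,
    RODENT_RATE,
    ages_from_annotation,
    event_repeat_association,
    word_repeat_enrichment,
)
from .intervals import overlaps_any

logger = logging.getLogger(__name__)

LINEAGE_GROUPS: dict[str, tuple[str, ...]] = {
    "rodent": ("mouse", "rat"),
    "primate": ("human", "macaque"),
    "dog": ("dog",),
    "opossum": ("opossum",),
}


@dataclass
class PipelineConfig:
    """All stage parameters with the published defaults, plus the cohort."""

    simulation: SimulationConfig
    anchor: str = "human"
    m1_cutoff_bound: float = -10.0
    m1_cutoff_conservation: float = -15.0
    m2_cutoff: float = -6.0
    spacing_window: tuple[int, int] = (12, 42)
    spacing_reps: int = 100
    preferred_spacings: tuple[int, ...] = (20, 21)
    word_k: int = 14
    min_bound: int = 5
    hierarchy_bins: int = 25
    ln_ratio: float = 2.0
    min_nocc: float = 8.0
    barrier_cap: float = 1000.0
    tandem_max_gap: int = 10_000
    mammal_rate: float = MAMMAL_RATE
    rodent_rate: float = RODENT_RATE
    conservation_flank: int = 50
    pwm_pseudocount: float = 0.5

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["tree"] = {
            "species": list(self.simulation.tree.species),
            "parents": self.simulation.tree.parents,
            "branch_lengths": self.simulation.tree.branch_lengths,
        }
        return d


def site_motif_sequences(cohort: Cohort, species: str, require_m2: bool = False) -> tuple[list[str], list[str]]:
    """Motif-oriented M1 (and M2) sequences at planted sites bound in a species."""
    sites = cohort.truth.sites
    genome = cohort.genomes[species]
    m1_seqs: list[str] = []
    m2_seqs: list[str] = []
    for row in sites.itertuples(index=False):
        if species not in row.bound_species.split(","):
            continue
        if require_m2 and not row.has_m2:
            continue
        pos = int(getattr(row, f"pos_{species}"))
        fp = int(row.footprint)
        if row.strand == "+":
            m1 = genome[pos : pos + M1_LENGTH]
        else:
            m1 = dna.revcomp(genome[pos + fp - M1_LENGTH : pos + fp])
        m1_seqs.append(dna.decode(m1))
        if row.has_m2:
            m2_off = M1_LENGTH // 2 + int(row.spacing) - M2_LENGTH // 2
            if row.strand == "+":
                m2 = genome[pos + m2_off : pos + m2_off + M2_LENGTH]
            else:
                m2 = dna.revcomp(genome[pos + fp - m2_off - M2_LENGTH : pos + fp - m2_off])
            m2_seqs.append(dna.decode(m2))
    return m1_seqs, m2_seqs


def estimate_pwms(cohort: Cohort, anchor: str, pseudocount: float = 0.5) -> tuple[PWM, PWM]:
    """PWMs estimated by counting bases at the seeded bound sites of the anchor."""
    m1_seqs, m2_seqs = site_motif_sequences(cohort, anchor)
    if not m1_seqs:
        raise ValueError(f"no bound sites in anchor species {anchor!r}")
    m1 = build_pwm(m1_seqs, pseudocount=pseudocount)
    m2 = build_pwm(m2_seqs, pseudocount=pseudocount) if m2_seqs else cohort.m2_pwm
    return m1, m2


def scan_genomes(
    cohort: Cohort, m1_pwm: PWM, m2_pwm: PWM, m1_cutoff: float, m2_cutoff: float
) -> dict[str, dict[str, pd.DataFrame]]:
    """Genome-wide M1/M2 hits per species at the given bits-suboptimal cutoffs."""
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for sp in cohort.species:
        out[sp] = {
            "m1": scan(cohort.genomes[sp], m1_pwm, m1_cutoff, motif_id="M1"),
            "m2": scan(cohort.genomes[sp], m2_pwm, m2_cutoff, motif_id="M2"),
        }
    return out


def annotate_event_words(
    events: pd.DataFrame,
    m1_hits: pd.DataFrame,
    genome: np.ndarray,
    positions: np.ndarray,
    codes: pd.Series | None = None,
) -> pd.DataFrame:
    """One row per event with its best-scoring M1 word (NaN when motif-free)."""
    hits = m1_hits.copy()
    hits["word"] = words_for_hits(hits, genome, positions, M1_LENGTH)
    ev = events.copy()
    words, hit_scores = [], []
    starts = hits["start"].to_numpy()
    for row in ev.itertuples(index=False):
        sub = hits[(starts >= row.start) & (hits["end"].to_numpy() <= row.end)]
        if sub.empty:
            words.append(None)
            hit_scores.append(np.nan)
        else:
            best = sub.loc[sub["score"].idxmax()]
            words.append(best["word"])
            hit_scores.append(float(best["score"]))
    ev["word"] = words
    ev["hit_score"] = hit_scores
    if codes is not None:
        ev["code"] = codes.reindex(ev.index)
    return ev


def label_events_repeat_associated(
    events: pd.DataFrame, m1_hits: pd.DataFrame, repeats: pd.DataFrame
) -> pd.Series:
    """True where an event's bound motif hit (not merely the peak) overlaps a repeat."""
    if repeats.empty or m1_hits.empty:
        return pd.Series(False, index=events.index)
    in_repeat = overlaps_any(
        m1_hits["start"].to_numpy(),
        m1_hits["end"].to_numpy(),
        repeats["start"].to_numpy(),
        repeats["end"].to_numpy(),
    )
    rep_hits = m1_hits[in_repeat]
    if rep_hits.empty:
        return pd.Series(False, index=events.index)
    return pd.Series(
        overlaps_any(
            events["start"].to_numpy(),
            events["end"].to_numpy(),
            rep_hits["start"].to_numpy(),
            rep_hits["end"].to_numpy(),
        ),
        index=events.index,
    )


def word_repeat_labels(
    word_table: WordTable,
    hits_by_species: dict[str, pd.DataFrame],
    genomes: dict[str, np.ndarray],
    positions: np.ndarray,
    repeats_by_species: dict[str, pd.DataFrame],
) -> dict[tuple[str, str], set[str]]:
    """(level, category) -> words with >= 1 hit inside that repeat category."""
    labels: dict[tuple[str, str], set[str]] = {}
    for sp, hits in hits_by_species.items():
        reps = repeats_by_species.get(sp)
        if reps is None or reps.empty or hits.empty:
            continue
        words = words_for_hits(hits, genomes[sp], positions, M1_LENGTH)
        hs = hits["start"].to_numpy()
        he = hits["end"].to_numpy()
        for level, col in (("class", "class"), ("family", "family"), ("name", "name")):
            for cat, sub in reps.groupby(col):
                inside = overlaps_any(hs, he, sub["start"].to_numpy(), sub["end"].to_numpy())
                if inside.any():
                    labels.setdefault((level, str(cat)), set()).update(
                        w for w in words[inside].dropna()
                    )
    return labels


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage on a (simulated) cohort and write versioned outputs.

    Returns the machine-readable summary that is also written as
    ``summary.json``; identical config and seed give identical summaries.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = io.output_meta(config.to_dict(), config.simulation.seed)
    summary: dict = {"seed": config.simulation.seed, "stages": {}}

    def fail(stage: str, err: Exception) -> None:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # simulate
    try:
        cohort = simulate_cohort(config.simulation)
    except Exception as err:  # pragma: no cover - error path
        fail("simulate", err)
    cohort.to_dir(out / "cohort")
    summary["stages"]["simulate"] = {
        "species": list(cohort.species),
        "events": {sp: int(len(cohort.events[sp])) for sp in cohort.species},
    }

    # scan
    m1_pwm, m2_pwm = estimate_pwms(cohort, config.anchor, config.pwm_pseudocount)
    m1_pwm.to_tsv(out / "m1_pwm.tsv")
    m2_pwm.to_tsv(out / "m2_pwm.tsv")
    hits = scan_genomes(cohort, m1_pwm, m2_pwm, config.m1_cutoff_bound, config.m2_cutoff)
    for sp in cohort.species:
        io.write_bed(out / f"{sp}.m1_hits.bed", hits_to_bed6(hits[sp]["m1"]), meta=meta)
    summary["stages"]["scan"] = {sp: int(len(hits[sp]["m1"])) for sp in cohort.species}

    # spacing (anchor species, hits inside bound regions)
    anchor = config.anchor
    regions = cohort.bound_regions(anchor)
    m1_b = hits[anchor]["m1"]
    m1_b = m1_b[
        overlaps_any(m1_b["start"].to_numpy(), m1_b["end"].to_numpy(),
                     regions["start"].to_numpy(), regions["end"].to_numpy())
    ]
    hist = spacing_analysis(
        m1_b,
        hits[anchor]["m2"],
        M1_LENGTH,
        M2_LENGTH,
        cohort.genomes[anchor].size,
        window=config.spacing_window,
        reps=config.spacing_reps,
        seed=config.simulation.seed + 1,
    )
    io.write_table(
        out / "spacing.tsv",
        pd.DataFrame(
            {"distance": hist.distances, "count": hist.counts, "background": hist.background}
        ),
        meta=meta,
    )
    summary["stages"]["spacing"] = {"modes": hist.modes(2)}

    # sharing
    codes = sharing_codes(
        cohort.events[anchor], cohort.events, cohort.block_map, anchor
    )
    ev_out = cohort.events[anchor].assign(code=codes)
    io.write_table(out / f"{anchor}.sharing.tsv", ev_out, meta=meta)
    summary["stages"]["share"] = {
        "alignable": int(codes.notna().sum()),
        "five_way_fraction": five_way_fraction(codes),
    }

    # words
    positions, captured = informative_positions(m1_pwm, config.word_k)
    table = extract_words(
        {sp: hits[sp]["m1"] for sp in cohort.species},
        cohort.genomes,
        positions,
        {sp: cohort.bound_regions(sp) for sp in cohort.species},
        M1_LENGTH,
    )
    io.write_table(out / "word_table.tsv", table.df, meta=meta, index=True)
    event_words = annotate_event_words(
        cohort.events[anchor], hits[anchor]["m1"], cohort.genomes[anchor], positions, codes
    )
    hier = hierarchy(table, anchor, event_words, config.min_bound, config.hierarchy_bins)
    io.write_table(out / "hierarchy_bins.tsv", hier.bins, meta=meta)
    io.write_table(out / "word_usage_correlations.tsv", hier.correlations, meta=meta, index=True)
    lineage = {
        name: sorted(
            lineage_specific_words(
                table,
                group,
                tuple(sp for sp in cohort.species if sp not in group),
                config.ln_ratio,
                config.min_nocc,
            )
        )
        for name, group in LINEAGE_GROUPS.items()
    }
    summary["stages"]["words"] = {
        "captured_ic_fraction": captured,
        "n_words": int(len(table.df)),
        "lineage_specific": {k: len(v) for k, v in lineage.items()},
    }

    # repeats
    repeat_results = {}
    labels = word_repeat_labels(
        table,
        {sp: hits[sp]["m1"] for sp in cohort.species},
        cohort.genomes,
        positions,
        cohort.repeats,
    )
    enrich_frames = []
    for name, words in lineage.items():
        if not words:
            continue
        df = word_repeat_enrichment(set(words), set(table.df.index), labels)
        df.insert(0, "lineage", name)
        enrich_frames.append(df)
    if enrich_frames:
        io.write_table(out / "word_repeat_enrichment.tsv", pd.concat(enrich_frames), meta=meta)
    assoc_frames = []
    for sp in cohort.species:
        if cohort.repeats[sp].empty or cohort.events[sp].empty:
            continue
        assoc = event_repeat_association(
            cohort.events[sp],
            cohort.repeats[sp],
            cohort.genomes[sp].size,
            randomizations=25,
            seed=config.simulation.seed + 2,
        )
        assoc.insert(0, "species", sp)
        assoc_frames.append(assoc)
    if assoc_frames:
        assoc_all = pd.concat(assoc_frames, ignore_index=True)
        io.write_table(out / "event_repeat_association.tsv", assoc_all, meta=meta)
        repeat_results["association"] = {
            f"{r.species}:{r.family}": float(r.p) for r in assoc_all.itertuples(index=False)
        }
    ages = {}
    for sp in cohort.species:
        reps = cohort.repeats[sp]
        if reps.empty:
            continue
        rate = config.rodent_rate if sp in ("mouse", "rat") else config.mammal_rate
        ages[sp] = float(ages_from_annotation(reps, rate).mean())
    repeat_results["mean_age_years"] = ages
    summary["stages"]["repeats"] = repeat_results

    # barriers
    bsp = config.simulation.barrier_species
    if cohort.coverage is not None and not cohort.domains.empty:
        conserved_ids = set(cohort.truth.sites.loc[cohort.truth.sites["conserved"], "site_id"])
        cats = event_category(cohort.events[bsp], config.simulation.expansions, bsp, conserved_ids)
        categories = {
            label: cohort.events[bsp][cats == label] for label in cats.unique()
        }
        fractions = barrier_fractions(
            categories,
            cohort.domains,
            cohort.genomes[bsp].size,
            seed=config.simulation.seed + 3,
            cap=config.barrier_cap,
        )
        io.write_table(out / "barrier_fractions.tsv", fractions, meta=meta)
        io.write_bedgraph(out / f"{bsp}.h2ak5ac.bedgraph", cohort.coverage, config.simulation.coverage_bin_size, meta=meta)
        mat = oriented_signal_matrix(
            cohort.events[bsp]["summit"].to_numpy(),
            cohort.coverage,
            config.simulation.coverage_bin_size,
        )
        np.savetxt(out / "oriented_signal_matrix.tsv", mat, delimiter="\t")
        summary["stages"]["barriers"] = {
            r.category: (None if pd.isna(r.fraction) else float(r.fraction))
            for r in fractions.itertuples(index=False)
        }

    # insulation
    esp = config.simulation.expression_species
    if len(cohort.genes):
        pairs = find_tandem_pairs(cohort.genes, config.tandem_max_gap)
        ev = cohort.events[esp].copy()
        esp_codes = sharing_codes(ev, cohort.events, cohort.block_map, esp) if esp in CODE_SPECIES else None
        if esp_codes is not None:
            ev["code"] = esp_codes
        ev["repeat_associated"] = label_events_repeat_associated(
            ev, hits[esp]["m1"], cohort.repeats[esp]
        )
        pairs = categorize_pairs(pairs, ev)
        pairs = expression_divergence(pairs, cohort.expression)
        comparison = compare_categories(pairs)
        io.write_table(out / "insulation.tsv", comparison, meta=meta)
        summary["stages"]["insulate"] = {
            r.category: {"n": int(r.n), "median": float(r.median_divergence),
                         "p": (None if pd.isna(r.p) else float(r.p))}
            for r in comparison.itertuples(index=False)
        }

    # conservation
    sites = cohort.truth.sites
    five_way_m2 = sites[sites["conserved"] & sites["has_m2"] & (sites["spacing"] == 20)]
    if len(five_way_m2):
        centers = (
            five_way_m2[f"pos_{anchor}"].to_numpy(np.int64)
            + five_way_m2["footprint"].to_numpy(np.int64) // 2
        )
        aln = aligned_windows(
            cohort, anchor, centers, five_way_m2["strand"].to_numpy(), config.conservation_flank + 40
        )
        profile = obs_exp_profile(aln, anchor_index=list(cohort.species).index(anchor), flank=config.conservation_flank)
        io.write_table(out / "conservation_profile.tsv", profile.table, meta=meta)
        mat, unchanged, degenerate = unchanged_base_pwm(aln, anchor_index=list(cohort.species).index(anchor))
        io.write_table(
            out / "unchanged_base_pwm.tsv",
            pd.DataFrame(mat, columns=list("ACGT")).assign(unchanged=unchanged),
            meta=meta,
        )
        summary["stages"]["conserve"] = {
            "n_sites": int(profile.n_sites),
            "low_confidence": bool(profile.low_confidence),
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
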