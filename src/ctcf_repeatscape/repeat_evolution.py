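"""Repeat-element association statistics, bound-repeat PWMs, and repeat dating.

Ages come from the molecular-clock estimate

    age (years) = divergence / rate,

with divergence = substitutions from the family consensus / consensus length
and a scalar neutral rate (defaults: 2.2e-9 /bp/yr for mammals, 4.5e-9 for
rodents).  Word/repeat association uses a one-sided Fisher exact test
(hypergeometric over-representation tail); event/repeat association uses an
upper-tail binomial test whose background probability is the median overlap
fraction of size-matched regions randomized into the gaps between events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import complement, overlaps_any
from .motif_scan import PWM, build_pwm, closest_downstream_spacings, scan

logger = logging.getLogger(__name__)

MAMMAL_RATE = 2.2e-9  # substitutions per bp per year
RODENT_RATE = 4.5e-9

REPEAT_LEVELS = ("class", "family", "name")


def fisher_enrichment_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p for over-representation in a 2x2 table.

    Table rows: (in set, not in set) x columns (labeled, unlabeled); the tail
    is the hypergeometric P(X >= a) with margins fixed.
    """
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    n_labeled = a + c
    n_set = a + b
    return float(stats.hypergeom.sf(a - 1, n_total, n_labeled, n_set))


def word_repeat_enrichment(
    word_set: set[str],
    all_words: set[str] | list[str],
    repeat_words: dict[tuple[str, str], set[str]],
) -> pd.DataFrame:
    """One-sided Fisher p per repeat category for a word set's repeat overlap.

    ``repeat_words`` maps (level, category name) -> words whose bound
    occurrences overlap that repeat category.  Levels are evaluated
    hierarchically (class, then family, then name); Bonferroni correction is
    applied within each level and reported alongside the raw p.
    """
    universe = set(all_words)
    word_set = set(word_set) & universe
    if not word_set:
        logger.info("empty word set; no enrichment test run")
        return pd.DataFrame(
            columns=["level", "name", "a", "b", "c", "d", "p", "p_bonferroni"]
        )
    rows = []
    for (level, name), labeled in repeat_words.items():
        labeled = set(labeled) & universe
        a = len(word_set & labeled)
        b = len(word_set - labeled)
        c = len(labeled - word_set)
        d = len(universe) - a - b - c
        rows.append(
            {"level": level, "name": name, "a": a, "b": b, "c": c, "d": d,
             "p": fisher_enrichment_p(a, b, c, d)}
        )
    df = pd.DataFrame(rows)
    level_order = {lv: i for i, lv in enumerate(REPEAT_LEVELS)}
    df["p_bonferroni"] = df.groupby("level")["p"].transform(
        lambda p: np.minimum(p * len(p), 1.0)
    )
    df = df.sort_values(
        ["level", "p"], key=lambda s: s.map(level_order) if s.name == "level" else s
    ).reset_index(drop=True)
    return df


def _random_gap_regions(
    sizes: np.ndarray,
    gap_starts: np.ndarray,
    gap_ends: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Place size-matched regions uniformly inside gaps (no gap-crossing)."""
    gap_lens = gap_ends - gap_starts
    starts = np.empty(sizes.size, dtype=np.int64)
    for i, size in enumerate(sizes):
        room = gap_lens - size
        ok = np.where(room >= 0)[0]
        if ok.size == 0:
            # fall back: largest gap, clipped region
            j = int(np.argmax(gap_lens))
            starts[i] = gap_starts[j]
            continue
        weights = room[ok] + 1
        j = ok[rng.choice(ok.size, p=weights / weights.sum())]
        starts[i] = gap_starts[j] + rng.integers(0, room[j] + 1)
    return starts, starts + sizes


def event_repeat_association(
    events: pd.DataFrame,
    repeats: pd.DataFrame,
    genome_length: int,
    randomizations: int = 100,
    seed: int | np.random.Generator = 0,
    by: str = "family",
) -> pd.DataFrame:
    """Upper-tail binomial p per repeat category for event/repeat overlap.

    n = number of events, k = events overlapping (>= 1 bp) a repeat of the
    category, p0 = median over randomizations of the overlap fraction of
    size-matched random regions placed in the gaps between events.
    """
    if randomizations < 1:
        raise ValueError("randomizations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ev_s = events["start"].to_numpy(np.int64)
    ev_e = events["end"].to_numpy(np.int64)
    sizes = ev_e - ev_s
    gap_s, gap_e = complement(ev_s, ev_e, genome_length)
    categories = sorted(repeats[by].dropna().unique())
    rep_by_cat = {
        cat: (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        for cat, sub in repeats.groupby(by)
    }
    bg_fracs = {cat: np.empty(randomizations) for cat in categories}
    for r in range(randomizations):
        rs, re_ = _random_gap_regions(sizes, gap_s, gap_e, rng)
        for cat in categories:
            cs, ce = rep_by_cat[cat]
            bg_fracs[cat][r] = overlaps_any(rs, re_, cs, ce).mean()
    rows = []
    n = len(events)
    for cat in categories:
        cs, ce = rep_by_cat[cat]
        k = int(overlaps_any(ev_s, ev_e, cs, ce).sum())
        p0 = float(np.median(bg_fracs[cat]))
        if p0 == 0.0:
            if k > 0:
                logger.warning(
                    "background probability 0 for %s with k=%d; p reported as 0-bound", cat, k
                )
                p = 0.0
            else:
                p = 1.0
        else:
            p = float(stats.binomtest(k, n, min(p0, 1.0), alternative="greater").pvalue)
        rows.append({by: cat, "n": n, "k": k, "background_p": p0, "p": p})
    return pd.DataFrame(rows)


def bound_repeat_pwm(hit_sequences: list[str], pseudocount: float = 0.0) -> PWM:
    """PWM from motif-oriented bound-motif sequences inside a repeat family."""
    if not hit_sequences:
        raise ValueError("at least one bound instance with a motif hit required")
    return build_pwm(hit_sequences, pseudocount=pseudocount)


def consensus_motif_report(
    consensus: str,
    m1_pwm: PWM,
    m2_pwm: PWM,
    m1_cutoff: float = -10.0,
    m2_cutoff: float = -6.0,
    window: tuple[int, int] = (12, 42),
) -> dict:
    """Presence and spacing of M1/M2 on a repeat consensus sequence."""
    m1 = scan(consensus, m1_pwm, m1_cutoff)
    m2 = scan(consensus, m2_pwm, m2_cutoff)
    spacings = closest_downstream_spacings(m1, m2, m1_pwm.length, m2_pwm.length, window)
    return {
        "m1_present": not m1.empty,
        "m2_present": not m2.empty,
        "spacing": int(spacings[0]) if spacings.size else None,
    }


def repeat_age(divergence: float | np.ndarray, rate: float) -> float | np.ndarray:
    """Age in years: divergence fraction / substitution rate (per bp per year)."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    div = np.asarray(divergence, dtype=float)
    if np.any((div < 0) | (div > 1)):
        raise ValueError("divergence must be in [0, 1]")
    out = div / rate
    return float(out) if out.ndim == 0 else out


@dataclass
class AgeEstimate:
    """Per-instance divergence and clock age."""

    instance_id: str
    divergence: float
    rate: float

    @property
    def age(self) -> float:
        return repeat_age(self.divergence, self.rate)


def ages_from_annotation(repeats: pd.DataFrame, rate: float) -> pd.Series:
    """Ages for a repeat annotation with substitutions and consensus_length columns."""
    div = repeats["substitutions"] / repeats["consensus_length"]
    return pd.Series(repeat_age(div.to_numpy(), rate), index=repeats.index, name="age")
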