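"""Motif-word extraction, normalized occurrence, hierarchy, lineage calls.

A motif-word is the 14-mer read at the most informative positions of the M1
matrix, in motif orientation.  Per species, a word's normalized occurrence is

    nocc = occ / factor,     factor = total bound bases / 1e6,

so nocc is "bound occurrences per megabase of bound sequence" and is
comparable across species with different binding repertoires.  Lineage-
specific words satisfy ln(nocc(S)/nocc(R)) > 2 and nocc(S) > 8 for a species
group S against the remaining group R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import dna
from .intervals import contained_in_any, total_length
from .motif_scan import PWM

logger = logging.getLogger(__name__)


def informative_positions(pwm: PWM, k: int = 14) -> tuple[np.ndarray, float]:
    """The k highest-IC positions in genomic order, plus captured IC fraction."""
    if k > pwm.length:
        raise ValueError(f"k={k} exceeds PWM length {pwm.length}")
    ic = pwm.ic
    # stable top-k: sort by (-ic, position) so ties resolve to earlier positions
    order = np.lexsort((np.arange(pwm.length), -ic))[:k]
    positions = np.sort(order)
    total = float(ic.sum())
    fraction = float(ic[positions].sum() / total) if total > 0 else 1.0
    return positions, fraction


def word_at_hit(
    genome: np.ndarray, start: int, strand: str, positions: np.ndarray, length: int
) -> str | None:
    """The motif-word of one hit, read in motif orientation; None on non-ACGT."""
    window = genome[start : start + length]
    if window.size < length:
        return None
    if strand == "-":
        window = dna.revcomp(window)
    bases = window[positions]
    if np.any(bases == dna.INVALID):
        return None
    return dna.decode(bases)


def words_for_hits(
    hits: pd.DataFrame, genome: np.ndarray, positions: np.ndarray, length: int
) -> pd.Series:
    """Vectorized motif-words for a hit table (NaN where a hit has non-ACGT)."""
    if hits.empty:
        return pd.Series(index=hits.index, dtype=object)
    starts = hits["start"].to_numpy(np.int64)
    windows = genome[starts[:, None] + np.arange(length)[None, :]]
    minus = (hits["strand"] == "-").to_numpy()
    if minus.any():
        rc = windows[minus][:, ::-1].copy()
        valid = rc != dna.INVALID
        rc[valid] = 3 - rc[valid]
        windows[minus] = rc
    sub = windows[:, positions]
    ok = ~np.any(sub == dna.INVALID, axis=1)
    if not ok.all():
        logger.info("excluded %d hits containing non-ACGT bases", int((~ok).sum()))
    lut = np.array(list(dna.BASES + "N"), dtype="U1")
    chars = lut[np.where(sub == dna.INVALID, 4, sub).astype(np.intp)]
    words = np.array(["".join(r) for r in chars], dtype=object)
    words[~ok] = None
    return pd.Series(words, index=hits.index, dtype=object)


@dataclass
class WordTable:
    """Per-species bound/genome occurrences and nocc of motif-words.

    ``df`` is indexed by word with columns occ_<sp>, genome_<sp>, nocc_<sp>;
    ``factors`` maps species -> total bound bases / 1e6.
    """

    df: pd.DataFrame
    factors: dict[str, float]
    species: tuple[str, ...]

    def occ(self, sp: str) -> pd.Series:
        return self.df[f"occ_{sp}"]

    def nocc(self, sp: str) -> pd.Series:
        return self.df[f"nocc_{sp}"]


def extract_words(
    hits_by_species: dict[str, pd.DataFrame],
    genomes: dict[str, np.ndarray],
    positions: np.ndarray,
    bound_regions: dict[str, pd.DataFrame],
    motif_length: int,
) -> WordTable:
    """Build the word table from genome-wide M1 hits.

    Genome occurrence counts every PWM hit regardless of binding; bound
    occurrence (occ) counts hits falling inside bound regions.  Words are
    always read in motif orientation, so a site reported on '-' yields the
    same word as its '+' reverse complement.
    """
    species = tuple(hits_by_species)
    per_species: dict[str, pd.DataFrame] = {}
    factors: dict[str, float] = {}
    for sp in species:
        hits = hits_by_species[sp]
        words = words_for_hits(hits, genomes[sp], positions, motif_length)
        hits = hits.assign(word=words).dropna(subset=["word"])
        regions = bound_regions[sp]
        rs, re_ = regions["start"].to_numpy(), regions["end"].to_numpy()
        factors[sp] = total_length(rs, re_) / 1e6
        bound = contained_in_any(
            hits["start"].to_numpy(), hits["end"].to_numpy(), rs, re_
        )
        genome_occ = hits.groupby("word").size()
        bound_occ = hits[bound].groupby("word").size()
        per_species[sp] = pd.DataFrame(
            {f"genome_{sp}": genome_occ, f"occ_{sp}": bound_occ}
        ).fillna(0)
    df = pd.concat(per_species.values(), axis=1).fillna(0)
    # the table's word set is the union of per-species *bound* words
    occ_cols = [f"occ_{sp}" for sp in species]
    df = df[df[occ_cols].sum(axis=1) > 0].copy()
    for sp in species:
        df[f"occ_{sp}"] = df[f"occ_{sp}"].astype(np.int64)
        df[f"genome_{sp}"] = df[f"genome_{sp}"].astype(np.int64)
        df[f"nocc_{sp}"] = df[f"occ_{sp}"] / factors[sp] if factors[sp] > 0 else np.nan
    df.index.name = "word"
    return WordTable(df=df.sort_index(), factors=factors, species=species)


def group_nocc(table: WordTable, group: tuple[str, ...]) -> pd.Series:
    """Group-level nocc: summed occ over the group / summed factor."""
    occ = sum(table.occ(sp) for sp in group)
    factor = sum(table.factors[sp] for sp in group)
    return occ / factor


def lineage_specific_words(
    table: WordTable,
    group_s: tuple[str, ...],
    group_r: tuple[str, ...],
    ln_ratio: float = 2.0,
    min_nocc: float = 8.0,
) -> set[str]:
    """Words with ln(nocc(S)/nocc(R)) > ln_ratio and nocc(S) > min_nocc.

    nocc(R) = 0 with nocc(S) above threshold counts as included (the ratio is
    treated as +inf: absence elsewhere is the strongest specificity signal).
    """
    if not group_s or not group_r or set(group_s) & set(group_r):
        raise ValueError("species groups must be disjoint and nonempty")
    ns = group_nocc(table, group_s)
    nr = group_nocc(table, group_r)
    with np.errstate(divide="ignore"):
        ratio_ok = (nr == 0) | (np.log(ns.where(ns > 0) / nr.where(nr > 0)) > ln_ratio)
    keep = (ns > min_nocc) & ratio_ok.fillna(False)
    return set(table.df.index[keep])


@dataclass
class HierarchyBins:
    """Frequency-sorted word bins with per-bin ChIP score and sharing."""

    bins: pd.DataFrame  # bin, n_words, mean_score, five_way_fraction
    correlations: pd.DataFrame  # species x species Spearman rho of word usage
    words: pd.DataFrame  # word, frequency per species, bin index


def hierarchy(
    table: WordTable,
    anchor: str,
    event_words: pd.DataFrame,
    min_bound: int = 5,
    n_bins: int = 25,
) -> HierarchyBins:
    """Rank words by anchor-species usage frequency and summarize bins.

    Words bound at least ``min_bound`` times in any species are retained;
    usage frequency = bound occurrence / genome occurrence.  ``event_words``
    carries one row per anchored binding event with columns word, score and
    code (sharing code or None); per bin the mean event score and five-way
    shared fraction are reported, along with pairwise Spearman correlations of
    word usage between species.
    """
    df = table.df
    occ_cols = [f"occ_{sp}" for sp in table.species]
    kept = df[df[occ_cols].max(axis=1) >= min_bound].copy()
    freq = pd.DataFrame(index=kept.index)
    for sp in table.species:
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[sp] = np.where(
                kept[f"genome_{sp}"] > 0, kept[f"occ_{sp}"] / kept[f"genome_{sp}"], 0.0
            )
    freq = freq.sort_values(anchor, ascending=False, kind="stable")
    n_bins_eff = min(n_bins, len(freq))
    if n_bins_eff < n_bins:
        logger.info("fewer words (%d) than bins (%d); using %d bins", len(freq), n_bins, n_bins_eff)
    if n_bins_eff == 0:
        raise ValueError("no words pass the min_bound filter")
    bin_index = pd.Series(
        np.concatenate([np.full(len(chunk), i) for i, chunk in enumerate(np.array_split(np.arange(len(freq)), n_bins_eff))]),
        index=freq.index,
        name="bin",
    )
    ev = event_words.dropna(subset=["word"]).copy()
    ev["bin"] = ev["word"].map(bin_index)
    ev = ev.dropna(subset=["bin"])
    full_code = "1" * 5
    rows = []
    for i in range(n_bins_eff):
        sub = ev[ev["bin"] == i]
        with_code = sub.dropna(subset=["code"]) if "code" in sub else sub.iloc[0:0]
        rows.append(
            {
                "bin": i,
                "n_words": int((bin_index == i).sum()),
                "n_events": len(sub),
                "mean_score": float(sub["score"].mean()) if len(sub) else np.nan,
                "five_way_fraction": float((with_code["code"] == full_code).mean())
                if len(with_code)
                else np.nan,
            }
        )
    corr = pd.DataFrame(index=list(table.species), columns=list(table.species), dtype=float)
    for a in table.species:
        for b in table.species:
            rho = stats.spearmanr(freq[a], freq[b]).statistic if len(freq) > 1 else np.nan
            corr.loc[a, b] = rho
    words = freq.copy()
    words["bin"] = bin_index
    return HierarchyBins(bins=pd.DataFrame(rows), correlations=corr, words=words)
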