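"""PWM construction, bits-suboptimal scanning, and two-part motif spacing.

Scores follow the nmscan convention: a window's score is its log2 likelihood
under the PWM minus the log2 likelihood of the PWM's best word, so 0.0 is a
perfect match and every other window scores below zero.

The CTCF motif is directional: the 9 bp M2 submotif sits a fixed distance
*downstream* of the 20 bp M1 on the same strand, so spacing is measured
center-to-center in the motif's 5'->3' direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import dna

def motif_center(start: np.ndarray | int, length: int, strand: str = "+") -> np.ndarray | int:
    """Motif center: floor(L/2) bases from the motif's 5' end.

    Measuring from the 5' end (start + L//2 on '+', start + L-1 - L//2 on '-')
    keeps center-to-center spacings identical for a site and its reverse
    complement, which a fixed genome-coordinate convention would not for
    even-length motifs."""
    if strand == "+":
        return start + length // 2
    return start + length - 1 - length // 2


@dataclass
class PWM:
    """Position probability matrix over {A,C,G,T} with information content."""

    probs: np.ndarray  # (L, 4), rows sum to 1
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("PWM probabilities must be an (L, 4) matrix with L >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def ic(self) -> np.ndarray:
        """Per-position information content in bits: 2 + sum p*log2 p."""
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(self.probs > 0, self.probs * np.log2(self.probs), 0.0)
        return 2.0 + plogp.sum(axis=1)

    @property
    def total_ic(self) -> float:
        return float(self.ic.sum())

    @property
    def consensus(self) -> str:
        return dna.decode(np.argmax(self.probs, axis=1).astype(np.uint8))

    def log2_probs(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probs)

    def max_score(self) -> float:
        """log2 likelihood of the best word."""
        return float(np.log2(self.probs.max(axis=1)).sum())

    def score_word(self, word: str | np.ndarray) -> float:
        """Bits-suboptimal score of a single window of length L."""
        arr = dna.encode(word) if isinstance(word, str) else np.asarray(word)
        if arr.size != self.length:
            raise ValueError("word length must equal PWM length")
        if np.any(arr == dna.INVALID):
            return float("-inf")
        lp = self.log2_probs()
        return float(lp[np.arange(self.length), arr].sum() - self.max_score())

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), self.pseudocount)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# length={self.length}\tpseudocount={self.pseudocount}\n")
            df = pd.DataFrame(self.probs, columns=list(dna.BASES))
            df.to_csv(fh, sep="\t", index_label="position")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PWM":
        with open(path) as fh:
            header = fh.readline()
            pseudo = 0.0
            for field in header.lstrip("#").split():
                if field.startswith("pseudocount="):
                    pseudo = float(field.split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t", index_col="position")
        return cls(df[list(dna.BASES)].to_numpy(), pseudocount=pseudo)


def build_pwm(sequences: list[str] | list[np.ndarray], pseudocount: float = 0.0) -> PWM:
    """Column base frequencies (with pseudocount) from equal-length aligned sites."""
    if len(sequences) == 0:
        raise ValueError("at least one sequence required")
    enc = [dna.encode(s) if isinstance(s, str) else np.asarray(s, dtype=np.uint8) for s in sequences]
    lengths = {e.size for e in enc}
    if len(lengths) != 1:
        raise ValueError("all site sequences must have equal length")
    mat = np.stack(enc)
    counts = np.zeros((mat.shape[1], 4), dtype=float)
    for b in range(4):
        counts[:, b] = (mat == b).sum(axis=0)
    counts += pseudocount
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("a column contains no ACGT bases and pseudocount is 0")
    return PWM(counts / totals, pseudocount=pseudocount)


def scan(
    sequence: str | np.ndarray,
    pwm: PWM,
    cutoff: float,
    both_strands: bool = True,
    chrom: str = "chr1",
    motif_id: str | None = None,
) -> pd.DataFrame:
    """All windows scoring >= cutoff (bits below best match), sorted by start.

    Windows containing non-ACGT characters are skipped.  Reverse-strand hits
    are reported on forward coordinates with strand '-'; their score is that
    of the window's reverse complement under the PWM.
    """
    if cutoff > 0:
        raise ValueError("cutoff must be <= 0 (bits below the best match)")
    seq = dna.encode(sequence) if isinstance(sequence, str) else np.asarray(sequence, dtype=np.uint8)
    L = pwm.length
    cols = ["chrom", "start", "end", "strand", "score"]
    if seq.size < L:
        df = pd.DataFrame(columns=cols)
    else:
        n_win = seq.size - L + 1
        idx = np.where(seq == dna.INVALID, 4, seq).astype(np.intp)
        frames = [("+", pwm)]
        if both_strands:
            frames.append(("-", pwm.reverse_complement()))
        rows = []
        for strand, mat in frames:
            lp = np.full((L, 5), -np.inf)
            lp[:, :4] = mat.log2_probs() - np.log2(mat.probs.max(axis=1))[:, None]
            acc = np.zeros(n_win)
            for i in range(L):
                acc += lp[i, idx[i : i + n_win]]
            hits = np.where(acc >= cutoff)[0]
            if hits.size:
                rows.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "start": hits,
                            "end": hits + L,
                            "strand": strand,
                            "score": acc[hits],
                        }
                    )
                )
        df = (
            pd.concat(rows, ignore_index=True).sort_values(["start", "strand"], kind="stable")
            if rows
            else pd.DataFrame(columns=cols)
        )
    df = df.reset_index(drop=True)
    df["start"] = df.get("start", pd.Series(dtype=np.int64)).astype(np.int64)
    df["end"] = df.get("end", pd.Series(dtype=np.int64)).astype(np.int64)
    if motif_id is not None:
        df["motif"] = motif_id
    return df


def hits_to_bed6(hits: pd.DataFrame, name: str = "M1") -> pd.DataFrame:
    """BED6 view of a hit table.

    Bits-suboptimal scores are non-positive floats; the BED score slot holds
    round(-100 * score), so 0 is a perfect match and larger values are worse.
    """
    out = hits[["chrom", "start", "end", "strand"]].copy()
    out.insert(3, "name", hits["motif"] if "motif" in hits.columns else name)
    out.insert(4, "score", np.round(-100.0 * hits["score"].to_numpy()).astype(int))
    return out[["chrom", "start", "end", "name", "score", "strand"]]


def _oriented_centers(hits: pd.DataFrame, length: int, strand: str) -> np.ndarray:
    return motif_center(hits["start"].to_numpy(np.int64), length, strand)


def closest_downstream_spacings(
    m1_hits: pd.DataFrame,
    m2_hits: pd.DataFrame,
    m1_length: int,
    m2_length: int,
    window: tuple[int, int] = (12, 42),
) -> np.ndarray:
    """Per M1 hit, center-to-center distance to the closest downstream same-strand M2.

    Downstream respects the M1 strand (larger coordinates on '+', smaller on
    '-').  M1 hits with no M2 in the window contribute nothing.
    """
    lo, hi = window
    out = []
    for strand in ("+", "-"):
        m1c = np.sort(_oriented_centers(m1_hits[m1_hits["strand"] == strand], m1_length, strand))
        m2c = np.sort(_oriented_centers(m2_hits[m2_hits["strand"] == strand], m2_length, strand))
        if m1c.size == 0 or m2c.size == 0:
            continue
        if strand == "+":
            # closest m2 center in [c+lo, c+hi]
            idx = np.searchsorted(m2c, m1c + lo, side="left")
            ok = idx < m2c.size
            d = np.where(ok, m2c[np.minimum(idx, m2c.size - 1)] - m1c, hi + 1)
        else:
            idx = np.searchsorted(m2c, m1c - lo, side="right") - 1
            ok = idx >= 0
            d = np.where(ok, m1c - m2c[np.maximum(idx, 0)], hi + 1)
        out.append(d[(d >= lo) & (d <= hi)])
    return np.concatenate(out) if out else np.array([], dtype=np.int64)


@dataclass
class SpacingHistogram:
    """Foreground and randomized-background counts of M1->M2 center spacings."""

    distances: np.ndarray  # window distances (bp)
    counts: np.ndarray  # foreground counts per distance
    background: np.ndarray  # per-distance median over randomization replicates
    window: tuple[int, int] = (12, 42)

    def modes(self, n: int = 2) -> list[int]:
        """The n distances with the highest foreground counts."""
        order = np.argsort(self.counts, kind="stable")[::-1][:n]
        return sorted(int(self.distances[i]) for i in order)


def spacing_analysis(
    m1_hits: pd.DataFrame,
    m2_hits: pd.DataFrame,
    m1_length: int,
    m2_length: int,
    sequence_length: int,
    window: tuple[int, int] = (12, 42),
    reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> SpacingHistogram:
    """Spacing histogram with a positional-null background.

    Background: ``reps`` times, M1 positions are re-drawn uniformly over the
    scanned sequence (same cardinality and strands) and the same closest-
    downstream-M2 procedure is applied; the per-distance median is reported.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if window[1] < window[0]:
        raise ValueError("empty spacing window")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dists = np.arange(window[0], window[1] + 1)

    def histo(m1: pd.DataFrame) -> np.ndarray:
        d = closest_downstream_spacings(m1, m2_hits, m1_length, m2_length, window)
        return np.bincount(d - window[0], minlength=dists.size)[: dists.size]

    fg = histo(m1_hits)
    bg = np.zeros((reps, dists.size))
    n_m1 = len(m1_hits)
    strands = m1_hits["strand"].to_numpy() if n_m1 else np.array([], dtype="U1")
    hi_start = max(sequence_length - m1_length, 1)
    for r in range(reps):
        starts = rng.integers(0, hi_start, size=n_m1)
        rand = pd.DataFrame({"start": starts, "strand": strands})
        bg[r] = histo(rand)
    return SpacingHistogram(
        distances=dists, counts=fg, background=np.median(bg, axis=0), window=window
    )


def categorize_peaks_by_motif(
    peaks: pd.DataFrame,
    m1_hits: pd.DataFrame,
    m2_hits: pd.DataFrame,
    m1_length: int,
    m2_length: int,
    window: tuple[int, int] = (12, 42),
    preferred: tuple[int, ...] = (20, 21),
) -> dict[str, int]:
    """Nested peak counts: total >= with M1 >= with M1+M2 in window >= at preferred spacing."""
    n_total = len(peaks)
    n_m1 = n_m2 = n_pref = 0
    for _, peak in peaks.iterrows():
        in_peak = m1_hits[(m1_hits["start"] >= peak["start"]) & (m1_hits["end"] <= peak["end"])]
        if in_peak.empty:
            continue
        n_m1 += 1
        local_m2 = m2_hits[(m2_hits["start"] >= peak["start"] - window[1]) & (m2_hits["end"] <= peak["end"] + window[1])]
        d = closest_downstream_spacings(in_peak, local_m2, m1_length, m2_length, window)
        if d.size:
            n_m2 += 1
            if np.isin(d, preferred).any():
                n_pref += 1
    return {
        "total": n_total,
        "with_m1": n_m1,
        "with_m1_m2_window": n_m2,
        "with_m1_m2_preferred": n_pref,
    }
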