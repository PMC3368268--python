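"""Tandem gene pairs and CTCF transcriptional insulation.

A tandem pair is two non-overlapping, same-strand neighboring genes whose
inter-gene gap is under 10 kb.  Expression divergence of a pair is the
Manhattan distance of the genes' log2 transcript estimates across replicates;
CTCF-separated categories are compared against pairs with no intervening CTCF
binding by a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ("five_way", "repeat_associated", "all_other", "no")
FIVE_WAY_CODE = "1" * 5


def find_tandem_pairs(genes: pd.DataFrame, max_gap: int = 10_000) -> pd.DataFrame:
    """Same-strand adjacent gene pairs with 0 < gap < max_gap.

    ``genes`` needs columns gene, chrom, start, end, strand (TSS = start on
    '+', end on '-').  Adjacency is genomic: only consecutive genes along the
    chromosome form pairs, so a gene appears in at most two pairs.
    """
    rows = []
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("start", kind="stable").reset_index(drop=True)
        for i in range(len(sub) - 1):
            g1, g2 = sub.iloc[i], sub.iloc[i + 1]
            gap = int(g2["start"] - g1["end"])
            if g1["strand"] != g2["strand"] or gap <= 0 or gap >= max_gap:
                continue
            upstream, downstream = (g1, g2) if g1["strand"] == "+" else (g2, g1)
            rows.append(
                {
                    "chrom": chrom,
                    "left_gene": g1["gene"],
                    "right_gene": g2["gene"],
                    "upstream_gene": upstream["gene"],
                    "downstream_gene": downstream["gene"],
                    "strand": g1["strand"],
                    "gap_start": int(g1["end"]),
                    "gap_end": int(g2["start"]),
                    "gap": gap,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "left_gene", "right_gene", "upstream_gene", "downstream_gene",
            "strand", "gap_start", "gap_end", "gap",
        ],
    )


def categorize_pairs(pairs: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Assign each pair a CTCF-separation category.

    A pair is CTCF-separated iff at least one event summit lies strictly
    inside the open gap interval.  Precedence for gaps holding several event
    types: five_way > repeat_associated > all_other; pairs with no event get
    "no".  ``events`` needs columns chrom, summit and optionally code (sharing
    code) and repeat_associated (bool).
    """
    cats = []
    for row in pairs.itertuples(index=False):
        sub = events[
            (events["chrom"] == row.chrom)
            & (events["summit"] > row.gap_start)
            & (events["summit"] < row.gap_end)
        ]
        if sub.empty:
            cats.append("no")
        elif "code" in sub.columns and (sub["code"] == FIVE_WAY_CODE).any():
            cats.append("five_way")
        elif "repeat_associated" in sub.columns and sub["repeat_associated"].fillna(False).any():
            cats.append("repeat_associated")
        else:
            cats.append("all_other")
    out = pairs.copy()
    out["category"] = cats
    return out


def expression_divergence(pairs: pd.DataFrame, expression: pd.DataFrame) -> pd.DataFrame:
    """Manhattan distance of log2 estimates per pair; missing genes dropped.

    ``expression`` is a gene x replicate table of log2 transcript estimates.
    """
    known = set(expression.index)
    keep = pairs["upstream_gene"].isin(known) & pairs["downstream_gene"].isin(known)
    if not keep.all():
        logger.info("dropped %d pairs with genes missing from the expression table", int((~keep).sum()))
    out = pairs[keep].copy()
    up = expression.loc[out["upstream_gene"]].to_numpy(float)
    down = expression.loc[out["downstream_gene"]].to_numpy(float)
    out["divergence"] = np.abs(up - down).sum(axis=1)
    return out


def manhattan_distance(v1: np.ndarray, v2: np.ndarray) -> float:
    """Sum over replicates of |log2 e1 - log2 e2|."""
    v1, v2 = np.asarray(v1, float), np.asarray(v2, float)
    if v1.shape != v2.shape:
        raise ValueError("expression vectors must have equal length")
    return float(np.abs(v1 - v2).sum())


def log2_with_pseudocount(counts: np.ndarray | pd.DataFrame, pseudocount: float = 1.0):
    """Convenience transform for raw counts: log2(x + pseudocount)."""
    return np.log2(counts + pseudocount)


def compare_categories(
    divergences: pd.DataFrame,
    reference: str = "no",
    min_n: int = 2,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum p per category against the reference.

    ``divergences`` needs columns category and divergence.  Categories (or a
    reference) with fewer than ``min_n`` observations report a missing p.
    """
    ref = divergences.loc[divergences["category"] == reference, "divergence"].to_numpy()
    rows = []
    for cat, sub in divergences.groupby("category"):
        vals = sub["divergence"].to_numpy()
        row = {
            "category": cat,
            "n": vals.size,
            "median_divergence": float(np.median(vals)) if vals.size else np.nan,
            "p": np.nan,
        }
        if cat != reference:
            if vals.size < min_n or ref.size < min_n:
                logger.info("category %s: insufficient observations for a test", cat)
            else:
                row["p"] = float(
                    stats.mannwhitneyu(vals, ref, alternative="two-sided").pvalue
                )
        rows.append(row)
    return pd.DataFrame(rows)
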