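"""Position-wise conservation around motifs from alignment columns.

Conservation is measured as an observed/expected substitution ratio computed
directly on alignment columns anchored at motif instances (an adapter accepts
externally computed per-base constraint scores such as GERP for real data):
per position, the number of species bases differing from the anchor base is
divided by the neutral expectation taken from the flanks.  The unchanged-base
frequency matrix renders the same signal as a PWM-like display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import dna

logger = logging.getLogger(__name__)


@dataclass
class ConservationProfile:
    """Per-position observed/expected substitutions and unchanged frequency."""

    table: pd.DataFrame  # position, observed, expected, ratio, unchanged_frequency
    n_sites: int
    low_confidence: bool


def obs_exp_profile(
    alignments: np.ndarray,
    anchor_index: int = 0,
    flank: int = 50,
    expected_per_position: float | None = None,
) -> ConservationProfile:
    """Observed/expected substitution ratio per alignment column.

    ``alignments`` is (sites, species, width) of encoded bases (255 =
    unalignable), strand-oriented with the anchor species at ``anchor_index``.
    Observed counts compare each non-anchor species base to the anchor base;
    the expectation is the mean observed count over the first and last
    ``flank`` columns unless supplied explicitly.  Profiles from fewer than 10
    sites are flagged low-confidence.
    """
    aln = np.asarray(alignments)
    if aln.ndim != 3:
        raise ValueError("alignments must be (sites, species, width)")
    n_sites, n_species, width = aln.shape
    anchor = aln[:, anchor_index, :]
    others = np.delete(aln, anchor_index, axis=1)
    valid = (others != dna.INVALID) & (anchor[:, None, :] != dna.INVALID)
    diff = (others != anchor[:, None, :]) & valid
    observed = diff.sum(axis=(0, 1)).astype(float)
    comparable = valid.sum(axis=(0, 1)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(comparable > 0, observed / comparable, np.nan)
    if expected_per_position is None:
        flank_idx = np.r_[0:min(flank, width), max(width - flank, 0):width]
        expected_rate = float(np.nanmean(rate[flank_idx]))
    else:
        expected_rate = float(expected_per_position)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = rate / expected_rate if expected_rate > 0 else np.full(width, np.nan)
    unchanged = np.where(comparable > 0, 1.0 - observed / np.maximum(comparable, 1), np.nan)
    low = n_sites < 10
    if low:
        logger.warning("profile built from only %d sites; flagged low-confidence", n_sites)
    table = pd.DataFrame(
        {
            "position": np.arange(width),
            "observed": observed,
            "comparable": comparable,
            "expected": expected_rate * comparable,
            "ratio": ratio,
            "unchanged_frequency": unchanged,
        }
    )
    return ConservationProfile(table=table, n_sites=n_sites, low_confidence=low)


def unchanged_base_pwm(
    alignments: np.ndarray, anchor_index: int = 0
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Frequency-of-unchanged-bases matrix at anchored sites.

    Returns (matrix (width, 4), per-position unchanged frequency, degenerate
    flag).  matrix[pos, b] is the fraction of comparable (site, species) pairs
    where the anchor base is b and the species base is unchanged; gapped or
    invalid columns are excluded from the denominator.  With a single species
    (anchor only) all frequencies are 1 by definition and the result is
    flagged degenerate.
    """
    aln = np.asarray(alignments)
    n_sites, n_species, width = aln.shape
    anchor = aln[:, anchor_index, :]
    degenerate = n_species == 1
    if degenerate:
        logger.warning("anchor-only alignment: unchanged frequencies are 1 by definition")
        mat = np.zeros((width, 4))
        for b in range(4):
            mat[:, b] = (anchor == b).mean(axis=0)
        return mat, np.ones(width), True
    others = np.delete(aln, anchor_index, axis=1)
    valid = (others != dna.INVALID) & (anchor[:, None, :] != dna.INVALID)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("excluded %d gapped/invalid species-position cells", n_excluded)
    same = (others == anchor[:, None, :]) & valid
    mat = np.zeros((width, 4))
    for b in range(4):
        at_b = (anchor == b)[:, None, :] & valid
        denom = valid.sum(axis=(0, 1))
        mat[:, b] = np.where(denom > 0, (same & at_b).sum(axis=(0, 1)) / np.maximum(denom, 1), 0.0)
    denom = valid.sum(axis=(0, 1))
    unchanged = np.where(denom > 0, same.sum(axis=(0, 1)) / np.maximum(denom, 1), np.nan)
    return mat, unchanged, False


def profile_from_scores(
    site_scores: np.ndarray, low_confidence_below: int = 10
) -> ConservationProfile:
    """Adapter for externally computed per-base constraint scores (e.g. GERP).

    ``site_scores`` is (sites, width): one row of per-position scores per
    anchored, strand-oriented site (NaN where unavailable).  The mean score
    per column is reported in the ``ratio`` slot of the profile table so the
    downstream plotting/summary path is shared with the substitution-based
    route.
    """
    arr = np.asarray(site_scores, dtype=float)
    if arr.ndim != 2:
        raise ValueError("site_scores must be (sites, width)")
    n_sites, width = arr.shape
    comparable = (~np.isnan(arr)).sum(axis=0).astype(float)
    mean = np.nanmean(arr, axis=0) if n_sites else np.full(width, np.nan)
    table = pd.DataFrame(
        {
            "position": np.arange(width),
            "observed": np.nansum(arr, axis=0),
            "comparable": comparable,
            "expected": np.nan,
            "ratio": mean,
            "unchanged_frequency": np.nan,
        }
    )
    return ConservationProfile(
        table=table, n_sites=n_sites, low_confidence=n_sites < low_confidence_below
    )


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.spearmanr(x, y).statistic)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho (all n! permutations).

    Spearman rho is the Pearson correlation of the rank vectors; permuting y
    permutes its ranks, whose mean and centered norm are permutation-
    invariant, so all n! correlations reduce to one matrix-vector product.
    """
    from itertools import permutations

    n = len(y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    norm = np.linalg.norm(rx_c) * np.linalg.norm(ry - ry.mean())
    obs = abs(_spearman_rho(x, y))
    perms = np.array(list(permutations(ry)))
    rho_all = (perms @ rx_c) / norm
    return float(np.mean(np.abs(rho_all) >= obs - 1e-12))


def motif_conservation_correlation(
    records: pd.DataFrame,
    conservation_col: str = "conservation",
    exclude: tuple[str, ...] = (),
    exact_max_n: int = 9,
) -> pd.DataFrame:
    """Spearman correlation of motif length and IC against conservation.

    ``records`` needs columns tf, length, ic and the conservation column
    (median per-motif constraint score per TF).  For n <= ``exact_max_n`` the
    p-value is an exact two-sided permutation p; otherwise scipy's asymptotic
    p is used.  ``exclude`` drops designated TFs before testing (e.g. the
    strongly-motif-driven outliers).  A constant conservation column yields
    rho = 0 by tie convention, flagged in the output.
    """
    df = records[~records["tf"].isin(exclude)].copy()
    n = len(df)
    if n < 3:
        raise ValueError("at least 3 TFs required")
    y = df[conservation_col].to_numpy(float)
    rows = []
    constant = np.allclose(y, y[0])
    for var in ("length", "ic"):
        x = df[var].to_numpy(float)
        if constant or np.allclose(x, x[0]):
            rows.append({"variable": var, "n": n, "rho": 0.0, "p": 1.0, "degenerate": True})
            continue
        rho = _spearman_rho(x, y)
        if n <= exact_max_n:
            p = _exact_permutation_p(x, y)
        else:
            p = float(stats.spearmanr(x, y).pvalue)
        rows.append({"variable": var, "n": n, "rho": rho, "p": p, "degenerate": False})
    return pd.DataFrame(rows)
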