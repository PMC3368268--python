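"""Chromatin-domain calling and CTCF barrier classification.

A binding event with summit x is a barrier of an acetylation (H2AK5ac) domain
of length l when its distance to the nearest domain boundary is at most
min(l/10, 1000 bp): close to the edge of a short domain in relative terms, or
within 1 kb of a long one.  Controls: unrelated-TF event sets, events shifted
by a random 2-100 kb, and size/count-matched random regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def call_domains(
    coverage: np.ndarray,
    bin_size: int,
    threshold: float,
    min_length: int = 0,
    max_gap: int = 0,
) -> pd.DataFrame:
    """Maximal above-threshold runs of bins, gap-merged and length-filtered.

    A simple threshold caller for synthetic coverage: runs of bins with signal
    > threshold, merging runs separated by <= max_gap bp and dropping merged
    runs shorter than min_length bp.  Returns bp coordinates.
    """
    above = np.asarray(coverage) > threshold
    if not above.any():
        return pd.DataFrame(columns=["start", "end", "length", "mean_signal"])
    edges = np.diff(above.astype(np.int8))
    starts = np.where(edges == 1)[0] + 1
    ends = np.where(edges == -1)[0] + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    runs: list[list[int]] = []
    for s, e in zip(starts, ends):
        if runs and (s - runs[-1][1]) * bin_size <= max_gap:
            runs[-1][1] = e
        else:
            runs.append([s, e])
    rows = []
    for s, e in runs:
        if (e - s) * bin_size < min_length:
            continue
        rows.append(
            {
                "start": s * bin_size,
                "end": e * bin_size,
                "length": (e - s) * bin_size,
                "mean_signal": float(np.mean(coverage[s:e])),
            }
        )
    return pd.DataFrame(rows, columns=["start", "end", "length", "mean_signal"])


@dataclass
class BarrierCall:
    """Outcome of the barrier rule for one event summit."""

    distance: float | None
    is_barrier: bool
    domain_index: int | None
    side: str | None  # 'left'|'right' boundary of the assigned domain
    cap: float = 1000.0


def classify_barriers(
    summits: np.ndarray,
    domains: pd.DataFrame,
    cap: float = 1000.0,
) -> pd.DataFrame:
    """Vectorized barrier rule: distance to nearest boundary vs min(l/10, cap).

    The nearest domain is the one whose closer boundary is nearest to the
    summit (events inside a domain use the closer internal boundary); ties
    between equidistant domains resolve to the domain with the smaller start.
    """
    summits = np.asarray(summits, dtype=np.int64)
    if domains.empty:
        return pd.DataFrame(
            {
                "summit": summits,
                "distance": np.nan,
                "domain_index": -1,
                "domain_length": np.nan,
                "is_barrier": False,
            }
        )
    dom = domains.sort_values("start", kind="stable").reset_index(drop=True)
    starts = dom["start"].to_numpy(np.int64)
    ends = dom["end"].to_numpy(np.int64)
    lengths = ends - starts
    d_start = np.abs(summits[:, None] - starts[None, :])
    d_end = np.abs(summits[:, None] - ends[None, :])
    d_dom = np.minimum(d_start, d_end)  # (events, domains)
    nearest = np.argmin(d_dom, axis=1)  # argmin takes the first == smaller start on ties
    dist = d_dom[np.arange(summits.size), nearest]
    l = lengths[nearest]
    allowed = np.minimum(l / 10.0, cap)
    return pd.DataFrame(
        {
            "summit": summits,
            "distance": dist.astype(float),
            "domain_index": nearest,
            "domain_length": l,
            "is_barrier": dist <= allowed,
        }
    )


def classify_barrier(summit: int, domains: pd.DataFrame, cap: float = 1000.0) -> BarrierCall:
    """Single-event barrier call (see classify_barriers)."""
    if domains.empty:
        return BarrierCall(distance=None, is_barrier=False, domain_index=None, side=None, cap=cap)
    df = classify_barriers(np.array([summit]), domains, cap)
    row = df.iloc[0]
    dom = domains.sort_values("start", kind="stable").reset_index(drop=True).iloc[int(row["domain_index"])]
    side = "left" if abs(summit - dom["start"]) <= abs(summit - dom["end"]) else "right"
    return BarrierCall(
        distance=float(row["distance"]),
        is_barrier=bool(row["is_barrier"]),
        domain_index=int(row["domain_index"]),
        side=side,
        cap=cap,
    )


def barrier_fractions(
    categories: dict[str, pd.DataFrame],
    domains: pd.DataFrame,
    genome_length: int,
    seed: int | np.random.Generator = 0,
    cap: float = 1000.0,
    shift_range: tuple[int, int] = (2_000, 100_000),
) -> pd.DataFrame:
    """Barrier fraction per event category plus shifted and random controls.

    Controls are built from the union of all category events: each event is
    shifted by a uniform distance in ``shift_range`` with a random sign
    (reflected back into the genome), and a size/count-matched random set is
    placed uniformly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    all_events = [df for df in categories.values() if len(df)]
    for name, df in categories.items():
        if df.empty:
            rows.append({"category": name, "n": 0, "fraction": np.nan})
            continue
        calls = classify_barriers(df["summit"].to_numpy(), domains, cap)
        rows.append(
            {"category": name, "n": len(df), "fraction": float(calls["is_barrier"].mean())}
        )
    if all_events:
        union = pd.concat(all_events, ignore_index=True)
        summits = union["summit"].to_numpy(np.int64)
        shift = rng.integers(shift_range[0], shift_range[1] + 1, size=summits.size)
        sign = rng.choice([-1, 1], size=summits.size)
        shifted = summits + sign * shift
        # reflect out-of-range summits back into [0, genome_length)
        shifted = np.abs(shifted)
        over = shifted >= genome_length
        shifted[over] = 2 * (genome_length - 1) - shifted[over]
        rows.append(
            {
                "category": "shifted_control",
                "n": summits.size,
                "fraction": float(classify_barriers(shifted, domains, cap)["is_barrier"].mean()),
            }
        )
        rand = rng.integers(0, genome_length, size=summits.size)
        rows.append(
            {
                "category": "random_control",
                "n": summits.size,
                "fraction": float(classify_barriers(rand, domains, cap)["is_barrier"].mean()),
            }
        )
    return pd.DataFrame(rows)


def filter_far_from(
    events: pd.DataFrame, reference_summits: np.ndarray, min_distance: int = 1000
) -> pd.DataFrame:
    """Drop events whose summit is within min_distance of any reference summit."""
    ref = np.sort(np.asarray(reference_summits, dtype=np.int64))
    if ref.size == 0:
        return events
    s = events["summit"].to_numpy(np.int64)
    idx = np.searchsorted(ref, s)
    left = np.where(idx > 0, s - ref[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
    right = np.where(idx < ref.size, ref[np.minimum(idx, ref.size - 1)] - s, np.iinfo(np.int64).max)
    return events[np.minimum(left, right) >= min_distance]


def oriented_signal_matrix(
    summits: np.ndarray,
    coverage: np.ndarray,
    bin_size: int,
    half_window: int = 20_000,
    orientation_coverage: np.ndarray | None = None,
) -> np.ndarray:
    """log2(count+1) rows around each summit, higher-signal side to the right.

    Rows whose window leaves the coverage track are padded with NaN; flipping
    uses the (possibly different) orientation signal so that the side with the
    larger mean lies rightward.  Orientation is a pure reversal: it never
    changes a row's multiset of values.
    """
    orientation_coverage = coverage if orientation_coverage is None else orientation_coverage
    summits = np.asarray(summits, dtype=np.int64)
    n_bins = 2 * (half_window // bin_size)
    half = n_bins // 2
    mat = np.full((summits.size, n_bins), np.nan)
    for i, x in enumerate(summits):
        c = x // bin_size
        lo, hi = c - half, c + half
        src_lo, src_hi = max(lo, 0), min(hi, coverage.size)
        row = np.full(n_bins, np.nan)
        row[src_lo - lo : n_bins - (hi - src_hi)] = np.log2(
            coverage[src_lo:src_hi].astype(float) + 1.0
        )
        orient = np.full(n_bins, np.nan)
        orient[src_lo - lo : n_bins - (hi - src_hi)] = orientation_coverage[src_lo:src_hi]
        left = np.nanmean(orient[:half]) if np.any(~np.isnan(orient[:half])) else 0.0
        right = np.nanmean(orient[half:]) if np.any(~np.isnan(orient[half:])) else 0.0
        mat[i] = row[::-1] if left > right else row
    return mat
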