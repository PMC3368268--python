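"""Poisson read-count model for ChIP enrichment and knockdown analysis.

The model: divide the genome into N non-overlapping bins; a fraction f of the
bins carry the feature and are enriched e-fold by the immunoprecipitation.
With R total aligned reads, counts are Poisson with mean e*M in feature bins
and M elsewhere, where M = R / (N * (e*f + (1 - f))).  A counter-intuitive
consequence: when a knockdown removes feature bins (f drops) while e is
unchanged, the expected count in the *remaining* feature bins rises, because
the same read budget is spread over fewer enriched bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import overlaps_any


@dataclass(frozen=True)
class ChipModelParams:
    """Parameters of the binned Poisson ChIP model.

    reads: total aligned reads R (> 0)
    bins: number of genome bins N (> 0)
    enrichment: fold enrichment e of feature bins (>= 1)
    feature_fraction: fraction f of bins carrying the feature (in [0, 1])
    bin_size: bin width in bp (bookkeeping only)
    """

    reads: float
    bins: int
    enrichment: float
    feature_fraction: float
    bin_size: int = 500

    def __post_init__(self) -> None:
        if self.reads <= 0:
            raise ValueError("reads must be > 0")
        if self.bins <= 0:
            raise ValueError("bins must be > 0")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if not 0.0 <= self.feature_fraction <= 1.0:
            raise ValueError("feature_fraction must be in [0, 1]")


@dataclass
class SignalTrack:
    """Per-bin read counts for a ChIP library and its matched input."""

    chip: np.ndarray
    input: np.ndarray
    bin_size: int = 500

    @property
    def chip_total(self) -> int:
        return int(self.chip.sum())

    @property
    def input_total(self) -> int:
        return int(self.input.sum())


def expected_read_means(params: ChipModelParams) -> dict[str, float]:
    """Analytic means: M = R/(N*(e*f+(1-f))) background, e*M in feature bins."""
    e, f = params.enrichment, params.feature_fraction
    m = params.reads / (params.bins * (e * f + (1.0 - f)))
    return {"feature_mean": e * m, "background_mean": m}


def simulate_bin_counts(
    params: ChipModelParams,
    feature_bins: np.ndarray,
    seed: int | np.random.Generator,
    input_reads: float | None = None,
) -> SignalTrack:
    """Draw independent Poisson counts per bin (mean e*M at feature bins, M elsewhere).

    The matched input library is un-enriched: every bin draws at mean
    input_reads / N (defaults to the ChIP read budget).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    feature_bins = np.asarray(feature_bins, dtype=np.int64)
    if feature_bins.size and (feature_bins.min() < 0 or feature_bins.max() >= params.bins):
        raise ValueError("feature_bins must index into range(bins)")
    means = expected_read_means(params)
    lam = np.full(params.bins, means["background_mean"])
    lam[feature_bins] = means["feature_mean"]
    chip = rng.poisson(lam)
    in_mean = (input_reads if input_reads is not None else params.reads) / params.bins
    inp = rng.poisson(np.full(params.bins, in_mean))
    return SignalTrack(chip=chip, input=inp, bin_size=params.bin_size)


def normalized_chip_signal(
    chip_window_sum: float,
    input_window_sum: float,
    chip_total: float,
    input_total: float,
    depth_correct: bool = False,
) -> float:
    """Normalized ChIP signal ((sum(ChIP)+1)/(sum(Input)+1)) * n, n = total(ChIP)/total(Input).

    The printed form multiplies by n; ``depth_correct=True`` divides instead,
    for callers that want the deeper library scaled down rather than up.
    """
    if chip_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be > 0")
    if chip_window_sum < 0 or input_window_sum < 0:
        raise ValueError("window sums must be >= 0")
    ratio = (chip_window_sum + 1.0) / (input_window_sum + 1.0)
    n = chip_total / input_total
    return ratio / n if depth_correct else ratio * n


def classify_knockdown_resistance(
    events_control: pd.DataFrame,
    events_kd: pd.DataFrame,
    category_col: str = "category",
) -> dict[str, float | None]:
    """Per-category fraction of control events that persist after knockdown.

    An event is resistant iff it overlaps (>= 1 bp) any knockdown-condition
    event.  Categories with no control events report ``None`` (undefined),
    never 0.
    """
    resistant = np.zeros(len(events_control), dtype=bool)
    if "chrom" in events_control.columns and "chrom" in events_kd.columns:
        for chrom, sub in events_control.groupby("chrom"):
            kd = events_kd[events_kd["chrom"] == chrom]
            resistant[events_control.index.get_indexer(sub.index)] = overlaps_any(
                sub["start"].to_numpy(), sub["end"].to_numpy(),
                kd["start"].to_numpy(), kd["end"].to_numpy(),
            )
    else:
        resistant = overlaps_any(
            events_control["start"].to_numpy(),
            events_control["end"].to_numpy(),
            events_kd["start"].to_numpy(),
            events_kd["end"].to_numpy(),
        )
    out: dict[str, float | None] = {}
    for cat, idx in events_control.groupby(category_col).groups.items():
        mask = events_control.index.isin(idx)
        n = int(mask.sum())
        out[str(cat)] = float(resistant[mask].mean()) if n else None
    return out
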