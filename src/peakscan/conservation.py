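"""Per-region conservation averaging and comparison statistics.

The per-region conservation score (PCCS) is the mean per-base conservation
probability over a region; bases without track data count as 0 (uncovered =
unconserved), with the covered fraction reported so the alternative reading
is auditable.  Cumulative cutoff curves, peak-height quartile summaries and
a Mann-Whitney two-set comparison complete the stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .genomics import GenomicInterval, Peak, ScoreTrack

__all__ = [
    "ConservationSummary",
    "region_mean_score",
    "summit_window",
    "cumulative_curve",
    "compare_sets",
    "quartile_summary",
]


@dataclass(frozen=True)
class ConservationSummary:
    region: GenomicInterval
    pccs: float
    covered_fraction: float


def region_mean_score(track: ScoreTrack, iv: GenomicInterval) -> ConservationSummary:
    """Mean conservation over every base of ``iv`` (missing bases count 0)."""
    vals = track.region(iv)  # raises KeyError for absent chromosomes
    present = ~np.isnan(vals)
    total = float(np.nansum(vals))
    return ConservationSummary(
        region=iv,
        pccs=total / iv.length(),
        covered_fraction=float(present.mean()),
    )


def summit_window(
    peak: Peak, size: int, chrom_length: int | None = None
) -> GenomicInterval:
    """``size``-bp window centred on the peak summit (floor-based for odd).

    Clipped at chromosome bounds with a warning.
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    start = peak.summit - size // 2
    end = start + size
    clipped_start = max(0, start)
    clipped_end = min(end, chrom_length) if chrom_length is not None else end
    if (clipped_start, clipped_end) != (start, end):
        warnings.warn(f"summit window for {peak.name} clipped at chromosome bounds")
    return GenomicInterval(peak.chrom, clipped_start, clipped_end)


def cumulative_curve(
    scores: Sequence[float], cutoffs: Sequence[float]
) -> pd.DataFrame:
    """Fraction of scores at or above each cutoff (the survival function).

    Fractions are non-decreasing as cutoffs decrease; any cutoff at or below
    the minimum score yields 100%.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("scores must be non-empty")
    c = np.asarray(cutoffs, dtype=float)
    frac = (s[None, :] >= c[:, None]).mean(axis=1)
    return pd.DataFrame({"cutoff": c, "fraction_at_or_above": frac})


def compare_sets(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney rank-sum comparison; returns (U statistic, two-sided p).

    Exact enumeration when the smaller set has <= 8 values and there are no
    ties; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sets must be non-empty")
    exact = min(a.size, b.size) <= 8 and np.unique(np.concatenate([a, b])).size == (
        a.size + b.size
    )
    res = mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def quartile_summary(
    values: Sequence[float], stratify_by: Sequence[float]
) -> pd.DataFrame:
    """Five-number summaries of ``values`` per quartile of ``stratify_by``.

    Quartile membership is by rank of ``stratify_by`` (ties broken by input
    order); requires n >= 4 paired observations.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(stratify_by, dtype=float)
    if v.size != s.size:
        raise ValueError("values and stratify_by must have equal length")
    if v.size < 4:
        raise ValueError("need at least 4 observations")
    order = np.argsort(s, kind="stable")
    groups = np.array_split(order, 4)
    rows = []
    for qi, idx in enumerate(groups, 1):
        vals = v[idx]
        rows.append(
            {
                "quartile": f"Q{qi}",
                "n": idx.size,
                "min": float(vals.min()),
                "q1": float(np.percentile(vals, 25)),
                "median": float(np.median(vals)),
                "q3": float(np.percentile(vals, 75)),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows).set_index("quartile")
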