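"""Corpus-level statistics: reactions per year, median-yield time series
with bootstrap confidence intervals, yield histograms with a
multiples-of-ten spike index, cumulative reagent coverage and Zipf
frequency-rank fitting.

All stochastic operations (the bootstrap) take an explicit seed and are
reproducible. The spike index quantifies the tendency of reported yields to
pile up on whole multiples of ten: mean histogram count on the bins
40,50,...,90 divided by the mean count on their immediate neighbor bins; a
value near 1 means no rounding artefact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aggregate import GroupKey, _getter
from .pipeline_types import ProcessedReaction

SPIKE_BINS = (40, 50, 60, 70, 80, 90)


@dataclass(frozen=True)
class FrequencyRankTable:
    """Items sorted by count: counts non-increasing, ranks 1..n."""

    items: tuple[tuple[str, int, int], ...]  # (id, count, rank)
    total: int

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "FrequencyRankTable":
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        items = tuple(
            (name, count, rank)
            for rank, (name, count) in enumerate(ordered, start=1)
        )
        return cls(items=items, total=sum(counts.values()))


@dataclass(frozen=True)
class BootstrapCI:
    statistic: float
    lower: float
    upper: float
    level: float
    n_boot: int
    seed: int
    n: int


def bootstrap_median_ci(
    values: Sequence[float],
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile-method bootstrap CI for the median."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two observations for a bootstrap CI")
    rng = np.random.default_rng(seed)
    resamples = rng.choice(arr, size=(n_boot, arr.size), replace=True)
    medians = np.median(resamples, axis=1)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(medians, [alpha, 1.0 - alpha])
    return BootstrapCI(
        statistic=float(np.median(arr)),
        lower=float(lower),
        upper=float(upper),
        level=level,
        n_boot=n_boot,
        seed=seed,
        n=int(arr.size),
    )


def reactions_per_year(
    records: Sequence[ProcessedReaction], split_by_doc_type: bool = False
) -> pd.DataFrame:
    """Counts per publication year; missing years inside the observed span
    appear as zero rows. Columns: year, count (or patent/nonpatent)."""
    if not records:
        return pd.DataFrame(columns=["year", "count"])
    years = [p.record.pub_year for p in records]
    span = range(min(years), max(years) + 1)
    if not split_by_doc_type:
        counts = pd.Series(years).value_counts()
        return pd.DataFrame(
            {"year": list(span), "count": [int(counts.get(y, 0)) for y in span]}
        )
    frame = pd.DataFrame(
        {
            "year": years,
            "doc_type": [p.record.doc_type.value for p in records],
        }
    )
    pivot = frame.value_counts(["year", "doc_type"]).unstack(fill_value=0)
    for col in ("patent", "nonpatent"):
        if col not in pivot.columns:
            pivot[col] = 0
    pivot = pivot.reindex(span, fill_value=0)
    out = pivot.reset_index()[["year", "patent", "nonpatent"]]
    out.columns.name = None
    return out


def median_yield_timeseries(
    records: Sequence[ProcessedReaction],
    window: int = 1,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
    split_by_doc_type: bool = True,
) -> pd.DataFrame:
    """Median yield per ``window``-year bin (and doc type) with percentile
    bootstrap CIs. Windows with fewer than two yields report the median
    only (NaN bounds)."""
    rows = []
    groups: dict[tuple[int, str], list[float]] = {}
    for p in records:
        if p.yield_percent is None:
            continue
        bin_start = (p.record.pub_year // window) * window
        key = (
            bin_start,
            p.record.doc_type.value if split_by_doc_type else "all",
        )
        groups.setdefault(key, []).append(p.yield_percent)
    for i, ((year, doc_type), yields) in enumerate(sorted(groups.items())):
        if len(yields) >= 2:
            ci = bootstrap_median_ci(
                yields, level=level, n_boot=n_boot, seed=seed + i
            )
            rows.append(
                dict(
                    year=year,
                    doc_type=doc_type,
                    n=ci.n,
                    median=ci.statistic,
                    lower=ci.lower,
                    upper=ci.upper,
                )
            )
        else:
            rows.append(
                dict(
                    year=year,
                    doc_type=doc_type,
                    n=len(yields),
                    median=float(np.median(yields)),
                    lower=np.nan,
                    upper=np.nan,
                )
            )
    return pd.DataFrame(rows)


def yield_histogram(
    records: Sequence[ProcessedReaction],
    bin_width: float = 1.0,
    doc_type: Optional[str] = None,
) -> tuple[pd.DataFrame, float]:
    """Integer-binned yield histogram plus the multiples-of-ten spike index.

    The spike index is the mean count on the bins containing 40..90 divided
    by the mean count on their immediate neighbor bins.
    """
    yields = [
        p.yield_percent
        for p in records
        if p.yield_percent is not None
        and (doc_type is None or p.record.doc_type.value == doc_type)
    ]
    edges = np.arange(0.0, 100.0 + 2 * bin_width, bin_width)
    counts, _ = np.histogram(np.asarray(yields), bins=edges)
    centers = edges[:-1]
    frame = pd.DataFrame({"bin": centers, "count": counts})

    def bin_count(value: float) -> float:
        idx = int(np.floor(value / bin_width))
        return float(counts[idx]) if 0 <= idx < len(counts) else np.nan

    spike_counts = [bin_count(v) for v in SPIKE_BINS]
    neighbor_counts = [
        bin_count(v + offset) for v in SPIKE_BINS for offset in (-bin_width, bin_width)
    ]
    denom = float(np.nanmean(neighbor_counts))
    spike_index = float(np.nanmean(spike_counts)) / denom if denom > 0 else np.nan
    return frame, spike_index


def reagent_counts(
    records: Sequence[ProcessedReaction], reagent_kind: str
) -> tuple[FrequencyRankTable, int]:
    """Frequency-rank table for solvent/base/ligand usage; second element
    is the number of records that have that reagent resolved at all."""
    get = _getter(reagent_kind)
    counts: dict[str, int] = {}
    n_with = 0
    for p in records:
        value = get(p)
        if value is None:
            continue
        n_with += 1
        counts[value] = counts.get(value, 0) + 1
    return FrequencyRankTable.from_counts(counts), n_with


def cumulative_coverage(
    records: Sequence[ProcessedReaction], reagent_kind: str
) -> pd.DataFrame:
    """Fraction of records covered by the top-k reagents, k = 1..n.

    Records missing the reagent are excluded from the denominator.
    """
    table, n_with = reagent_counts(records, reagent_kind)
    rows = []
    cum = 0
    for name, count, rank in table.items:
        cum += count
        rows.append(
            dict(
                rank=rank,
                reagent=name,
                count=count,
                coverage=cum / n_with if n_with else np.nan,
            )
        )
    return pd.DataFrame(rows)


def zipf_fit(
    table: FrequencyRankTable, min_count: int = 5
) -> tuple[float, float]:
    """Least-squares slope of log(count) vs log(rank) over items with
    count >= min_count; returns (exponent, r_squared) with
    exponent = -slope."""
    pts = [(rank, count) for _, count, rank in table.items if count >= min_count]
    if len(pts) < 3:
        raise ValueError(
            f"need at least 3 items with count >= {min_count}; got {len(pts)}"
        )
    x = np.log(np.asarray([r for r, _ in pts], dtype=float))
    y = np.log(np.asarray([c for _, c in pts], dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(-slope), r_squared


def class_share_timeseries(
    records: Sequence[ProcessedReaction], key: GroupKey
) -> pd.DataFrame:
    """Per-year normalized shares of each group; shares sum to 1 per year."""
    get = _getter(key)
    rows = [
        {"year": p.record.pub_year, "group": get(p)}
        for p in records
        if get(p) is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["year", "group", "share"])
    frame = pd.DataFrame(rows)
    counts = frame.value_counts(["year", "group"]).rename("count").reset_index()
    totals = counts.groupby("year")["count"].transform("sum")
    counts["share"] = counts["count"] / totals
    return counts.sort_values(["year", "group"]).reset_index(drop=True)
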