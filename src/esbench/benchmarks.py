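"""Empirical small/medium/large benchmarks from effect-magnitude distributions.

The benchmarks are the 25th, 50th and 75th percentiles of the absolute
effect sizes, computed by linear interpolation between order statistics at
plotting positions (k-1)/(n-1) (R's default quantile type 7), together with
moment-based skewness and excess kurtosis describing the shape of the
distribution.  Subgroup variants split the records by vessel bed, measurement
modality or biological category; records with an unknown level are counted in
a residual rather than silently dropped.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .records import EffectRecord

__all__ = [
    "BenchmarkTriple",
    "SubgroupBenchmarks",
    "GroupBy",
    "benchmark_quantiles",
    "moments",
    "subgroup_benchmarks",
    "benchmarks_frame",
    "histogram_counts",
]

MIN_GROUP_SIZE = 4


class GroupBy(str, enum.Enum):
    VESSEL_BED = "vessel_bed"
    MODALITY = "modality"
    BIO_CATEGORY = "bio_category"


@dataclass(frozen=True)
class BenchmarkTriple:
    """Percentile benchmarks and shape statistics for one (sub)distribution."""

    label: str
    n_effects: int
    q25: float
    q50: float
    q75: float
    skewness: float
    kurtosis_excess: float

    def __post_init__(self) -> None:
        if not (self.q25 <= self.q50 <= self.q75):
            raise ValueError("quantiles must be non-decreasing")


@dataclass(frozen=True)
class SubgroupBenchmarks:
    """Per-subgroup triples plus counts of records not assigned to a triple."""

    by: GroupBy
    triples: Mapping[str, BenchmarkTriple]
    insufficient: Mapping[str, int]  # levels with too few records for a triple
    n_unknown: int


def benchmark_quantiles(
    values: Iterable[float],
    label: str = "pooled",
    *,
    method: str = "linear",
    bias: bool = True,
) -> BenchmarkTriple:
    """Small/medium/large benchmarks of a magnitude sample.

    ``method`` is forwarded to :func:`numpy.quantile`; the default ``linear``
    interpolates order statistics at positions (k-1)/(n-1).  Requires at
    least four values.  Shape statistics use :func:`moments` when the sample
    has positive variance and are NaN for a degenerate (constant) sample.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < MIN_GROUP_SIZE:
        raise ValueError(
            f"need at least {MIN_GROUP_SIZE} values to derive benchmarks, got {arr.size}"
        )
    q25, q50, q75 = np.quantile(arr, [0.25, 0.50, 0.75], method=method)
    if np.ptp(arr) == 0:
        skew = kurt = math.nan
    else:
        skew, kurt = moments(arr, bias=bias)
    return BenchmarkTriple(
        label=label,
        n_effects=int(arr.size),
        q25=float(q25),
        q50=float(q50),
        q75=float(q75),
        skewness=skew,
        kurtosis_excess=kurt,
    )


def moments(values: Iterable[float], *, bias: bool = True) -> tuple[float, float]:
    """Skewness g1 = m3/m2^{3/2} and excess kurtosis g2 = m4/m2^2 - 3.

    ``bias=True`` (default) uses population central moments; ``bias=False``
    applies the usual small-sample adjustments (R ``type = 2`` style).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < MIN_GROUP_SIZE:
        raise ValueError("need at least 4 values for shape statistics")
    if np.ptp(arr) == 0:
        raise ValueError("moments undefined for a zero-variance sample")
    skew = stats.skew(arr, bias=bias)
    kurt = stats.kurtosis(arr, fisher=True, bias=bias)
    return float(skew), float(kurt)


def subgroup_benchmarks(
    records: Sequence[EffectRecord],
    by: GroupBy | str,
    *,
    method: str = "linear",
    include_unconverted_g: bool = True,
) -> SubgroupBenchmarks:
    """Benchmark triples per non-unknown subgroup level of harmonized records.

    Levels with fewer than four records are reported in ``insufficient``
    (label -> count) rather than producing an unstable triple.  Records with
    the unknown level are tallied in ``n_unknown``.  ``include_unconverted_g``
    keeps g records lacking sample sizes in the pooled magnitudes (they cannot
    be rescaled); a strict analysis may exclude them.
    """
    by = GroupBy(by)
    groups: dict[str, list[float]] = {}
    n_unknown = 0
    for r in records:
        if not include_unconverted_g and r.unconverted_g:
            continue
        level = getattr(r, by.value).value
        if level == "unknown":
            n_unknown += 1
            continue
        groups.setdefault(level, []).append(abs(r.es_value))
    triples = {}
    insufficient = {}
    for level, vals in sorted(groups.items()):
        if len(vals) < MIN_GROUP_SIZE:
            insufficient[level] = len(vals)
        else:
            triples[level] = benchmark_quantiles(vals, label=level, method=method)
    return SubgroupBenchmarks(
        by=by, triples=triples, insufficient=insufficient, n_unknown=n_unknown
    )


def benchmarks_frame(triples: Iterable[BenchmarkTriple]):
    """Tabulate triples (one row per label) for CSV/JSON export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "label": t.label,
                "n": t.n_effects,
                "q25": t.q25,
                "q50": t.q50,
                "q75": t.q75,
                "skewness": t.skewness,
                "kurtosis_excess": t.kurtosis_excess,
            }
            for t in triples
        ]
    )


def histogram_counts(
    values: Iterable[float], bin_width: float = 0.25, path: str | Path | None = None
) -> dict:
    """Fixed-width histogram bin counts of a magnitude sample, for re-plotting."""
    arr = np.asarray(list(values), dtype=float)
    top = max(bin_width, float(arr.max()) if arr.size else bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(arr, bins=edges)
    out = {"bin_edges": edges.tolist(), "counts": counts.tolist()}
    if path is not None:
        Path(path).write_text(json.dumps(out) + "\n", encoding="utf-8")
    return out
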