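"""Statistical power of meta-analytic summary effects across assumed true effects.

A meta-analysis with summary standard error ``se`` tests its pooled effect
with a two-tailed z test, so its power against an assumed true effect δ is

    power(δ) = 1 - Φ(z_{1-α/2} - δ/se) + Φ(-z_{1-α/2} - δ/se).

Each meta-analysis is profiled over a grid of plausible δ values (default
0.1 to 1.0 in steps of 0.1) and at the magnitude of its own observed summary
effect; medians across meta-analyses summarise the evidential value of a
literature.  Standard errors are taken directly when supplied or derived from
the reported 95% interval half-width.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import se_from_ci

__all__ = [
    "MetaRecord",
    "MetaPowerProfile",
    "MedianPower",
    "DEFAULT_DELTA_GRID",
    "meta_power_at",
    "meta_power_profile",
    "median_power",
    "read_meta_table",
    "profiles_frame",
]

DEFAULT_DELTA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


@dataclass(frozen=True)
class MetaRecord:
    """One meta-analysis summary effect with its uncertainty."""

    meta_id: str
    summary_es: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    se: float | None = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.se is not None and self.se <= 0:
            raise ValueError(f"meta {self.meta_id}: se must be positive")
        if (
            self.ci_lower is not None
            and self.ci_upper is not None
            and not (self.ci_lower <= self.summary_es <= self.ci_upper)
        ):
            raise ValueError(f"meta {self.meta_id}: summary effect outside its CI")

    def standard_error(self) -> float:
        """Reported se, or the one implied by the symmetric CI."""
        if self.se is not None:
            return self.se
        if self.ci_lower is None or self.ci_upper is None:
            raise ValueError(
                f"meta {self.meta_id}: no standard error and no CI to derive one"
            )
        se = se_from_ci(
            self.ci_lower, self.ci_upper, self.ci_level, estimate=self.summary_es
        )
        if se <= 0:
            raise ValueError(f"meta {self.meta_id}: degenerate CI implies se = 0")
        return se


@dataclass(frozen=True)
class MetaPowerProfile:
    meta_id: str
    delta_grid: tuple[float, ...]
    power_at_delta: tuple[float, ...]
    power_at_observed: float
    observed_es: float


@dataclass(frozen=True)
class MedianPower:
    """Across-meta medians of the power profiles and observed-effect power."""

    delta_grid: tuple[float, ...]
    median_at_delta: tuple[float, ...]
    median_at_observed: float
    mean_at_observed: float
    min_at_observed: float
    max_at_observed: float
    n_meta: int


def meta_power_at(delta: float, se: float, alpha: float = 0.05) -> float:
    """Two-tailed z-test power to detect true effect ``delta`` given ``se``."""
    if se <= 0:
        raise ValueError("se must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    shift = delta / se
    return float(stats.norm.sf(zcrit - shift) + stats.norm.cdf(-zcrit - shift))


def meta_power_profile(
    meta: MetaRecord,
    delta_grid: Sequence[float] = DEFAULT_DELTA_GRID,
    alpha: float = 0.05,
) -> MetaPowerProfile:
    """Power of one meta-analysis over the δ grid and at its observed effect."""
    se = meta.standard_error()
    grid = tuple(float(d) for d in delta_grid)
    return MetaPowerProfile(
        meta_id=meta.meta_id,
        delta_grid=grid,
        power_at_delta=tuple(meta_power_at(d, se, alpha) for d in grid),
        power_at_observed=meta_power_at(abs(meta.summary_es), se, alpha),
        observed_es=meta.summary_es,
    )


def median_power(profiles: Sequence[MetaPowerProfile]) -> MedianPower:
    """Element-wise medians across profiles (grids must match)."""
    if not profiles:
        raise ValueError("need at least one power profile")
    grid = profiles[0].delta_grid
    if any(p.delta_grid != grid for p in profiles):
        raise ValueError("profiles were computed on different delta grids")
    mat = np.array([p.power_at_delta for p in profiles])
    obs = np.array([p.power_at_observed for p in profiles])
    return MedianPower(
        delta_grid=grid,
        median_at_delta=tuple(np.median(mat, axis=0).tolist()),
        median_at_observed=float(np.median(obs)),
        mean_at_observed=float(np.mean(obs)),
        min_at_observed=float(np.min(obs)),
        max_at_observed=float(np.max(obs)),
        n_meta=len(profiles),
    )


def read_meta_table(path: str | Path) -> list[MetaRecord]:
    """Read a meta-summary CSV: meta_id, summary_es, then ci bounds and/or se."""
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in ("meta_id", "summary_es"):
            if col not in header:
                raise ValueError(f"required column {col!r} missing from header")
        for i, raw in enumerate(reader, start=1):
            row = {k: (v or "").strip() for k, v in raw.items() if k is not None}

            def opt(col):
                cell = row.get(col, "")
                return float(cell) if cell else None

            records.append(
                MetaRecord(
                    meta_id=row["meta_id"] or f"meta{i}",
                    summary_es=float(row["summary_es"]),
                    ci_lower=opt("ci_lower"),
                    ci_upper=opt("ci_upper"),
                    se=opt("se"),
                )
            )
    return records


def profiles_frame(
    profiles: Iterable[MetaPowerProfile], medians: MedianPower | None = None
) -> pd.DataFrame:
    """Long-format table (meta_id, delta, power) with observed-effect rows.

    The observed-effect power is stored with ``delta = NaN`` and
    ``at = "observed"``; a medians block is appended when supplied.
    """
    rows = []
    for p in profiles:
        for d, w in zip(p.delta_grid, p.power_at_delta):
            rows.append({"meta_id": p.meta_id, "at": "delta", "delta": d, "power": w})
        rows.append(
            {
                "meta_id": p.meta_id,
                "at": "observed",
                "delta": np.nan,
                "power": p.power_at_observed,
            }
        )
    if medians is not None:
        for d, w in zip(medians.delta_grid, medians.median_at_delta):
            rows.append({"meta_id": "__median__", "at": "delta", "delta": d, "power": w})
        rows.append(
            {
                "meta_id": "__median__",
                "at": "observed",
                "delta": np.nan,
                "power": medians.median_at_observed,
            }
        )
    return pd.DataFrame(rows)
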