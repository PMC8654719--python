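"""End-to-end study object: clean, harmonize, benchmark, regress, power.

:class:`EffectSizeStudy` is the model-style front door.  Built from an
effects table (and optionally a meta-summary table), ``fit()`` runs the whole
analysis — cleaning, d-scale harmonization, pooled and subgroup percentile
benchmarks, cluster-robust correlate regressions with clustered-bootstrap
intervals, a priori power tables at the derived benchmarks, and meta-analysis
power profiles — returning an :class:`EffectSizeStudyResults` that carries
every stage's output and renders a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import benchmarks as bm
from . import metapower as mp
from .metrics import harmonize_all
from .records import (
    CleanResult,
    EffectRecord,
    clean_effects,
    frame_to_records,
    magnitudes,
    read_effects,
)
from .regression import BootstrapSpec, ClusterOLS, ClusterOLSResults, LoessSpec, loess_curve

__all__ = ["EffectSizeStudy", "EffectSizeStudyResults"]


class EffectSizeStudy:
    """Effect-size distribution study over one extracted literature.

    Parameters
    ----------
    effects : sequence of EffectRecord
        Raw extracted rows (pre-cleaning).
    meta : sequence of MetaRecord, optional
        Meta-analysis summary effects for the power-profile stage.
    """

    def __init__(self, effects: Sequence[EffectRecord], meta=None):
        self.effects = list(effects)
        self.meta = list(meta) if meta is not None else None

    @classmethod
    def from_csv(cls, effects_path: str | Path, meta_path: str | Path | None = None):
        meta = mp.read_meta_table(meta_path) if meta_path else None
        return cls(read_effects(effects_path), meta)

    @classmethod
    def from_dataframe(cls, effects: pd.DataFrame, meta=None):
        return cls(frame_to_records(effects), meta)

    def fit(
        self,
        *,
        outlier_threshold: float = 8.0,
        quantile_method: str = "linear",
        log_base: float = 10.0,
        bootstrap: BootstrapSpec | None = None,
        power_levels: Sequence[float] = (0.7, 0.8, 0.9),
        target_power: float = 0.80,
        alpha: float = 0.05,
        delta_grid: Sequence[float] = mp.DEFAULT_DELTA_GRID,
        loess: LoessSpec | None = None,
    ) -> "EffectSizeStudyResults":
        from .power import power_curve, required_n

        clean = clean_effects(self.effects, outlier_threshold)
        harmonized = harmonize_all(clean.retained)
        mags = magnitudes(harmonized)

        pooled = bm.benchmark_quantiles(mags, "pooled", method=quantile_method)
        subgroups = {
            key: bm.subgroup_benchmarks(harmonized, key, method=quantile_method)
            for key in ("vessel_bed", "modality", "bio_category")
        }

        bootstrap = bootstrap or BootstrapSpec()
        regressions: dict[str, ClusterOLSResults] = {}
        loess_tables: dict[str, pd.DataFrame] = {}
        for cov in ("year", "log_n"):
            try:
                model = ClusterOLS.from_records(harmonized, cov, log_base=log_base)
            except ValueError:
                continue  # covariate absent from this dataset
            regressions[cov] = model.fit().with_bootstrap(bootstrap)
            grid = np.linspace(model.x.min(), model.x.max(), 51)
            loess_tables[cov] = pd.DataFrame(
                {"x": grid, "fitted": loess_curve(model.x, model.y, loess, grid)}
            )

        d_grid = (pooled.q25, pooled.q50, pooled.q75)
        power_tables = {
            design: power_curve(design, power_levels, d_grid, alpha)
            for design in ("paired", "two_sample")
        }
        table1 = pd.DataFrame(
            [
                {
                    "d": d,
                    "benchmark": name,
                    "paired_n_pairs": required_n("paired", d, target_power, alpha).n_required,
                    "independent_n_per_group": required_n(
                        "two_sample", d, target_power, alpha
                    ).n_required,
                }
                for name, d in zip(("small", "medium", "large"), d_grid)
            ]
        )

        profiles = medians = None
        if self.meta:
            profiles = [mp.meta_power_profile(m, delta_grid, alpha) for m in self.meta]
            medians = mp.median_power(profiles)

        return EffectSizeStudyResults(
            model=self,
            clean=clean,
            harmonized=tuple(harmonized),
            pooled=pooled,
            subgroups=subgroups,
            regressions=regressions,
            loess_tables=loess_tables,
            power_tables=power_tables,
            table1=table1,
            profiles=tuple(profiles) if profiles else None,
            median_power=medians,
            alpha=alpha,
            target_power=target_power,
        )


@dataclass(frozen=True)
class EffectSizeStudyResults:
    model: EffectSizeStudy
    clean: CleanResult
    harmonized: tuple[EffectRecord, ...]
    pooled: bm.BenchmarkTriple
    subgroups: Mapping[str, bm.SubgroupBenchmarks]
    regressions: Mapping[str, ClusterOLSResults]
    loess_tables: Mapping[str, pd.DataFrame]
    power_tables: Mapping[str, pd.DataFrame]
    table1: pd.DataFrame
    profiles: tuple[mp.MetaPowerProfile, ...] | None
    median_power: mp.MedianPower | None
    alpha: float
    target_power: float

    def benchmarks_frame(self) -> pd.DataFrame:
        triples = [self.pooled]
        for sg in self.subgroups.values():
            triples.extend(sg.triples.values())
        return bm.benchmarks_frame(triples)

    def summary(self) -> str:
        c = self.clean
        p = self.pooled
        lines = [
            "Effect-size distribution study",
            "=" * 34,
            f"records: {c.n_input} extracted, {c.n_duplicates_removed} duplicates and "
            f"{c.n_outliers_removed} outliers removed, {c.n_retained} retained",
            f"benchmarks (n={p.n_effects}): small={p.q25:.2f}  medium={p.q50:.2f}  "
            f"large={p.q75:.2f}",
            f"shape: skewness={p.skewness:.2f}  excess kurtosis={p.kurtosis_excess:.2f}",
        ]
        for level, t in self.subgroups["vessel_bed"].triples.items():
            lines.append(
                f"  {level:<18} n={t.n_effects:<4} q25={t.q25:.2f} q50={t.q50:.2f} "
                f"q75={t.q75:.2f}"
            )
        for cov, res in self.regressions.items():
            f = res.fit
            extra = ""
            if res.bootstrap_ci:
                extra = f"  bootstrap CI ({res.bootstrap_ci[0]:.2f}, {res.bootstrap_ci[1]:.2f})"
            lines.append(
                f"{cov:>6}: beta={f.beta: .3f}  SE_adj={f.se_adj:.3f}  "
                f"CI ({f.ci_lower:.2f}, {f.ci_upper:.2f})  p={f.p_value:.3f}"
                f"  G={f.n_clusters}{extra}"
            )
        lines.append(
            f"required n at {self.target_power:.0%} power (alpha={self.alpha}):"
        )
        for row in self.table1.itertuples(index=False):
            lines.append(
                f"  {row.benchmark:<7} d={row.d:.2f}: {row.paired_n_pairs} pairs / "
                f"{row.independent_n_per_group} per group"
            )
        if self.median_power is not None:
            m = self.median_power
            lines.append(
                f"meta-analyses (n={m.n_meta}): median power at observed effect "
                f"{100 * m.median_at_observed:.1f}%"
            )
        return "\n".join(lines)
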