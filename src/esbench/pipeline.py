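"""Batch pipeline: run the full study on files and write a report bundle.

``run_pipeline`` reads the effects (and optional meta-summary) tables, fits
:class:`~esbench.study.EffectSizeStudy`, and writes CSV/JSON reports plus a
manifest capturing the complete configuration — enough to re-run the pipeline
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import metapower as mp
from .records import cleaning_audit
from .regression import BootstrapSpec, LoessSpec
from .study import EffectSizeStudy

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Complete, serialisable configuration of one pipeline run."""

    effects_path: str
    out_dir: str
    meta_path: str | None = None
    outlier_threshold: float = 8.0
    quantile_method: str = "linear"
    log_base: float = 10.0
    bootstrap_replicates: int = 10_000
    ci_level: float = 0.95
    loess_span: float = 0.75
    loess_degree: int = 2
    power_levels: tuple[float, ...] = (0.7, 0.8, 0.9)
    target_power: float = 0.80
    alpha: float = 0.05
    delta_grid: tuple[float, ...] = mp.DEFAULT_DELTA_GRID
    seed: int = 20211027

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a simple ``key = value`` text file or JSON."""
        text = Path(path).read_text(encoding="utf-8").strip()
        if text.startswith("{"):
            data = json.loads(text)
        else:
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = json.loads(value.strip())
        for key in ("power_levels", "delta_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute all stages and write the report bundle; returns output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    study = EffectSizeStudy.from_csv(config.effects_path, config.meta_path)
    results = study.fit(
        outlier_threshold=config.outlier_threshold,
        quantile_method=config.quantile_method,
        log_base=config.log_base,
        bootstrap=BootstrapSpec(
            n_replicates=config.bootstrap_replicates,
            seed=config.seed,
            ci_level=config.ci_level,
        ),
        power_levels=config.power_levels,
        target_power=config.target_power,
        alpha=config.alpha,
        delta_grid=config.delta_grid,
        loess=LoessSpec(span=config.loess_span, degree=config.loess_degree),
    )

    paths: dict[str, str] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = str(p)

    audit = cleaning_audit(results.clean, out / "cleaning_audit.json")
    paths["cleaning_audit.json"] = str(out / "cleaning_audit.json")
    logger.info("cleaning: %s", audit)

    save("benchmarks.csv", results.benchmarks_frame())

    reg_rows = []
    for cov, res in results.regressions.items():
        f = res.fit
        lo, hi = res.bootstrap_ci or (float("nan"), float("nan"))
        reg_rows.append(
            {
                "covariate": cov,
                "beta": f.beta,
                "se_adj": f.se_adj,
                "ci_lower": f.ci_lower,
                "ci_upper": f.ci_upper,
                "p_value": f.p_value,
                "bootstrap_ci_lower": lo,
                "bootstrap_ci_upper": hi,
                "n_obs": f.n_obs,
                "n_clusters": f.n_clusters,
            }
        )
    save("regressions.csv", pd.DataFrame(reg_rows))
    for cov, table in results.loess_tables.items():
        save(f"loess_{cov}.csv", table)

    save("power_table.csv", results.table1)
    for design, table in results.power_tables.items():
        save(f"power_curve_{design}.csv", table)

    if results.profiles is not None:
        save("meta_power.csv", mp.profiles_frame(results.profiles, results.median_power))

    manifest = {
        "config": dataclasses.asdict(config),
        "counts": {
            **audit,
            "n_meta_summaries": len(results.profiles) if results.profiles else 0,
        },
        "outputs": sorted(paths),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", "utf-8")
    paths["manifest.json"] = str(out / "manifest.json")
    return paths
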