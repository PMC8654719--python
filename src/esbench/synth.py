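"""Synthetic clustered effect-size literatures with known ground truth.

The generator emulates the salient shapes of a meta-research extraction
dataset for endothelial function: ~40 meta-analyses (clusters) holding
correlated effects (~750 rows), a right-skewed magnitude distribution
(lognormal, median 0.69, log-sd 0.83, so the large/medium benchmark ratio is
about 1.75), group sample sizes with medians near 21/20, publication years
1990-2021, mixed effect signs, a mix of Cohen's d and Hedges' g labels (some
g rows lacking sample sizes), a weak negative magnitude-vs-log-sample-size
slope, and planted rule violations (flagged duplicates, |es| > 8 outliers).

Magnitudes are drawn stratified at the outlier threshold: retained rows come
from the law conditioned on [0, threshold] and exactly ``outlier_count``
planted rows from the tail beyond it.  :class:`GroundTruth` therefore reports
the closed-form quantiles of the *truncated* law — what the cleaned sample
follows exactly when the injected slopes are zero — plus the injected slopes.

A lognormal random effect shared within each meta-analysis (``within_meta_sd``
on the log scale) creates the within-cluster correlation; the marginal law is
preserved because the residual log-sd is shrunk to compensate.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .metrics import correction_factor
from .records import (
    BioCategory,
    EffectRecord,
    ESMetric,
    Modality,
    VesselBed,
)
from .metapower import MetaRecord

__all__ = ["SyntheticConfig", "GroundTruth", "generate_effect_dataset",
           "generate_meta_dataset", "write_ground_truth"]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic literature.

    Defaults mirror the target extraction dataset: 40 clusters, 752 clean
    rows plus 6 duplicates and 2 outliers (760 raw), lognormal magnitudes
    with median 0.69 and log-sd 0.83, group-size medians 21/20, years
    1990-2021, injected magnitude-vs-log10(N) slope -0.19 and zero year trend.
    """

    n_meta: int = 40
    n_effects: int = 752          # clean rows before planting violations
    magnitude_law: str = "lognormal"
    magnitude_median: float = 0.69
    magnitude_sigma: float = 0.83
    within_meta_sd: float = 0.30  # cluster random effect, log-magnitude scale
    sign_negative_prob: float = 0.35
    year_range: tuple[int, int] = (1990, 2021)
    year_slope: float = 0.0
    logn_slope: float = -0.19     # per unit log10(total N)
    n_median_treatment: float = 21.0
    n_median_control: float = 20.0
    n_sigma: float = 0.45
    n_min: int = 5
    g_fraction: float = 0.50          # rows labelled Hedges' g with sample sizes
    g_missing_n_fraction: float = 0.02  # g rows whose sample sizes are withheld
    bed_log_shift: float = 0.0    # log-magnitude deficit of the microvascular bed
    outlier_threshold: float = 8.0
    dup_count: int = 6
    outlier_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.magnitude_law not in ("lognormal", "gamma"):
            raise ValueError("magnitude_law must be 'lognormal' or 'gamma'")
        if min(self.n_meta, self.n_effects) < 1:
            raise ValueError("n_meta and n_effects must be positive")
        if min(self.dup_count, self.outlier_count) < 0:
            raise ValueError("planted counts must be non-negative")
        if not 0 <= self.sign_negative_prob <= 1:
            raise ValueError("sign_negative_prob must be a probability")
        if self.within_meta_sd < 0 or self.magnitude_sigma <= 0:
            raise ValueError("scale parameters must be positive")
        if self.magnitude_law == "lognormal" and self.within_meta_sd >= self.magnitude_sigma:
            raise ValueError("within_meta_sd must be below the marginal log-sd")
        if self.g_fraction + self.g_missing_n_fraction > 1:
            raise ValueError("metric fractions must sum to at most 1")


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form targets the analysis pipeline should recover."""

    true_q25: float
    true_q50: float
    true_q75: float
    true_year_slope: float
    true_logn_slope: float
    magnitude_median: float
    magnitude_sigma: float
    outlier_threshold: float
    per_meta_se: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (self.true_q25 <= self.true_q50 <= self.true_q75):
            raise ValueError("ground-truth quantiles must be non-decreasing")


def _truncated_law_quantiles(cfg: SyntheticConfig) -> tuple[float, float, float]:
    """Exact q25/q50/q75 of the magnitude law conditioned on [0, threshold]."""
    if cfg.magnitude_law == "lognormal":
        dist = stats.lognorm(s=cfg.magnitude_sigma, scale=cfg.magnitude_median)
    else:
        # gamma parameterised to share the median and a similar right skew
        shape = 1.2
        dist = stats.gamma(shape, scale=cfg.magnitude_median / stats.gamma(shape).ppf(0.5))
    cap = dist.cdf(cfg.outlier_threshold)
    return tuple(float(dist.ppf(p * cap)) for p in (0.25, 0.50, 0.75))


def _draw_magnitudes(cfg, rng, b_cluster, upper: float) -> np.ndarray:
    """Log-space residual draws, resampled until below ``upper``."""
    n = len(b_cluster)
    if cfg.magnitude_law == "lognormal":
        resid_sd = math.sqrt(cfg.magnitude_sigma**2 - cfg.within_meta_sd**2)
        mu = math.log(cfg.magnitude_median)
        vals = np.exp(mu + b_cluster + rng.normal(0.0, resid_sd, n))
    else:
        shape = 1.2
        scale = cfg.magnitude_median / stats.gamma(shape).ppf(0.5)
        vals = rng.gamma(shape, scale, n) * np.exp(b_cluster)
    for _ in range(1000):
        bad = vals > upper
        if not bad.any():
            return vals
        if cfg.magnitude_law == "lognormal":
            vals[bad] = np.exp(mu + b_cluster[bad] + rng.normal(0.0, resid_sd, bad.sum()))
        else:
            vals[bad] = rng.gamma(shape, scale, bad.sum()) * np.exp(b_cluster[bad])
    raise RuntimeError("magnitude resampling did not converge")


def _draw_group_sizes(rng, median: float, sigma: float, n_min: int, size: int) -> np.ndarray:
    raw = np.rint(rng.lognormal(math.log(median), sigma, size)).astype(int)
    return np.maximum(raw, n_min)


_MACRO_MODALITY = (("ultrasound", 0.93), ("plethysmography", 0.04), ("other", 0.02),
                   ("unknown", 0.01))
_MICRO_MODALITY = (("laser_doppler", 0.29), ("plethysmography", 0.37),
                   ("ultrasound", 0.20), ("other", 0.13), ("unknown", 0.01))
_BIO_PROBS = (("exercise", 0.20), ("supplement_diet", 0.37),
              ("pathophysiology", 0.36), ("other", 0.06), ("unknown", 0.01))


def _pick(rng, table) -> str:
    labels, probs = zip(*table)
    return rng.choice(labels, p=np.array(probs) / sum(probs))


def generate_effect_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[list[EffectRecord], GroundTruth]:
    """Simulate one extraction dataset; deterministic given ``config.seed``.

    Returns the raw (pre-cleaning) records — including the planted flagged
    duplicates and super-threshold outliers, in shuffled row order — together
    with the closed-form ground truth of the retained rows.
    """
    cfg = config or SyntheticConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(2)[0])

    G = cfg.n_meta
    counts = rng.multinomial(cfg.n_effects, np.full(G, 1.0 / G))
    meta_ids = np.repeat([f"M{g + 1:03d}" for g in range(G)], counts)
    b = np.repeat(rng.normal(0.0, cfg.within_meta_sd, G) if cfg.within_meta_sd > 0
                  else np.zeros(G), counts)
    n = len(meta_ids)

    n_treat = _draw_group_sizes(rng, cfg.n_median_treatment, cfg.n_sigma, cfg.n_min, n)
    n_ctrl = _draw_group_sizes(rng, cfg.n_median_control, cfg.n_sigma, cfg.n_min, n)
    years = rng.integers(cfg.year_range[0], cfg.year_range[1] + 1, n)

    bed_draw = rng.random(n)
    is_micro = (bed_draw >= 0.723) & (bed_draw < 0.996)
    bed_shift = np.where(is_micro, -cfg.bed_log_shift, 0.0)

    # covariate-linked magnitude: additive slopes on centred covariates, then
    # resampled into (0, threshold] so the cleaning rules never fire naturally
    x_logn = np.log10(n_treat + n_ctrl)
    x0 = math.log10(cfg.n_median_treatment + cfg.n_median_control)
    y0 = 0.5 * (cfg.year_range[0] + cfg.year_range[1])
    trend = cfg.logn_slope * (x_logn - x0) + cfg.year_slope * (years - y0)
    mag = _draw_magnitudes(cfg, rng, b + bed_shift, cfg.outlier_threshold) + trend
    for _ in range(1000):
        bad = (mag <= 0.01) | (mag > cfg.outlier_threshold)
        if not bad.any():
            break
        redraw = _draw_magnitudes(
            cfg, rng, (b + bed_shift)[bad], cfg.outlier_threshold
        )
        mag[bad] = redraw + trend[bad]
    else:
        raise RuntimeError("slope injection kept violating the magnitude bounds")

    signs = np.where(rng.random(n) < cfg.sign_negative_prob, -1.0, 1.0)
    es_d = signs * mag
    se_d = np.sqrt(1.0 / n_treat + 1.0 / n_ctrl + es_d**2 / (2.0 * (n_treat + n_ctrl)))

    u = rng.random(n)
    g_missing = u < cfg.g_missing_n_fraction
    g_with_n = (~g_missing) & (u < cfg.g_missing_n_fraction + cfg.g_fraction)
    as_g = g_missing | g_with_n

    records: list[EffectRecord] = []
    for i in range(n):
        value, lo_se = es_d[i], se_d[i]
        metric = ESMetric.HEDGES_G if as_g[i] else ESMetric.COHENS_D
        if as_g[i]:
            J = correction_factor(int(n_treat[i] + n_ctrl[i]))
            value, lo_se = value * J, lo_se * J
        bed = VesselBed.MICRO if is_micro[i] else (
            VesselBed.MACRO if bed_draw[i] < 0.723 else VesselBed.UNKNOWN
        )
        modality = _pick(rng, _MICRO_MODALITY if bed is VesselBed.MICRO
                         else _MACRO_MODALITY)
        records.append(
            EffectRecord(
                record_id=f"e{i + 1:05d}",
                meta_id=str(meta_ids[i]),
                es_value=float(value),
                es_metric=metric,
                ci_lower=float(value - _Z95 * lo_se),
                ci_upper=float(value + _Z95 * lo_se),
                n_treatment=None if g_missing[i] else int(n_treat[i]),
                n_control=None if g_missing[i] else int(n_ctrl[i]),
                year=int(years[i]),
                vessel_bed=bed,
                modality=Modality(modality),
                bio_category=BioCategory(_pick(rng, _BIO_PROBS)),
            )
        )

    # planted violations: flagged copies of real rows, then tail outliers
    if cfg.dup_count:
        for j, idx in enumerate(rng.choice(n, size=min(cfg.dup_count, n), replace=False)):
            records.append(
                dataclasses.replace(
                    records[int(idx)], record_id=f"dup{j + 1:03d}", is_duplicate=True
                )
            )
    for j in range(cfg.outlier_count):
        big = cfg.outlier_threshold + rng.uniform(0.5, 3.0)
        sign = -1.0 if rng.random() < cfg.sign_negative_prob else 1.0
        value = sign * big
        records.append(
            EffectRecord(
                record_id=f"out{j + 1:03d}",
                meta_id=str(meta_ids[int(rng.integers(0, n))]),
                es_value=float(value),
                es_metric=ESMetric.COHENS_D,
                ci_lower=float(value - _Z95 * 1.0),
                ci_upper=float(value + _Z95 * 1.0),
                n_treatment=int(_draw_group_sizes(rng, cfg.n_median_treatment,
                                                  cfg.n_sigma, cfg.n_min, 1)[0]),
                n_control=int(_draw_group_sizes(rng, cfg.n_median_control,
                                                cfg.n_sigma, cfg.n_min, 1)[0]),
                year=int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1)),
            )
        )

    order = rng.permutation(len(records))
    records = [records[int(i)] for i in order]

    q25, q50, q75 = _truncated_law_quantiles(cfg)
    truth = GroundTruth(
        true_q25=q25,
        true_q50=q50,
        true_q75=q75,
        true_year_slope=cfg.year_slope,
        true_logn_slope=cfg.logn_slope,
        magnitude_median=cfg.magnitude_median,
        magnitude_sigma=cfg.magnitude_sigma,
        outlier_threshold=cfg.outlier_threshold,
    )
    return records, truth


def generate_meta_dataset(
    config: SyntheticConfig | None = None,
    *,
    se_median: float = 0.18,
    se_sigma: float = 0.5,
    summary_mean: float = 0.10,
    summary_sd: float = 0.55,
) -> tuple[list[MetaRecord], GroundTruth]:
    """Simulate the meta-analysis summary table (one row per cluster).

    Summary effects are mixed-sign normal draws; per-meta standard errors are
    lognormal around ``se_median``; the reported 95% CI is symmetric and
    exactly consistent with the se, so CI-derived standard errors match the
    generated ones to floating precision.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    ses = rng.lognormal(math.log(se_median), se_sigma, cfg.n_meta)
    effects = rng.normal(summary_mean, summary_sd, cfg.n_meta)
    records = [
        MetaRecord(
            meta_id=f"M{g + 1:03d}",
            summary_es=float(effects[g]),
            ci_lower=float(effects[g] - _Z95 * ses[g]),
            ci_upper=float(effects[g] + _Z95 * ses[g]),
            se=float(ses[g]),
        )
        for g in range(cfg.n_meta)
    ]
    q25, q50, q75 = _truncated_law_quantiles(cfg)
    truth = GroundTruth(
        true_q25=q25,
        true_q50=q50,
        true_q75=q75,
        true_year_slope=cfg.year_slope,
        true_logn_slope=cfg.logn_slope,
        magnitude_median=cfg.magnitude_median,
        magnitude_sigma=cfg.magnitude_sigma,
        outlier_threshold=cfg.outlier_threshold,
        per_meta_se=tuple(float(s) for s in ses),
    )
    return records, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground-truth JSON sidecar for a generated dataset."""
    Path(path).write_text(
        json.dumps(dataclasses.asdict(truth), indent=2) + "\n", encoding="utf-8"
    )
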