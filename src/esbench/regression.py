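"""Correlates of effect magnitude: cluster-aware regression and LOESS trend.

Effects extracted from the same meta-analysis are correlated, so ordinary
standard errors understate the uncertainty of a magnitude-vs-covariate slope.
:class:`ClusterOLS` fits the bivariate OLS line but draws inference from the
cluster-robust sandwich estimator — scores summed within clusters, the
small-sample factor c = [G/(G-1)]*[(N-1)/(N-k)], and a t reference with G-1
degrees of freedom (the Stata ``vce(cluster)`` convention).  A clustered
bootstrap (resampling whole clusters with replacement) provides a
distribution-free percentile interval for the slope, and a local quadratic
LOESS with tricube weights traces the trend nonparametrically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .records import EffectRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionFit",
    "BootstrapSpec",
    "LoessSpec",
    "ClusterOLS",
    "ClusterOLSResults",
    "fit_cluster_ols",
    "cluster_bootstrap_ci",
    "loess_curve",
    "covariate_from_records",
]

DEFAULT_BOOTSTRAP_SEED = 20211027  # documented default; override per analysis


@dataclass(frozen=True)
class RegressionFit:
    """Slope inference for effect magnitude against one covariate."""

    beta: float
    intercept: float
    se_adj: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n_obs: int
    n_clusters: int

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.beta <= self.ci_upper):
            raise ValueError("confidence interval must bracket the slope")
        if self.se_adj < 0 or self.n_clusters > self.n_obs:
            raise ValueError("invalid fit summary")


@dataclass(frozen=True)
class BootstrapSpec:
    n_replicates: int = 10_000
    seed: int = DEFAULT_BOOTSTRAP_SEED
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class LoessSpec:
    span: float = 0.75
    degree: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must be in (0, 1]")
        if self.degree < 0:
            raise ValueError("degree must be non-negative")


def _validate_xyg(y, x, cluster_ids):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    g = np.asarray(cluster_ids)
    if not (len(y) == len(x) == len(g)):
        raise ValueError("y, x and cluster_ids must have equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; slope is not identified")
    codes = pd.factorize(g)[0]
    if codes.max() < 1:
        raise ValueError("cluster-robust inference needs at least 2 clusters")
    return y, x, codes


class ClusterOLS:
    """Bivariate OLS model of a response on one covariate with clustered errors.

    Parameters
    ----------
    y, x : array-like
        Response (effect magnitudes) and covariate, equal length >= 3.
    cluster_ids : array-like
        Cluster labels (parent meta-analysis of each effect); >= 2 distinct.
    """

    def __init__(self, y, x, cluster_ids):
        self.y, self.x, self._codes = _validate_xyg(y, x, cluster_ids)
        self.n_obs = len(self.y)
        self.n_clusters = int(self._codes.max()) + 1

    @classmethod
    def from_records(
        cls,
        records: Sequence[EffectRecord],
        covariate: str,
        *,
        log_base: float = 10.0,
    ) -> "ClusterOLS":
        """Build the magnitude-vs-covariate model from harmonized records.

        ``covariate`` is ``"year"`` or ``"log_n"`` (logarithm of the combined
        sample size, base ``log_base``).  Records missing the covariate are
        dropped with a logged count.
        """
        y, x, g = covariate_from_records(records, covariate, log_base=log_base)
        return cls(y, x, g)

    def fit(self, *, ci_level: float = 0.95, reference: str = "t") -> "ClusterOLSResults":
        """Fit OLS and return cluster-robust inference for the slope.

        ``reference="t"`` (default) uses a t distribution with G-1 degrees of
        freedom for the CI and p-value; ``"normal"`` uses the z reference.
        """
        X = sm.add_constant(self.x)
        use_t = reference == "t"
        res = sm.OLS(self.y, X).fit(
            cov_type="cluster", cov_kwds={"groups": self._codes}, use_t=use_t
        )
        se = float(res.bse[1])
        beta = float(res.params[1])
        alpha = 1.0 - ci_level
        if use_t:
            crit = stats.t.ppf(1 - alpha / 2, self.n_clusters - 1)
            p = 2 * stats.t.sf(abs(beta / se), self.n_clusters - 1) if se > 0 else (
                1.0 if beta == 0 else 0.0
            )
        else:
            crit = stats.norm.ppf(1 - alpha / 2)
            p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
        fit = RegressionFit(
            beta=beta,
            intercept=float(res.params[0]),
            se_adj=se,
            ci_lower=beta - crit * se,
            ci_upper=beta + crit * se,
            p_value=float(p),
            n_obs=self.n_obs,
            n_clusters=self.n_clusters,
        )
        return ClusterOLSResults(model=self, fit=fit, ci_level=ci_level, reference=reference)


@dataclass(frozen=True)
class ClusterOLSResults:
    """Results wrapper carrying the slope inference and optional bootstrap CI."""

    model: ClusterOLS
    fit: RegressionFit
    ci_level: float
    reference: str
    bootstrap_ci: tuple[float, float] | None = None

    def __getattr__(self, name):
        # delegate beta, se_adj, ... to the RegressionFit summary
        return getattr(object.__getattribute__(self, "fit"), name)

    def with_bootstrap(self, spec: BootstrapSpec | None = None) -> "ClusterOLSResults":
        """Attach a clustered-bootstrap percentile CI for the slope."""
        spec = spec or BootstrapSpec(ci_level=self.ci_level)
        ci = cluster_bootstrap_ci(self.model.y, self.model.x, self.model._codes, spec)
        return ClusterOLSResults(
            model=self.model,
            fit=self.fit,
            ci_level=self.ci_level,
            reference=self.reference,
            bootstrap_ci=ci,
        )

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Cluster-robust OLS (sandwich over clusters, "
            f"{self.reference} reference, df = G-1)",
            f"  n_obs = {f.n_obs}, n_clusters = {f.n_clusters}",
            f"  beta      = {f.beta: .4f}   SE_adj = {f.se_adj:.4f}",
            f"  {self.ci_level:.0%} CI    = ({f.ci_lower: .4f}, {f.ci_upper: .4f})",
            f"  p-value   = {f.p_value:.4f}",
            f"  intercept = {f.intercept: .4f}",
        ]
        if self.bootstrap_ci is not None:
            lo, hi = self.bootstrap_ci
            lines.append(f"  bootstrap {self.ci_level:.0%} CI = ({lo: .4f}, {hi: .4f})")
        return "\n".join(lines)


def fit_cluster_ols(y, x, cluster_ids, *, ci_level: float = 0.95) -> RegressionFit:
    """Functional shorthand for ``ClusterOLS(y, x, cluster_ids).fit().fit``."""
    return ClusterOLS(y, x, cluster_ids).fit(ci_level=ci_level).fit


def _slopes_from_cluster_moments(M: np.ndarray, draws: np.ndarray) -> np.ndarray:
    """OLS slopes for cluster resamples via per-cluster sufficient statistics.

    ``M`` is (G, 5): per-cluster sums of (1, x, y, x^2, x*y).  Summing rows of
    the drawn clusters reproduces exactly the moments of the stacked resample,
    so the slope equals that of refitting OLS on the resampled rows.
    """
    T = M[draws].sum(axis=1)  # (B, 5)
    n, sx, sy, sxx, sxy = T.T
    denom = n * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, (n * sxy - sx * sy) / denom, np.nan)


def cluster_bootstrap_ci(
    y, x, cluster_ids, spec: BootstrapSpec | None = None
) -> tuple[float, float]:
    """Percentile CI for the OLS slope from a clustered bootstrap.

    Whole clusters are resampled with replacement (all rows of each drawn
    cluster kept), OLS is refit per replicate and the interval is taken at
    the (1-level)/2 and 1-(1-level)/2 quantiles of the replicate slopes.
    Replicates with a degenerate design (constant covariate) are redrawn, up
    to 100 extra rounds, with the count logged.  Deterministic given the seed.
    """
    spec = spec or BootstrapSpec()
    y, x, codes = _validate_xyg(y, x, cluster_ids)
    G = int(codes.max()) + 1
    M = np.zeros((G, 5))
    np.add.at(M, codes, np.column_stack([np.ones_like(x), x, y, x * x, x * y]))

    rng = np.random.default_rng(spec.seed)
    draws = rng.integers(0, G, size=(spec.n_replicates, G))
    slopes = _slopes_from_cluster_moments(M, draws)
    n_degenerate = 0
    for _ in range(100):
        bad = np.isnan(slopes)
        if not bad.any():
            break
        n_degenerate += int(bad.sum())
        redraw = rng.integers(0, G, size=(int(bad.sum()), G))
        slopes[bad] = _slopes_from_cluster_moments(M, redraw)
    else:
        raise RuntimeError("bootstrap kept drawing degenerate designs")
    if n_degenerate:
        logger.info("clustered bootstrap redrew %d degenerate replicates", n_degenerate)
    a = (1.0 - spec.ci_level) / 2.0
    lo, hi = np.quantile(slopes, [a, 1.0 - a])
    return float(lo), float(hi)


def loess_curve(
    x,
    y,
    spec: LoessSpec | None = None,
    grid=None,
) -> np.ndarray:
    """LOESS fit (tricube-weighted local polynomial) evaluated on a grid.

    For each grid point the ``ceil(span * n)`` nearest observations get
    tricube weights ``(1 - (dist/dist_max)^3)^3`` and a degree-``spec.degree``
    weighted polynomial is fitted and evaluated there.  The grid must lie
    within [min(x), max(x)]; extrapolation is refused.
    """
    spec = spec or LoessSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    k = max(spec.degree + 2, math.ceil(spec.span * n))
    if n < k:
        raise ValueError(f"need at least {k} points for span {spec.span}, degree {spec.degree}")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 101)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < x.min() or grid.max() > x.max():
        raise ValueError("grid requests extrapolation beyond the data range")

    fitted = np.empty_like(grid)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for j, x0 in enumerate(grid):
        dist = np.abs(xs - x0)
        idx = np.argpartition(dist, k - 1)[:k]
        dmax = dist[idx].max()
        if dmax == 0:
            w = np.ones(k)
        else:
            w = (1.0 - np.minimum(dist[idx] / dmax, 1.0) ** 3) ** 3
        keep = w > 0
        # guard: keep at least degree+1 points even if boundary weights vanish
        if keep.sum() < spec.degree + 1:
            keep = np.ones(k, dtype=bool)
            w = np.maximum(w, 1e-12)
        coeffs = np.polynomial.polynomial.polyfit(
            xs[idx][keep] - x0, ys[idx][keep], spec.degree, w=np.sqrt(w[keep])
        )
        fitted[j] = coeffs[0]
    return fitted


def covariate_from_records(
    records: Sequence[EffectRecord], covariate: str, *, log_base: float = 10.0
):
    """Extract (magnitude, covariate, cluster) triples for a regression.

    ``covariate="year"`` uses the publication year; ``"log_n"`` uses the
    logarithm (base ``log_base``) of the combined group sample size.  Rows
    missing the covariate are dropped and the count is logged.
    """
    ys, xs, gs = [], [], []
    n_missing = 0
    for r in records:
        if covariate == "year":
            v = r.year
        elif covariate == "log_n":
            v = None if r.n_total is None else math.log(r.n_total, log_base)
        else:
            raise ValueError(f"unknown covariate {covariate!r}")
        if v is None:
            n_missing += 1
            continue
        ys.append(abs(r.es_value))
        xs.append(float(v))
        gs.append(r.meta_id)
    if n_missing:
        logger.info("%s regression: dropped %d records lacking the covariate",
                    covariate, n_missing)
    return np.array(ys), np.array(xs), np.array(gs)
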