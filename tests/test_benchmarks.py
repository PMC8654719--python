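"""Percentile benchmarks, shape statistics and subgroup splits."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from esbench import (
    EffectRecord,
    ESMetric,
    SyntheticConfig,
    VesselBed,
    benchmark_quantiles,
    clean_effects,
    generate_effect_dataset,
    harmonize_all,
    moments,
    subgroup_benchmarks,
)


def hand_quantile(sorted_vals, p):
    """Oracle: linear interpolation at plotting position h = (n-1)p."""
    n = len(sorted_vals)
    h = (n - 1) * p
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def test_hand_interpolation_examples():
    t = benchmark_quantiles([1, 2, 3, 4, 5])
    assert (t.q25, t.q50, t.q75) == (2, 3, 4)
    t = benchmark_quantiles([0, 0, 1, 1])
    assert (t.q25, t.q50, t.q75) == (0.0, 0.5, 1.0)


def test_constant_sample_has_equal_quantiles_and_nan_shape():
    t = benchmark_quantiles([0.7] * 6)
    assert t.q25 == t.q50 == t.q75 == 0.7
    assert math.isnan(t.skewness) and math.isnan(t.kurtosis_excess)


def test_fewer_than_four_values_is_an_error():
    with pytest.raises(ValueError, match="at least 4"):
        benchmark_quantiles([1.0, 2.0, 3.0])


@given(st.lists(st.floats(0, 50, allow_nan=False), min_size=4, max_size=12))
def test_quantiles_match_brute_force_interpolation(values):
    t = benchmark_quantiles(values)
    s = sorted(values)
    for q, p in ((t.q25, 0.25), (t.q50, 0.50), (t.q75, 0.75)):
        assert q == pytest.approx(hand_quantile(s, p), abs=1e-12)


@given(
    st.lists(st.floats(0, 50, allow_nan=False), min_size=4, max_size=30),
    st.floats(0.1, 5, allow_nan=False),
    st.floats(-3, 3, allow_nan=False),
)
def test_affine_equivariance_of_quantiles(values, a, b):
    base = benchmark_quantiles(values)
    scaled = benchmark_quantiles([a * v + b for v in values])
    for q0, q1 in zip((base.q25, base.q50, base.q75), (scaled.q25, scaled.q50, scaled.q75)):
        assert q1 == pytest.approx(a * q0 + b, abs=1e-9)


def test_moments_hand_value_and_symmetry():
    skew, _ = moments([0, 0, 0, 1])
    assert skew == pytest.approx(0.09375 / 0.1875**1.5, abs=1e-12)
    skew, _ = moments([1, 2, 3, 4, 5])
    assert skew == pytest.approx(0.0, abs=1e-12)


def test_moments_large_normal_sample_is_near_gaussian_shape():
    rng = np.random.default_rng(5)
    skew, kurt = moments(rng.normal(size=200_000))
    assert abs(skew) < 0.03 and abs(kurt) < 0.06


def test_moments_reject_zero_variance():
    with pytest.raises(ValueError):
        moments([1.0, 1.0, 1.0, 1.0])


def _bed_record(i, value, bed):
    return EffectRecord(
        record_id=f"r{i}", meta_id="M1", es_value=value,
        es_metric=ESMetric.COHENS_D, vessel_bed=bed,
    )


def test_single_group_subgroup_equals_pooled():
    records = [_bed_record(i, 0.2 * (i + 1), VesselBed.MACRO) for i in range(6)]
    sg = subgroup_benchmarks(records, "vessel_bed")
    assert set(sg.triples) == {"macro"}
    pooled = benchmark_quantiles([abs(r.es_value) for r in records])
    macro = sg.triples["macro"]
    assert (macro.q25, macro.q50, macro.q75) == (pooled.q25, pooled.q50, pooled.q75)


def test_small_subgroup_flagged_insufficient_and_unknowns_counted():
    records = (
        [_bed_record(i, 0.5 + i * 0.1, VesselBed.MACRO) for i in range(5)]
        + [_bed_record(10 + i, 0.3, VesselBed.MICRO) for i in range(3)]
        + [_bed_record(20, 0.4, VesselBed.UNKNOWN)]
    )
    sg = subgroup_benchmarks(records, "vessel_bed")
    assert set(sg.triples) == {"macro"}
    assert sg.insufficient == {"micro": 3}
    assert sg.n_unknown == 1


def test_stochastically_larger_macro_bed_yields_larger_median():
    cfg = SyntheticConfig(seed=21, bed_log_shift=0.6, dup_count=0, outlier_count=0)
    records, _ = generate_effect_dataset(cfg)
    harmonized = harmonize_all(clean_effects(records).retained)
    sg = subgroup_benchmarks(harmonized, "vessel_bed")
    assert sg.triples["macro"].q50 > sg.triples["micro"].q50


@pytest.mark.parametrize("n, tol", [(2_000, 0.08), (32_000, 0.02)])
def test_lognormal_quantile_recovery_within_root_n_tolerance(n, tol):
    # tolerance scales roughly as n^{-1/2}: 4x the sample, half the band
    cfg = SyntheticConfig(
        seed=3, n_effects=n, n_meta=max(40, n // 20), within_meta_sd=0.0,
        logn_slope=0.0, dup_count=0, outlier_count=0,
    )
    records, truth = generate_effect_dataset(cfg)
    harmonized = harmonize_all(clean_effects(records).retained)
    t = benchmark_quantiles([abs(r.es_value) for r in harmonized])
    assert t.q25 == pytest.approx(truth.true_q25, abs=tol)
    assert t.q50 == pytest.approx(truth.true_q50, abs=tol)
    assert t.q75 == pytest.approx(truth.true_q75, abs=tol)
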