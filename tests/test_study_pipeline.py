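"""Study object, batch pipeline and command-line interface."""

import dataclasses
import json
from pathlib import Path

import pandas as pd
import pytest
from click.testing import CliRunner

from esbench import (
    BootstrapSpec,
    EffectSizeStudy,
    PipelineConfig,
    SyntheticConfig,
    generate_effect_dataset,
    generate_meta_dataset,
    run_pipeline,
    write_effects,
)
from esbench.cli import main

BOOT = BootstrapSpec(n_replicates=300, seed=5)


@pytest.fixture(scope="module")
def fitted(default_dataset, meta_dataset):
    records, _ = default_dataset
    metas, _ = meta_dataset
    return EffectSizeStudy(records, metas).fit(bootstrap=BOOT)


def test_results_carry_all_stages(fitted):
    assert fitted.clean.n_retained == 752
    assert fitted.pooled.n_effects == 752
    assert set(fitted.subgroups) == {"vessel_bed", "modality", "bio_category"}
    assert set(fitted.regressions) <= {"year", "log_n"}
    assert set(fitted.power_tables) == {"paired", "two_sample"}
    assert fitted.median_power is not None
    assert fitted.median_power.n_meta == 40


def test_summary_is_human_readable(fitted):
    text = fitted.summary()
    assert "752 retained" in text
    assert "benchmarks" in text and "pairs" in text


def test_power_table_uses_derived_benchmarks(fitted):
    assert list(fitted.table1["d"]) == [
        pytest.approx(fitted.pooled.q25),
        pytest.approx(fitted.pooled.q50),
        pytest.approx(fitted.pooled.q75),
    ]


def _write_inputs(tmp_path, seed=11):
    cfg = SyntheticConfig(seed=seed)
    records, _ = generate_effect_dataset(cfg)
    metas, _ = generate_meta_dataset(cfg)
    effects_csv = tmp_path / "effects.csv"
    write_effects(records, effects_csv)
    meta_csv = tmp_path / "meta.csv"
    pd.DataFrame([dataclasses.asdict(m) for m in metas]).to_csv(meta_csv, index=False)
    return effects_csv, meta_csv


def test_pipeline_writes_reports_and_conserving_manifest(tmp_path):
    effects_csv, meta_csv = _write_inputs(tmp_path)
    cfg = PipelineConfig(
        effects_path=str(effects_csv),
        meta_path=str(meta_csv),
        out_dir=str(tmp_path / "out"),
        bootstrap_replicates=200,
        seed=3,
    )
    paths = run_pipeline(cfg)
    for name in (
        "cleaning_audit.json",
        "benchmarks.csv",
        "regressions.csv",
        "power_table.csv",
        "meta_power.csv",
        "manifest.json",
    ):
        assert name in paths and Path(paths[name]).exists()
    manifest = json.loads(Path(paths["manifest.json"]).read_text())
    counts = manifest["counts"]
    assert counts["n_input"] == (
        counts["n_retained"]
        + counts["n_duplicates_removed"]
        + counts["n_outliers_removed"]
    )
    # the manifest's config re-runs the pipeline bit-identically
    cfg2 = PipelineConfig(**{**manifest["config"],
                             "power_levels": tuple(manifest["config"]["power_levels"]),
                             "delta_grid": tuple(manifest["config"]["delta_grid"]),
                             "out_dir": str(tmp_path / "out2")})
    paths2 = run_pipeline(cfg2)
    for name in ("benchmarks.csv", "regressions.csv", "meta_power.csv"):
        assert Path(paths[name]).read_text() == Path(paths2[name]).read_text()


def test_config_file_round_trip(tmp_path):
    text = (
        'outlier_threshold = 8.0\n'
        'bootstrap_replicates = 150\n'
        'seed = 9\n'
        'effects_path = "x.csv"\n'
        'out_dir = "out"\n'
    )
    p = tmp_path / "cfg.txt"
    p.write_text(text)
    cfg = PipelineConfig.from_file(p)
    assert cfg.bootstrap_replicates == 150 and cfg.seed == 9


def test_cli_simulate_clean_benchmark_power(tmp_path):
    runner = CliRunner()
    out = tmp_path / "sim"
    res = runner.invoke(main, ["simulate", "--out-dir", str(out), "--seed", "4"])
    assert res.exit_code == 0, res.output
    res = runner.invoke(main, ["clean", str(out / "effects.csv")])
    assert res.exit_code == 0
    audit = json.loads(res.output)
    assert audit["n_input"] == audit["n_retained"] + 8
    res = runner.invoke(main, ["benchmark", str(out / "effects.csv")])
    assert res.exit_code == 0 and "pooled" in res.output
    res = runner.invoke(
        main, ["power", "--design", "two_sample", "--d", "1.21", "--power-level", "0.8"]
    )
    assert res.exit_code == 0 and " 12 " in res.output


def test_cli_run_all_bundle_deterministic(tmp_path):
    effects_csv, meta_csv = _write_inputs(tmp_path, seed=8)
    runner = CliRunner()
    outputs = []
    for sub in ("a", "b"):
        res = runner.invoke(
            main,
            [
                "run-all",
                "--effects", str(effects_csv),
                "--meta", str(meta_csv),
                "--out-dir", str(tmp_path / sub),
                "--seed", "77",
                "--replicates", "200",
            ],
        )
        assert res.exit_code == 0, res.output
        outputs.append(
            (tmp_path / sub / "regressions.csv").read_text()
            + (tmp_path / sub / "benchmarks.csv").read_text()
        )
    assert outputs[0] == outputs[1]
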