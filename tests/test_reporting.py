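"""Threshold classification, the end-to-end pipeline and the CLI surface."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from tmtdiff import (
    EffectSpec,
    PipelineError,
    SignificanceThresholds,
    ValidationError,
    classify_features,
    default_design,
    run_pipeline,
    simulate_lsv_table,
    simulate_phospho_psm_table,
    simulate_psm_table,
    write_design,
    write_psm_table,
)
from tmtdiff.cli import main as cli_main
from tmtdiff.splicing import write_lsv_table


def records_frame(rows, columns=("feature_id", "contrast", "log2fc", "q")):
    return pd.DataFrame(rows, columns=list(columns))


class TestClassify:
    def test_rna_gates_strict(self):
        rec = records_frame([
            ("g1", "c1", 1.2, 0.04),   # up
            ("g2", "c1", 1.0, 0.04),   # log2fc not > 1 -> unchanged
            ("g3", "c1", 1.2, 0.05),   # q not < 0.05 -> unchanged
            ("g4", "c1", -1.3, 0.01),  # down
        ])
        s = classify_features(rec, "rna").iloc[0]
        assert (s["n_up"], s["n_down"], s["n_total"]) == (1, 1, 4)

    def test_protein_uses_fdr_point_one(self):
        rec = records_frame([
            ("p1", "c1", 1.5, 0.08),  # passes protein gate, would fail RNA gate
            ("p2", "c1", 1.5, 0.2),
        ])
        s = classify_features(rec, "protein").iloc[0]
        assert s["n_up"] == 1

    def test_phospho_inclusive_twofold_no_fdr(self):
        rec = records_frame(
            [("p1", "c1", 1.0), ("p2", "c1", -1.0), ("p3", "c1", 0.99)],
            columns=("peptide_id", "contrast", "adjusted_log2fc"),
        )
        s = classify_features(rec, "phospho").iloc[0]
        assert (s["n_up"], s["n_down"]) == (1, 1)

    def test_hand_counted_percentages(self):
        rows = [("f%d" % i, "c1", lfc, q) for i, (lfc, q) in enumerate([
            (2.0, 0.01), (1.5, 0.02),           # 2 up
            (-1.4, 0.03),                        # 1 down
            (0.2, 0.01), (2.0, 0.50), (0.0, 1.0), (-0.8, 0.01), (1.01, 0.30),
        ])]
        s = classify_features(records_frame(rows), "rna").iloc[0]
        assert (s["n_up"], s["n_down"], s["n_total"]) == (2, 1, 8)
        assert (s["pct_up"], s["pct_down"]) == (25.0, 12.5)

    def test_unknown_data_type_rejected(self):
        with pytest.raises(ValidationError, match="data_type"):
            classify_features(records_frame([("f", "c", 1.0, 0.5)]), "metabolite")

    def test_record_order_invariance(self):
        rows = [("f%d" % i, "c1", lfc, q)
                for i, (lfc, q) in enumerate([(2.0, 0.01), (0.1, 0.9), (-1.5, 0.02)])]
        s1 = classify_features(records_frame(rows), "rna")
        s2 = classify_features(records_frame(rows[::-1]), "rna")
        pd.testing.assert_frame_equal(s1, s2)


@pytest.fixture()
def synthetic_dataset(tmp_path):
    design = default_design()
    spec = EffectSpec(
        n_proteins=40, frac_proteins_changed=0.1, protein_log2fc=1.5,
        n_phosphopeptides=60, frac_phospho_changed=0.1, phospho_log2fc=1.5,
        noise_sd_log2=0.0, ionization_spread_sd_log2=0.0,
        loading_offsets_log2=np.linspace(-0.3, 0.3, 16), seed=21,
    )
    psms, truth = simulate_psm_table(design, spec)
    phospho, truth = simulate_phospho_psm_table(design, spec, truth)
    lsv, lsv_truth = simulate_lsv_table(50, 0.2, seed=21)
    write_design(design, tmp_path / "design.tsv")
    write_psm_table(psms, tmp_path / "protein_psm.tsv")
    write_psm_table(phospho, tmp_path / "phospho_psm.tsv")
    write_lsv_table(lsv, tmp_path / "lsv.tsv")
    config = {
        "design": str(tmp_path / "design.tsv"),
        "protein_psm": str(tmp_path / "protein_psm.tsv"),
        "phospho_psm": str(tmp_path / "phospho_psm.tsv"),
        "lsv_table": str(tmp_path / "lsv.tsv"),
    }
    return config, truth, lsv_truth, design


class TestRunPipeline:
    def test_end_to_end_matches_ground_truth_at_zero_noise(
        self, tmp_path, synthetic_dataset
    ):
        config, truth, lsv_truth, design = synthetic_dataset
        results = run_pipeline(config, tmp_path / "out")
        # protein classification: planted |log2fc|=1.5 effects are the only
        # calls (strict gates; zero residual variance makes them certain)
        prot = results["protein_differential"].merge(
            truth.protein.assign(
                contrast=lambda d: d["condition"] + " vs " + design.reference_condition,
            ).rename(columns={"protein_accession": "feature_id"}),
            on=["feature_id", "contrast"],
        )
        assert np.allclose(prot["log2fc"], prot["true_log2fc"], atol=1e-9)
        # adjusted phospho equals planted site effect exactly
        adj = results["phospho_adjusted"].merge(
            truth.phospho.assign(
                contrast=lambda d: d["condition"] + " vs " + design.reference_condition,
            ),
            on=["peptide_id", "contrast"],
        )
        assert (adj["status"] == "adjusted").all()
        assert np.allclose(adj["adjusted_log2fc"], adj["site_log2fc"], atol=1e-9)
        # splicing summary equals planted truth
        assert (
            results["splicing_summary"].n_genes_with_significant_lsv
            == lsv_truth["n_significant_genes"]
        )
        expected = (tmp_path / "out" / "classification.tsv").exists()
        assert expected

    def test_rerun_is_byte_identical(self, tmp_path, synthetic_dataset):
        config, *_ = synthetic_dataset

        def digest(d: Path) -> dict:
            return {
                f.name: hashlib.sha256(f.read_bytes()).hexdigest()
                for f in sorted(d.iterdir())
            }

        run_pipeline(config, tmp_path / "out1")
        run_pipeline(config, tmp_path / "out2")
        d1, d2 = digest(tmp_path / "out1"), digest(tmp_path / "out2")
        assert d1 == d2 and len(d1) >= 7

    def test_missing_design_field_aborts_with_name(self, tmp_path):
        with pytest.raises(PipelineError, match="design"):
            run_pipeline({}, tmp_path / "out")
        assert not (tmp_path / "out").exists()

    def test_stage_error_carries_stage_name(self, tmp_path, synthetic_dataset):
        config, *_ = synthetic_dataset
        bad = dict(config)
        bad["phospho_psm"] = config["phospho_psm"]
        del bad["protein_psm"]
        with pytest.raises(PipelineError, match="adjust-phospho"):
            run_pipeline(bad, tmp_path / "out")

    def test_threshold_overrides_respected(self, tmp_path, synthetic_dataset):
        config, *_ = synthetic_dataset
        loose = dict(config, thresholds={"phospho_abs_log2fc": 0.1})
        results = run_pipeline(loose, tmp_path / "loose")
        strict = run_pipeline(config, tmp_path / "strict")
        assert (
            results["phospho_counts"]["n_changed"].sum()
            >= strict["phospho_counts"]["n_changed"].sum()
        )


class TestCli:
    def test_simulate_then_run(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        r = runner.invoke(cli_main, [
            "simulate", "--out-dir", str(data), "--seed", "5",
            "--n-proteins", "25", "--n-phosphopeptides", "30",
            "--noise-sd-log2", "0.1",
        ])
        assert r.exit_code == 0, r.output
        for name in ["design.tsv", "protein_psm.tsv", "phospho_psm.tsv",
                     "lsv_table.tsv", "truth_protein.tsv"]:
            assert (data / name).exists()
        cfg = tmp_path / "config.yaml"
        cfg.write_text(
            "design: {0}/design.tsv\nprotein_psm: {0}/protein_psm.tsv\n"
            "phospho_psm: {0}/phospho_psm.tsv\nlsv_table: {0}/lsv_table.tsv\n".format(data)
        )
        r = runner.invoke(cli_main, [
            "run", "--config", str(cfg), "--out-dir", str(tmp_path / "out"),
        ])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "out" / "protein_differential.tsv").exists()

    def test_splice_count_subcommand(self, tmp_path):
        events, truth = simulate_lsv_table(30, 0.2, seed=2)
        p = tmp_path / "lsv.tsv"
        write_lsv_table(events, p)
        runner = CliRunner()
        r = runner.invoke(cli_main, ["splice-count", "--lsv", str(p)])
        assert r.exit_code == 0, r.output
        assert str(truth["n_significant_genes"]) in r.output

    def test_quantify_rejects_bad_file(self, tmp_path):
        design = default_design()
        write_design(design, tmp_path / "design.tsv")
        (tmp_path / "psm.tsv").write_text("peptide_sequence\tmodifications\n")
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "quantify", "--psm", str(tmp_path / "psm.tsv"),
            "--design", str(tmp_path / "design.tsv"),
            "--out", str(tmp_path / "out.tsv"),
        ])
        assert r.exit_code != 0
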