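"""Threshold classification of differential tables and the end-to-end pipeline.

Classification applies the study's gates per data type: RNA calls need
FDR < 0.05 and |log2FC| > 1 (strict, as printed), protein calls FDR < 0.1
and |log2FC| > 1 (strict), and phosphopeptide calls an inclusive
|adjusted log2FC| >= 1 with no FDR gate (fold-change thresholding of the
protein-normalized values).  Percentages are reported to one decimal of
the per-contrast total.

``run_pipeline`` chains the stages for one configuration file:
quantify -> summarize -> test for the proteome, quantify -> test ->
adjust-phospho -> count for the phosphoproteome, classification of every
differential table, and an optional splicing summary.  All outputs are
deterministic TSVs, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .design import (
    SampleDesign,
    SignificanceThresholds,
    read_config,
    read_design,
    read_psm_table,
    read_records,
    thresholds_from_config,
    write_matrix,
    write_records,
)
from .exceptions import PipelineError, TmtDiffError, ValidationError
from .phospho import adjust_phospho, count_changed
from .quant import collapse_psms, median_normalize
from .splicing import parse_lsv_table, summarize_splicing
from .stats import run_differential
from .summarize import summarize_proteins

logger = logging.getLogger("tmtdiff")

DATA_TYPES = {"rna", "protein", "phospho"}


def classify_features(
    records: pd.DataFrame,
    data_type: str,
    thresholds: SignificanceThresholds | None = None,
) -> pd.DataFrame:
    """Per-contrast up/down counts and percentages under the type's gates.

    ``records`` carries log2fc and q (RNA/protein) or adjusted_log2fc
    (phospho).  Returns one row per contrast with n_total, n_up, n_down,
    pct_up and pct_down (one decimal).
    """
    thresholds = thresholds or SignificanceThresholds()
    if data_type not in DATA_TYPES:
        raise ValidationError(
            f"unknown data_type {data_type!r}; expected one of {sorted(DATA_TYPES)}"
        )
    rows = []
    for contrast in dict.fromkeys(records["contrast"]):
        sub = records[records["contrast"] == contrast]
        n_total = len(sub)
        if data_type == "phospho":
            thr = thresholds.phospho_abs_log2fc
            up = int((sub["adjusted_log2fc"] >= thr).sum())
            down = int((sub["adjusted_log2fc"] <= -thr).sum())
        else:
            fdr = thresholds.rna_fdr if data_type == "rna" else thresholds.protein_fdr
            thr = (
                thresholds.rna_abs_log2fc
                if data_type == "rna"
                else thresholds.protein_abs_log2fc
            )
            passing = sub["q"] < fdr
            up = int((passing & (sub["log2fc"] > thr)).sum())
            down = int((passing & (sub["log2fc"] < -thr)).sum())
        rows.append(
            {
                "data_type": data_type,
                "contrast": contrast,
                "n_total": n_total,
                "n_up": up,
                "n_down": down,
                "pct_up": round(100.0 * up / n_total, 1) if n_total else 0.0,
                "pct_down": round(100.0 * down / n_total, 1) if n_total else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["data_type", "contrast", "n_total", "n_up", "n_down",
                 "pct_up", "pct_down"],
    )


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis described by a configuration mapping.

    Configuration keys: ``design`` (required), ``protein_psm``,
    ``phospho_psm``, ``rna_differential``, ``lsv_table`` (each optional),
    ``thresholds`` (overrides), ``out_dir``, ``keep_shared_peptides``,
    ``median_polish`` ({tol, max_iter}), ``drop_unmatched_phospho``.
    Returns a dict of the in-memory results; every table is also written
    under ``out_dir``.
    """
    if not isinstance(config, dict):
        config = read_config(config)
    if "design" not in config:
        raise PipelineError("config", "missing required field 'design'")
    out_dir = Path(out_dir or config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = thresholds_from_config(config)
    mp_cfg = config.get("median_polish", {})
    tol = float(mp_cfg.get("tol", 1e-4))
    max_iter = int(mp_cfg.get("max_iter", 20))
    keep_shared = bool(config.get("keep_shared_peptides", False))

    results: dict = {"thresholds": thresholds}
    run_log = {
        "tmtdiff_version": __version__,
        "config": {k: str(v) for k, v in config.items()},
    }

    design = _stage("design", read_design, config["design"])
    results["design"] = design
    classifications = []

    protein_records = None
    if config.get("protein_psm"):
        psms = _stage("quantify", read_psm_table, config["protein_psm"], design)
        peptides = _stage(
            "quantify",
            lambda p: median_normalize(collapse_psms(p, allow_shared=keep_shared)),
            psms,
        )
        write_matrix(peptides.values, out_dir / "peptide_matrix.tsv")
        proteins = _stage(
            "summarize", summarize_proteins, peptides, tol, max_iter, keep_shared
        )
        write_matrix(proteins, out_dir / "protein_matrix.tsv")
        protein_records = _stage("test", run_differential, proteins, design)
        write_records(protein_records, out_dir / "protein_differential.tsv")
        results["protein_matrix"] = proteins
        results["protein_differential"] = protein_records
        classifications.append(
            classify_features(protein_records, "protein", thresholds)
        )
        logger.info("proteome: %d proteins, %d contrasts",
                    len(proteins), protein_records["contrast"].nunique())

    if config.get("phospho_psm"):
        psms = _stage("quantify", read_psm_table, config["phospho_psm"], design)
        peptides = _stage(
            "quantify",
            lambda p: median_normalize(collapse_psms(p, allow_shared=True)),
            psms,
        )
        write_matrix(peptides.values, out_dir / "phospho_peptide_matrix.tsv")
        matrix = peptides.values.copy()
        meta = pd.DataFrame(
            {"protein_accession": peptides.protein_accessions}, index=matrix.index
        )
        matrix.index = pd.Index(peptides.feature_ids(), name="feature_id")
        meta.index = matrix.index
        phospho_records = _stage(
            "test", run_differential, matrix, design, None, meta
        )
        write_records(phospho_records, out_dir / "phospho_differential.tsv")
        results["phospho_differential"] = phospho_records
        if protein_records is None:
            raise PipelineError(
                "adjust-phospho",
                "phospho adjustment requires protein_psm in the same run",
            )
        adjusted = _stage(
            "adjust-phospho",
            adjust_phospho,
            phospho_records,
            protein_records,
            bool(config.get("drop_unmatched_phospho", False)),
        )
        write_records(adjusted, out_dir / "phospho_adjusted.tsv")
        counts = count_changed(adjusted, thresholds.phospho_abs_log2fc)
        write_records(counts, out_dir / "phospho_counts.tsv")
        results["phospho_adjusted"] = adjusted
        results["phospho_counts"] = counts
        classifications.append(classify_features(adjusted, "phospho", thresholds))

    if config.get("rna_differential"):
        rna = _stage("classify", read_records, config["rna_differential"])
        results["rna_differential"] = rna
        classifications.append(classify_features(rna, "rna", thresholds))

    if classifications:
        summary = pd.concat(classifications, ignore_index=True)
        write_records(summary, out_dir / "classification.tsv")
        results["classification"] = summary

    if config.get("lsv_table"):
        events = _stage("splice-count", parse_lsv_table, config["lsv_table"])
        summary = summarize_splicing(
            events, thresholds, comparison=str(config.get("comparison", ""))
        )
        write_records(summary.to_frame(), out_dir / "splicing_summary.tsv")
        results["splicing_summary"] = summary

    import json

    (out_dir / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n"
    )
    return results


def _stage(name: str, fn, *args):
    """Run one pipeline stage, converting failures to a named error."""
    try:
        return fn(*args)
    except TmtDiffError as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(name, str(exc)) from exc
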