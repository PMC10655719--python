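"""Counting significant local splice variations (LSVs) from VOILA-style tables.

An LSV (local splice variation) groups the splice-junction and
intron-retention events sharing a source or target exon.  Upstream
inference (MAJIQ/VOILA) supplies, per event, the expected change in
percent spliced inclusion E[dPSI] and the posterior probability that
|dPSI| exceeds a threshold (0.20 here).  An event is significant when
that posterior exceeds 0.95 (strictly); an LSV is significant when at
least one of its events is; a gene is counted once however many of its
LSVs change.  Directional tallies split exon-skipping junctions and
retained introns by the sign of E[dPSI].
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .design import SignificanceThresholds
from .exceptions import FormatError, ValidationError

LSV_COLUMNS = ["gene_id", "lsv_id", "event_kind", "exon_skip", "e_dpsi", "p_ge_threshold"]
EVENT_KINDS = {"junction", "intron_retention"}


@dataclass
class SplicingSummary:
    comparison: str
    n_events: int
    n_significant_events: int
    n_significant_lsvs: int
    n_genes_with_significant_lsv: int
    exon_skip_up: int
    exon_skip_down: int
    intron_retention_up: int
    intron_retention_down: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


def parse_lsv_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a VOILA-style event table (TSV).

    Expected columns: gene_id, lsv_id, event_kind in {junction,
    intron_retention}, exon_skip (0/1; whether the junction bypasses an
    annotated exon), e_dpsi in [-1, 1] and p_ge_threshold in [0, 1].
    Row numbers in error messages refer to data rows (header = row 0).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: LSV table missing column(s): {missing}")
    bad_kind = ~df["event_kind"].isin(EVENT_KINDS)
    if bad_kind.any():
        row = int(df.index[bad_kind][0]) + 1
        raise ValidationError(
            f"{path}: unknown event_kind {df.loc[row - 1, 'event_kind']!r} at row {row}"
        )
    for col, lo, hi in [("e_dpsi", -1.0, 1.0), ("p_ge_threshold", 0.0, 1.0)]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < lo) | (vals > hi)
        if bad.any():
            row = int(df.index[bad][0]) + 1
            raise ValidationError(
                f"{path}: {col} value {df.loc[row - 1, col]!r} outside "
                f"[{lo}, {hi}] at row {row}"
            )
        df[col] = vals
    df["exon_skip"] = df["exon_skip"].astype(int).astype(bool)
    return df[LSV_COLUMNS]


def write_lsv_table(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    out["exon_skip"] = out["exon_skip"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def significant_events(
    events: pd.DataFrame, thresholds: SignificanceThresholds | None = None
) -> pd.DataFrame:
    """Flag events with posterior > confidence (strict) and their direction."""
    thresholds = thresholds or SignificanceThresholds()
    out = events.copy()
    out["significant"] = out["p_ge_threshold"] > thresholds.dpsi_confidence
    out["direction"] = out["e_dpsi"].map(
        lambda d: "up" if d > 0 else ("down" if d < 0 else "none")
    )
    return out


def summarize_splicing(
    events: pd.DataFrame,
    thresholds: SignificanceThresholds | None = None,
    comparison: str = "",
) -> SplicingSummary:
    """Tally significant events, LSVs and genes for one comparison."""
    flagged = significant_events(events, thresholds)
    sig = flagged[flagged["significant"]]
    sig_lsvs = sig["lsv_id"].unique()
    sig_genes = sig["gene_id"].unique()
    skips = sig[(sig["event_kind"] == "junction") & sig["exon_skip"]]
    introns = sig[sig["event_kind"] == "intron_retention"]
    return SplicingSummary(
        comparison=comparison,
        n_events=int(len(events)),
        n_significant_events=int(len(sig)),
        n_significant_lsvs=int(len(sig_lsvs)),
        n_genes_with_significant_lsv=int(len(sig_genes)),
        exon_skip_up=int((skips["e_dpsi"] > 0).sum()),
        exon_skip_down=int((skips["e_dpsi"] < 0).sum()),
        intron_retention_up=int((introns["e_dpsi"] > 0).sum()),
        intron_retention_down=int((introns["e_dpsi"] < 0).sum()),
    )
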