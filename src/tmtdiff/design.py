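"""Experiment design, significance thresholds and tabular I/O.

Every stage of the pipeline shares one :class:`SampleDesign` that maps TMT
channels to biological samples (cell line, treatment, timepoint, replicate)
and designates the reference condition that all contrasts are taken against.
In the study this package models, DMSO-treated iDUX4 myoblasts are that
reference.

All tables are plain tab-separated text.  Missing intensities are encoded as
empty fields, never as zeros; zeros in an intensity column are treated as
missing downstream because log2(0) is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import DesignError, FormatError, ValidationError

PSM_KEY_COLUMNS = ["peptide_sequence", "modifications", "charge", "protein_accession"]
ION_COLUMNS = ["peptide_sequence", "modifications", "charge"]

DESIGN_COLUMNS = [
    "sample_id",
    "channel",
    "cell_line",
    "treatment",
    "timepoint_h",
    "replicate",
    "is_reference",
]

#: separator joining accessions of a shared (multi-protein) peptide
SHARED_ACCESSION_SEP = ";"

_FLOAT_FORMAT = "%.10g"


def condition_label(cell_line: str, treatment: str, timepoint_h: float) -> str:
    """Derive the condition label from its three components.

    Pure function: the label is ``{cell_line}.{treatment}.{timepoint}h`` with
    the timepoint printed without trailing zeros (``14`` not ``14.0``).
    """
    t = float(timepoint_h)
    return f"{cell_line}.{treatment}.{t:g}h"


@dataclass(frozen=True)
class SignificanceThresholds:
    """Significance gates used when classifying differential records.

    RNA calls use FDR < ``rna_fdr`` and |log2FC| > ``rna_abs_log2fc``
    (strict); protein calls use FDR < ``protein_fdr`` with the same strict
    fold-change gate; phosphopeptides use the inclusive twofold rule
    |adjusted log2FC| >= ``phospho_abs_log2fc`` with no FDR gate.  Splicing
    events are significant when the posterior probability of a |dPSI| >=
    ``dpsi_threshold`` change exceeds ``dpsi_confidence`` (strict).
    """

    rna_fdr: float = 0.05
    rna_abs_log2fc: float = 1.0
    protein_fdr: float = 0.1
    protein_abs_log2fc: float = 1.0
    phospho_abs_log2fc: float = 1.0
    dpsi_threshold: float = 0.20
    dpsi_confidence: float = 0.95

    def __post_init__(self) -> None:
        for name in ("rna_fdr", "protein_fdr", "dpsi_threshold", "dpsi_confidence"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        for name in ("rna_abs_log2fc", "protein_abs_log2fc", "phospho_abs_log2fc"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    def with_overrides(self, **kwargs: float) -> "SignificanceThresholds":
        known = {f.name for f in fields(self)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValidationError(f"unknown threshold name(s): {sorted(unknown)}")
        return replace(self, **kwargs)


@dataclass
class SampleDesign:
    """The channel-to-sample mapping for a single TMT plex.

    ``table`` has one row per sample with the columns in
    :data:`DESIGN_COLUMNS` plus the derived ``condition`` column.  Exactly
    one condition carries the reference flag.
    """

    table: pd.DataFrame
    reference_condition: str = field(init=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise DesignError(f"design table missing column(s): {missing}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise DesignError(f"duplicate sample_id(s): {dup}")
        if t["channel"].duplicated().any():
            dup = t.loc[t["channel"].duplicated(), "channel"].tolist()
            raise DesignError(f"duplicate channel(s) within the plex: {dup}")
        if (t["timepoint_h"].astype(float) < 0).any():
            raise DesignError("timepoint_h must be non-negative")
        if (t["replicate"].astype(int) < 1).any():
            raise DesignError("replicate must be a positive integer")
        t = t.copy()
        t["condition"] = [
            condition_label(cl, tr, tp)
            for cl, tr, tp in zip(t["cell_line"], t["treatment"], t["timepoint_h"])
        ]
        ref = sorted(set(t.loc[t["is_reference"].astype(bool), "condition"]))
        if len(ref) != 1:
            raise DesignError(
                f"exactly one reference condition required, found {len(ref)}: {ref}"
            )
        self.table = t.reset_index(drop=True)
        self.reference_condition = ref[0]

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        return list(dict.fromkeys(self.table["condition"]))

    def condition_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise DesignError(f"unknown sample_id: {sample_id}")
        return row["condition"].iloc[0]

    @property
    def condition_map(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["condition"]))

    def non_reference_conditions(self) -> list[str]:
        return [c for c in self.conditions if c != self.reference_condition]


def read_design(path: str | Path) -> SampleDesign:
    """Read a sample-design TSV (columns in :data:`DESIGN_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "channel": str})
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: design file missing column(s): {missing}")
    df["is_reference"] = _parse_bool_column(df["is_reference"], "is_reference")
    return SampleDesign(df[DESIGN_COLUMNS])


def write_design(design: SampleDesign, path: str | Path) -> None:
    out = design.table[DESIGN_COLUMNS].copy()
    out["is_reference"] = out["is_reference"].astype(bool).astype(int)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def _parse_bool_column(col: pd.Series, name: str) -> pd.Series:
    mapping = {
        "1": True, "0": False, "true": True, "false": False,
        "yes": True, "no": False,
    }
    out = []
    for v in col:
        key = str(v).strip().lower()
        if key not in mapping:
            raise FormatError(f"column {name}: cannot interpret {v!r} as boolean")
        out.append(mapping[key])
    return pd.Series(out, index=col.index)


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

@dataclass
class PsmTable:
    """PSM-level reporter-ion intensities, one intensity column per sample.

    A peptide ion is the key (peptide_sequence, modifications, charge);
    multiple PSM rows per ion per sample are allowed and are collapsed later
    by keeping the maximum intensity.  Intensities are non-negative raw
    reporter units; empty cells mean "not observed".
    """

    table: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in PSM_KEY_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"PSM table missing column(s): {missing}")
        for s in self.sample_ids:
            if s not in self.table.columns:
                raise FormatError(f"PSM table missing intensity column for sample {s!r}")
            vals = self.table[s]
            if not pd.api.types.is_numeric_dtype(vals):
                raise ValidationError(f"non-numeric intensity in column {s!r}")
            if (vals.dropna() < 0).any():
                raise ValidationError(f"negative intensity in column {s!r}")

    def __len__(self) -> int:
        return len(self.table)


def read_psm_table(path: str | Path, design: SampleDesign) -> PsmTable:
    """Read a PSM TSV whose header names every sample in ``design``."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in ION_COLUMNS[:2]})
    for s in design.sample_ids:
        if s not in df.columns:
            raise FormatError(
                f"{path}: missing intensity column for designed sample {s!r}"
            )
    for s in design.sample_ids:
        try:
            df[s] = pd.to_numeric(df[s])
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"{path}: non-numeric intensity in column {s!r}: {exc}"
            ) from exc
    df["charge"] = df["charge"].astype(int)
    if (df["charge"] < 1).any():
        raise ValidationError(f"{path}: charge must be a positive integer")
    df["modifications"] = df["modifications"].fillna("")
    return PsmTable(df[PSM_KEY_COLUMNS + design.sample_ids], design.sample_ids)


def write_psm_table(psms: PsmTable, path: str | Path) -> None:
    psms.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Feature-by-sample matrices and differential tables
# ---------------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature-by-sample matrix TSV (index column(s) preserved)."""
    df.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)


def read_matrix(path: str | Path, index_cols: int | Iterable[str] = 1) -> pd.DataFrame:
    if isinstance(index_cols, int):
        index_cols = list(range(index_cols))
    else:
        index_cols = list(index_cols)
    return pd.read_csv(path, sep="\t", index_col=index_cols)


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    """Write a differential/adjusted/summary record table as TSV."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_config(path: str | Path) -> dict:
    """Read a YAML (or plain ``key: value``) configuration file."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return cfg


def thresholds_from_config(cfg: dict) -> SignificanceThresholds:
    return SignificanceThresholds().with_overrides(**cfg.get("thresholds", {}))


def is_shared_accession(accession: str) -> bool:
    return SHARED_ACCESSION_SEP in str(accession)


def _check_float(x: float, lo: float, hi: float, what: str, where: str = "") -> float:
    x = float(x)
    if not (lo <= x <= hi) or np.isnan(x):
        suffix = f" ({where})" if where else ""
        raise ValidationError(f"{what} must be in [{lo}, {hi}], got {x}{suffix}")
    return x
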