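"""Phospho-to-protein fold-change normalization and regulated-peptide counts.

A phosphopeptide's measured log2 fold change mixes true site-level
regulation with any change in the abundance of its parent protein.
Subtracting the parent protein's log2 fold change for the same contrast
isolates the site-level component:

    adjusted log2FC = raw log2FC - protein log2FC.

Phosphopeptides whose parent protein was not quantified are retained
unadjusted and flagged (dropping them would hide genuine signal from
proteins below proteome coverage); peptides mapping to more than one
protein are flagged ambiguous and left unadjusted.  Regulated peptides are
counted with an inclusive twofold rule, |adjusted log2FC| >= 1 by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import is_shared_accession
from .exceptions import ContrastError, ValidationError

STATUS_ADJUSTED = "adjusted"
STATUS_UNMATCHED = "unmatched"
STATUS_AMBIGUOUS = "ambiguous"


def adjust_phospho(
    phospho: pd.DataFrame,
    proteins: pd.DataFrame,
    drop_unmatched: bool = False,
) -> pd.DataFrame:
    """Normalize phosphopeptide contrasts to their parent-protein contrasts.

    ``phospho`` needs columns feature_id, protein_accession, contrast,
    log2fc; ``proteins`` needs feature_id (the accession), contrast,
    log2fc.  Matching is on (protein_accession, contrast).  Returns one
    record per phosphopeptide and contrast with the raw, protein and
    adjusted log2FC plus a status column.
    """
    needed = {"feature_id", "protein_accession", "contrast", "log2fc"}
    if not needed.issubset(phospho.columns):
        raise ValidationError(
            f"phospho records missing column(s): {sorted(needed - set(phospho.columns))}"
        )
    missing_contrasts = sorted(
        set(phospho["contrast"]) - set(proteins["contrast"])
    )
    if missing_contrasts:
        raise ContrastError(
            "contrast(s) present in phospho but absent from protein records: "
            f"{missing_contrasts}"
        )
    prot = proteins.rename(columns={"feature_id": "protein_accession",
                                    "log2fc": "protein_log2fc"})
    prot = prot[["protein_accession", "contrast", "protein_log2fc"]]

    out = phospho.rename(columns={"log2fc": "raw_log2fc"})[
        ["feature_id", "protein_accession", "contrast", "raw_log2fc"]
    ].merge(prot, on=["protein_accession", "contrast"], how="left")

    ambiguous = out["protein_accession"].map(is_shared_accession).to_numpy()
    matched = out["protein_log2fc"].notna().to_numpy() & ~ambiguous
    out.loc[ambiguous, "protein_log2fc"] = np.nan

    status = np.where(
        ambiguous, STATUS_AMBIGUOUS, np.where(matched, STATUS_ADJUSTED, STATUS_UNMATCHED)
    )
    out["adjusted_log2fc"] = np.where(
        matched, out["raw_log2fc"] - out["protein_log2fc"], out["raw_log2fc"]
    )
    out["status"] = status
    out = out.rename(columns={"feature_id": "peptide_id"})
    if drop_unmatched:
        out = out[out["status"] == STATUS_ADJUSTED].reset_index(drop=True)
    return out


def count_changed(records: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Count regulated phosphopeptides per contrast (boundary inclusive).

    A record counts as changed when |adjusted log2FC| >= ``threshold``
    ("at least a twofold increase or decrease" at the default of 1).
    Returns per-contrast totals split into up and down.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    rows = []
    contrasts = list(dict.fromkeys(records["contrast"])) if len(records) else []
    for contrast in contrasts:
        sub = records.loc[records["contrast"] == contrast, "adjusted_log2fc"]
        up = int((sub >= threshold).sum())
        down = int((sub <= -threshold).sum())
        rows.append(
            {
                "contrast": contrast,
                "n_total": int(len(sub)),
                "n_changed": up + down,
                "n_up": up,
                "n_down": down,
            }
        )
    return pd.DataFrame(
        rows, columns=["contrast", "n_total", "n_changed", "n_up", "n_down"]
    )
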