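"""Reporter-ion quantification: PSM collapse and median normalization.

Collapsing keeps, for every peptide ion (sequence, modifications, charge)
and sample, only the maximum intensity across the PSMs that measured it.
Log2 intensities are then median-aligned across channels under the
equal-loading assumption: each sample is shifted so that its median over
observed values equals the global target median, defined as the median of
the per-sample medians so the intensity scale is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ION_COLUMNS, PSM_KEY_COLUMNS, SHARED_ACCESSION_SEP, PsmTable
from .exceptions import AmbiguousPeptideError, NormalizationError


@dataclass
class PeptideMatrix:
    """Log2 peptide-ion intensities, one row per ion, one column per sample.

    ``values`` is indexed by (peptide_sequence, modifications, charge,
    protein_accession).  ``normalized`` records whether channels have been
    median-aligned.
    """

    values: pd.DataFrame
    normalized: bool = False
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            self.sample_ids = list(self.values.columns)
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise AmbiguousPeptideError(f"duplicate peptide-ion rows: {dup[:5]}")

    @property
    def protein_accessions(self) -> pd.Index:
        return self.values.index.get_level_values("protein_accession")

    def feature_ids(self) -> list[str]:
        """One stable string id per peptide ion (sequence/mods/charge)."""
        return [
            f"{seq}/{mods}/{z}" if mods else f"{seq}//{z}"
            for seq, mods, z, _ in self.values.index
        ]


def collapse_psms(psms: PsmTable, allow_shared: bool = False) -> PeptideMatrix:
    """Collapse PSM rows to one log2 value per peptide ion and sample.

    When an ion was measured several times in a sample only the maximum
    intensity is kept.  Zero intensities are treated as missing (log2
    undefined).  An ion whose rows carry more than one protein accession is
    an error unless ``allow_shared`` is set, in which case the accessions
    are joined with ';' and the ion is flagged as shared downstream.
    """
    df = psms.table
    # resolve protein accession per ion first so conflicts surface early
    acc = df.groupby(ION_COLUMNS, sort=True)["protein_accession"].agg(
        lambda a: sorted(set(a))
    )
    multi = acc[acc.map(len) > 1]
    if len(multi) and not allow_shared:
        ion = multi.index[0]
        raise AmbiguousPeptideError(
            f"peptide ion {ion} maps to multiple proteins {multi.iloc[0]}; "
            "enable shared-peptide handling to keep it"
        )
    acc = acc.map(SHARED_ACCESSION_SEP.join)

    intens = df[ION_COLUMNS + psms.sample_ids].copy()
    intens[psms.sample_ids] = intens[psms.sample_ids].where(
        intens[psms.sample_ids] > 0
    )  # zeros -> missing
    collapsed = intens.groupby(ION_COLUMNS, sort=True)[psms.sample_ids].max()
    values = np.log2(collapsed)
    values["protein_accession"] = acc
    values = values.set_index("protein_accession", append=True)
    return PeptideMatrix(values[psms.sample_ids], normalized=False)


def median_normalize(m: PeptideMatrix) -> PeptideMatrix:
    """Median-align every sample's log2 intensities (equal-loading assumption).

    For each sample the offset (sample median - target) is subtracted from
    all its observed values, where the target is the median of the
    per-sample medians.  Missing cells are untouched.  The operation is
    idempotent: after alignment every per-sample median equals the target,
    so a second application subtracts zero.
    """
    vals = m.values
    n_obs = vals.notna().sum(axis=0)
    empty = n_obs[n_obs == 0]
    if len(empty):
        raise NormalizationError(
            f"sample(s) with no observed values: {list(empty.index)}"
        )
    sample_medians = vals.median(axis=0, skipna=True)
    target = float(np.median(sample_medians.to_numpy()))
    shifted = vals.sub(sample_medians - target, axis=1)
    return PeptideMatrix(shifted, normalized=True, sample_ids=list(m.sample_ids))
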