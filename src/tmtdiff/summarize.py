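"""Protein summarization by Tukey's median polish.

A protein's peptide-ion submatrix (peptides x samples, log2 scale) is
decomposed into overall + row effect + column effect + residual by
alternating row and column median sweeps.  The protein's summary in a
sample is overall + column effect: peptide-specific ionization offsets are
absorbed into the row effects and discarded, which is what makes the
summary robust to which peptides happened to be identified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import is_shared_accession
from .exceptions import ValidationError
from .quant import PeptideMatrix


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iterations: int
    converged: bool

    def fitted(self) -> np.ndarray:
        return (
            self.overall
            + self.row_effects[:, None]
            + self.col_effects[None, :]
        )

    def column_summaries(self) -> np.ndarray:
        """overall + column effects: the per-sample protein summary."""
        return self.overall + self.col_effects


def median_polish(
    y: np.ndarray, tol: float = 1e-4, max_iter: int = 20
) -> MedianPolishResult:
    """Decompose a two-way table into overall + row + column effects.

    Sweeps rows first, then columns, each sweep subtracting the median of
    the observed residuals in that row/column; the medians of the row- and
    column-effect vectors are absorbed into the overall term after each
    half-sweep.  Iteration stops when the change in the sum of absolute
    residuals is at most ``tol``.  Missing values (NaN) are ignored by the
    medians; an all-missing row or column is rejected.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[0] < 1 or y.shape[1] < 1:
        raise ValidationError("median_polish needs a 2-D matrix with >=1 row and column")
    obs = ~np.isnan(y)
    bad_rows = np.where(~obs.any(axis=1))[0]
    if len(bad_rows):
        raise ValidationError(f"all-missing row(s) at index {bad_rows.tolist()}")
    bad_cols = np.where(~obs.any(axis=0))[0]
    if len(bad_cols):
        raise ValidationError(f"all-missing column(s) at index {bad_cols.tolist()}")

    resid = y.copy()
    overall = 0.0
    row_eff = np.zeros(y.shape[0])
    col_eff = np.zeros(y.shape[1])
    last_abs = np.nansum(np.abs(resid))
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        row_med = np.nanmedian(resid, axis=1)
        resid -= row_med[:, None]
        row_eff += row_med
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta

        col_med = np.nanmedian(resid, axis=0)
        resid -= col_med[None, :]
        col_eff += col_med
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta

        cur_abs = np.nansum(np.abs(resid))
        if abs(last_abs - cur_abs) <= tol:
            converged = True
            break
        last_abs = cur_abs
    return MedianPolishResult(
        overall=float(overall),
        row_effects=row_eff,
        col_effects=col_eff,
        residuals=resid,
        n_iterations=n_iter,
        converged=converged,
    )


def summarize_proteins(
    m: PeptideMatrix,
    tol: float = 1e-4,
    max_iter: int = 20,
    include_shared: bool = False,
) -> pd.DataFrame:
    """Summarize a normalized peptide matrix to one protein row per sample.

    Per protein, median polish runs on its peptide-ion submatrix restricted
    to samples with at least one observation; samples without any
    observation for that protein get a missing summary.  A protein with a
    single peptide ion passes through unchanged (the polish is exact there).
    Shared peptides (multi-accession ions) are excluded unless
    ``include_shared``, in which case the ion contributes to every protein
    it lists.
    """
    if not m.normalized:
        raise ValidationError("peptide matrix must be median-normalized first")
    vals = m.values
    accessions = m.protein_accessions
    shared = accessions.map(is_shared_accession)

    groups: dict[str, list[int]] = {}
    for i, (acc, is_sh) in enumerate(zip(accessions, shared)):
        if is_sh:
            if not include_shared:
                continue
            for a in str(acc).split(";"):
                groups.setdefault(a, []).append(i)
        else:
            groups.setdefault(str(acc), []).append(i)

    data = vals.to_numpy()
    out = np.full((len(groups), data.shape[1]), np.nan)
    prot_ids = sorted(groups)
    for r, acc in enumerate(prot_ids):
        sub = data[groups[acc], :]
        sub = sub[~np.all(np.isnan(sub), axis=1), :]
        if sub.shape[0] == 0:
            continue
        observed_cols = ~np.all(np.isnan(sub), axis=0)
        res = median_polish(sub[:, observed_cols], tol=tol, max_iter=max_iter)
        out[r, observed_cols] = res.column_summaries()
    return pd.DataFrame(out, index=pd.Index(prot_ids, name="protein_accession"),
                        columns=vals.columns)
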