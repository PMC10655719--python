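"""Feature-wise linear models, contrasts against the reference and BH FDR.

Each feature (protein or phosphopeptide) is fitted with a one-way
fixed-effects model over all conditions in the design,

    y_st = beta_0 + beta_condition(t) + eps_st,   eps ~ N(0, sigma^2),

estimated by ordinary least squares: condition means, with the residual
variance pooled over every condition that has data.  A contrast of
condition c against the reference r is then

    log2FC = mean_c - mean_r,  SE = sqrt(sigma2 * (1/n_c + 1/n_r)),

with a two-sided Student-t p-value on the pooled residual degrees of
freedom.  With exactly two conditions this reduces to the classical pooled
two-sample t-test.  p-values are corrected per contrast with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .design import SampleDesign
from .exceptions import ContrastError, ValidationError


@dataclass
class FeatureModelFit:
    """One-way OLS fit of a single feature across all conditions."""

    feature_id: str
    condition_means: dict[str, float]
    n_per_condition: dict[str, int]
    residual_variance: float
    residual_df: int

    @property
    def flagged(self) -> bool:
        """True when the variance is inestimable (zero residual df)."""
        return self.residual_df == 0


@dataclass
class ContrastResult:
    feature_id: str
    contrast: str
    log2fc: float
    se: float
    t_stat: float
    df: int
    p_value: float
    degenerate: bool = False


def _groupwise(values: np.ndarray, codes: np.ndarray, n_groups: int):
    """Vectorized per-condition counts/means/RSS for an F x S value matrix."""
    values = np.atleast_2d(values)
    counts = np.zeros((values.shape[0], n_groups))
    means = np.full((values.shape[0], n_groups), np.nan)
    rss = np.zeros(values.shape[0])
    for g in range(n_groups):
        sub = values[:, codes == g]
        n = np.sum(~np.isnan(sub), axis=1)
        counts[:, g] = n
        with np.errstate(invalid="ignore"):
            mu = np.nansum(sub, axis=1) / n
        means[:, g] = np.where(n > 0, mu, np.nan)
        dev = sub - means[:, g][:, None]
        rss += np.nansum(dev * dev, axis=1)
    n_obs = counts.sum(axis=1)
    k = (counts > 0).sum(axis=1)
    df = (n_obs - k).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = np.where(df > 0, rss / np.maximum(df, 1), np.nan)
    return counts.astype(int), means, sigma2, df


def fit_feature(
    values: pd.Series | np.ndarray,
    design: SampleDesign,
    feature_id: str = "feature",
) -> FeatureModelFit:
    """Fit the one-way model for one feature.

    ``values`` is aligned to ``design.sample_ids`` (a Series indexed by
    sample id, or an array in design order).  Missing values are dropped.
    At least two conditions must have data; residual df of zero (one
    observation per condition) yields a flagged fit whose contrasts carry
    missing p-values.
    """
    if isinstance(values, pd.Series):
        vec = values.reindex(design.sample_ids).to_numpy(dtype=float)
    else:
        vec = np.asarray(values, dtype=float)
        if vec.shape[0] != len(design.sample_ids):
            raise ValidationError("values length does not match the design")
    conditions = design.conditions
    codes = np.array(
        [conditions.index(c) for c in design.table["condition"]], dtype=int
    )
    counts, means, sigma2, df = _groupwise(vec[None, :], codes, len(conditions))
    present = counts[0] > 0
    if present.sum() < 2:
        raise ValidationError(
            f"feature {feature_id!r}: need >=2 conditions with observations"
        )
    return FeatureModelFit(
        feature_id=feature_id,
        condition_means={c: float(means[0, i]) for i, c in enumerate(conditions) if present[i]},
        n_per_condition={c: int(counts[0, i]) for i, c in enumerate(conditions) if present[i]},
        residual_variance=float(sigma2[0]) if df[0] > 0 else float("nan"),
        residual_df=int(df[0]),
    )


def contrast_label(condition: str, reference: str) -> str:
    return f"{condition} vs {reference}"


def test_contrast(
    fit: FeatureModelFit, condition: str, reference: str
) -> ContrastResult:
    """Contrast one condition against the reference within a fitted model."""
    for c in (condition, reference):
        if c not in fit.condition_means:
            raise ContrastError(
                f"condition {c!r} absent from fit of {fit.feature_id!r}"
            )
    lfc = fit.condition_means[condition] - fit.condition_means[reference]
    label = contrast_label(condition, reference)
    if fit.flagged:
        return ContrastResult(fit.feature_id, label, lfc, float("nan"),
                              float("nan"), 0, float("nan"))
    s2 = fit.residual_variance
    n_c = fit.n_per_condition[condition]
    n_r = fit.n_per_condition[reference]
    se = float(np.sqrt(s2 * (1.0 / n_c + 1.0 / n_r)))
    if s2 == 0.0:
        # degenerate: no residual variation; a nonzero difference is "certain"
        if lfc != 0.0:
            return ContrastResult(fit.feature_id, label, lfc, 0.0,
                                  float("inf"), fit.residual_df, 0.0,
                                  degenerate=True)
        return ContrastResult(fit.feature_id, label, 0.0, 0.0, 0.0,
                              fit.residual_df, 1.0, degenerate=True)
    t = lfc / se
    p = 2.0 * sps.t.sf(abs(t), fit.residual_df)
    return ContrastResult(fit.feature_id, label, lfc, se, float(t),
                          fit.residual_df, float(p))


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through unadjusted."""
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def run_differential(
    matrix: pd.DataFrame,
    design: SampleDesign,
    contrasts: list[tuple[str, str]] | None = None,
    feature_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit every row of a feature-by-sample matrix and test all contrasts.

    ``contrasts`` defaults to every non-reference condition against the
    reference.  BH correction is applied per contrast across the features
    of this matrix.  ``feature_meta`` (indexed like ``matrix``) is carried
    into the output, e.g. the parent protein accession of a phosphopeptide.
    Returns a tidy table with columns feature_id, contrast, log2fc, se, t,
    df, p, q (+ any metadata columns).
    """
    if contrasts is None:
        contrasts = [
            (c, design.reference_condition)
            for c in design.non_reference_conditions()
        ]
    conditions = design.conditions
    codes = np.array(
        [conditions.index(c) for c in design.table["condition"]], dtype=int
    )
    values = matrix[design.sample_ids].to_numpy(dtype=float)
    counts, means, sigma2, df = _groupwise(values, codes, len(conditions))

    frames = []
    for condition, reference in contrasts:
        for c in (condition, reference):
            if c not in conditions:
                raise ContrastError(f"condition {c!r} not in the design")
        ic, ir = conditions.index(condition), conditions.index(reference)
        n_c, n_r = counts[:, ic].astype(float), counts[:, ir].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lfc = means[:, ic] - means[:, ir]
            se = np.sqrt(sigma2 * (1.0 / n_c + 1.0 / n_r))
            t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf))
            p = np.where(
                df > 0,
                np.where(
                    se > 0,
                    2.0 * sps.t.sf(np.abs(t), np.maximum(df, 1)),
                    np.where(lfc == 0, 1.0, 0.0),
                ),
                np.nan,
            )
        t = np.where(df > 0, t, np.nan)
        p = np.where((n_c > 0) & (n_r > 0), p, np.nan)
        lfc = np.where((n_c > 0) & (n_r > 0), lfc, np.nan)
        frame = pd.DataFrame(
            {
                "feature_id": matrix.index.map(str)
                if matrix.index.nlevels == 1
                else ["/".join(map(str, ix)) for ix in matrix.index],
                "contrast": contrast_label(condition, reference),
                "log2fc": lfc,
                "se": se,
                "t": t,
                "df": df,
                "p": p,
                "q": adjust_bh(p),
            }
        )
        if feature_meta is not None:
            for col in feature_meta.columns:
                frame[col] = feature_meta[col].to_numpy()
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
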