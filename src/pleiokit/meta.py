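"""Fixed-effect inverse-variance-weighted meta-analysis and genomic control."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import KEY_COLS, SummaryStatSet

__all__ = ["GCReport", "ivw_meta", "genomic_control", "CHI2_1_MEDIAN"]

#: median of the chi-squared distribution with one degree of freedom
CHI2_1_MEDIAN = float(stats.chi2.median(1))  # 0.4549364...


@dataclass
class GCReport:
    """Genomic-control outcome: the inflation factor and whether the
    correction was applied (it is one-sided: deflation is never applied)."""

    lambda_gc: float
    applied: bool


def ivw_meta(paired: pd.DataFrame, beta_cols: list[str], se_cols: list[str],
             trait_name: str = "meta", trait_type: str = "case-control",
             ) -> SummaryStatSet:
    """Fixed-effect IVW pooling across studies on a joined record table.

    For each variant, ``beta* = sum(w_i b_i) / sum(w_i)`` with
    ``w_i = 1/se_i^2``; ``se* = sum(w_i)^(-1/2)``;
    ``p = 2 Phi(-|beta*/se*|)``.  A study absent at a variant (NaN beta or
    se) contributes no weight; variants with no contributing study are
    excluded, as are rows with a non-positive stated se.
    """
    if len(beta_cols) != len(se_cols) or not beta_cols:
        raise ValueError("need matching, non-empty beta/se column lists")
    b = paired[beta_cols].to_numpy(float)
    se = paired[se_cols].to_numpy(float)
    bad_se = np.nan_to_num(se, nan=1.0) <= 0
    b = np.where(bad_se, np.nan, b)
    se = np.where(bad_se, np.nan, se)
    contrib = np.isfinite(b) & np.isfinite(se)
    w = np.where(contrib, 1.0 / np.square(se), 0.0)
    wsum = w.sum(axis=1)
    any_study = wsum > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        beta_star = np.where(any_study,
                             np.nansum(np.where(contrib, w * b, 0.0), axis=1) / wsum,
                             np.nan)
        se_star = np.where(any_study, 1.0 / np.sqrt(wsum), np.nan)
        z = beta_star / se_star
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    out = paired.loc[any_study, KEY_COLS].copy()
    out["BETA"] = beta_star[any_study]
    out["SE"] = se_star[any_study]
    out["P"] = p[any_study]
    out["K_STUDIES"] = contrib.sum(axis=1)[any_study]
    for extra in ("EAF", "PANEL_MAF"):
        for c in paired.columns:
            if c.startswith(extra):
                out[extra] = paired.loc[any_study, c].to_numpy()
                break
    return SummaryStatSet(out.reset_index(drop=True), trait_name, trait_type,
                          validate=False)


def genomic_control(s: SummaryStatSet) -> tuple[SummaryStatSet, GCReport]:
    """Genomic-control correction of a set's test statistics.

    lambda = median(z^2) / 0.4549364 with z^2 the chi-squared statistic
    implied by the two-sided p.  If lambda > 1, z^2 is divided by lambda and
    p recomputed (BETA/SE left untouched; downstream use is p-based); if
    lambda <= 1 the statistics are returned unchanged with ``applied=False``.
    """
    if len(s) == 0:
        raise ValueError("cannot genomic-control an empty set")
    if len(s) == 1:
        import warnings
        warnings.warn("genomic control on a single variant is degenerate")
    p = s.df["P"].to_numpy(float)
    chi2 = stats.chi2.isf(np.clip(p, np.finfo(float).tiny, 1.0), 1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    if lam <= 1.0 + 1e-12:   # tolerance absorbs p <-> chi2 round-trip error
        return s.copy(), GCReport(lambda_gc=lam, applied=False)
    p_corr = np.clip(stats.chi2.sf(chi2 / lam, 1), np.finfo(float).tiny, 1.0)
    df = s.df.copy()
    df["P"] = p_corr
    return s.copy(df), GCReport(lambda_gc=lam, applied=True)
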