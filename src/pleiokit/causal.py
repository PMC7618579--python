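"""Two-sample Mendelian randomisation with a colocalisation-based
instrument screen, plus small shared statistics utilities.

``mr_ivw`` pools per-instrument Wald ratios (outcome effect over exposure
effect) by inverse variance, estimating the causal effect of the exposure on
the outcome under the usual instrumental-variable assumptions.  Because a
locus harbouring *distinct* causal variants for exposure and outcome
suggests an effect on the outcome not mediated by the exposure (horizontal
pleiotropy), each instrument's region is screened with approximate-Bayes-
factor colocalisation and instruments whose regional posterior favours
distinct causal variants (PP3) are excluded before pooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .sumstats import KEY_COLS, SummaryStatSet, join_sets

__all__ = [
    "MRResult", "ColocResult", "ColocPriors",
    "mr_ivw", "coloc_abf", "screen_instruments", "bh_adjust", "wald_test",
]

_TINY = np.finfo(float).tiny


@dataclass
class MRResult:
    """IVW causal-effect estimate."""

    theta: float
    se: float
    p: float
    n_instruments: int
    excluded: list[str] = field(default_factory=list)

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        zq = stats.norm.isf((1.0 - level) / 2.0)
        return (self.theta - zq * self.se, self.theta + zq * self.se)


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of association: with trait 1 only (p1),
    trait 2 only (p2), and with both (p12).  Published defaults."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValueError("priors must be positive")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError("p12 should not exceed min(p1, p2)")


@dataclass
class ColocResult:
    """Posterior probabilities of the five regional hypotheses.

    H0 no association; H1/H2 association with one trait only; H3 distinct
    causal variants; H4 one shared causal variant.
    """

    pp: np.ndarray                # PP0..PP4, sums to 1
    log_abf_a: np.ndarray
    log_abf_b: np.ndarray
    priors: ColocPriors
    prior_sd_a: float
    prior_sd_b: float

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def pp3(self) -> float:
        return float(self.pp[3])


def wald_test(est: float, se: float) -> float:
    """Two-sided Wald p-value for H0: parameter = 0."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(min(1.0, 2.0 * stats.norm.sf(abs(est / se))))


def bh_adjust(pvec) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvec, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mr_ivw(instruments: pd.DataFrame, exclude: list[str] | None = None,
           ) -> MRResult:
    """Fixed-effect IVW Mendelian randomisation over an instrument table.

    Columns: SNP, BETA_EXPOSURE, SE_EXPOSURE, BETA_OUTCOME, SE_OUTCOME.
    Per-instrument ratio theta_j = beta_out/beta_exp with
    se_j = se_out/|beta_exp|; pooled theta = sum(theta_j/se_j^2) /
    sum(1/se_j^2); se = sum(1/se_j^2)^(-1/2); two-sided Wald p.  Instruments
    with a zero exposure effect are rejected with a warning; ``exclude``
    drops the named SNPs before pooling (screened-out instruments).
    """
    df = instruments.copy()
    excluded = []
    if exclude:
        excluded = [s for s in exclude if s in set(df["SNP"])]
        df = df[~df["SNP"].isin(set(exclude))]
    zero = df["BETA_EXPOSURE"] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} instrument(s) with zero exposure "
                      "effect rejected")
        excluded += df.loc[zero, "SNP"].tolist()
        df = df[~zero]
    if df.empty:
        raise ValueError("no instruments left after screening")
    if (df["SE_OUTCOME"] <= 0).any() or (df["SE_EXPOSURE"] <= 0).any():
        raise ValueError("non-positive instrument standard errors")

    bx = df["BETA_EXPOSURE"].to_numpy(float)
    by = df["BETA_OUTCOME"].to_numpy(float)
    sy = df["SE_OUTCOME"].to_numpy(float)
    ratio = by / bx
    se_ratio = sy / np.abs(bx)
    w = 1.0 / np.square(se_ratio)
    theta = float(np.sum(w * ratio) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return MRResult(theta=theta, se=se, p=wald_test(theta, se),
                    n_instruments=len(df), excluded=excluded)


def _log_abf(z: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Wakefield approximate Bayes factor (log scale) per SNP:
    r = W/(W + se^2); log ABF = 0.5 log(1 - r) + 0.5 r z^2."""
    w = prior_sd * prior_sd
    r = w / (w + np.square(se))
    return 0.5 * np.log1p(-r) + 0.5 * r * np.square(z)


def coloc_abf(region_a: SummaryStatSet, region_b: SummaryStatSet,
              priors: ColocPriors = ColocPriors(),
              prior_sd_a: float | None = None,
              prior_sd_b: float | None = None) -> ColocResult:
    """ABF colocalisation of two traits over a shared regional SNP list.

    Regions are inner-joined on (CHR, BP, REF, ALT); per SNP and trait the
    Wakefield log-ABF is computed with the trait's prior effect sd (0.2 for
    a quantitative trait, 0.15 for case-control, unless overridden).
    Hypothesis sums are accumulated by log-sum-exp:
    S1 = sum_j ABF_j1, S2 = sum_j ABF_j2, S4 = sum_j ABF_j1 ABF_j2 and
    S3 = S1*S2 - S4 (distinct-variant configurations); unnormalised
    posteriors (1, p1 S1, p2 S2, p1 p2 S3, p12 S4) are normalised to
    PP0..PP4.
    """
    def default_sd(s: SummaryStatSet) -> float:
        return 0.15 if s.trait_type == "case-control" else 0.2

    sd_a = default_sd(region_a) if prior_sd_a is None else prior_sd_a
    sd_b = default_sd(region_b) if prior_sd_b is None else prior_sd_b

    joined = join_sets(region_a, region_b, mode="inner", suffixes=("_a", "_b"))
    if len(joined) < 2:
        raise ValueError("regions share fewer than 2 SNPs")
    za = (joined["BETA_a"] / joined["SE_a"]).to_numpy(float)
    zb = (joined["BETA_b"] / joined["SE_b"]).to_numpy(float)
    labf_a = _log_abf(za, joined["SE_a"].to_numpy(float), sd_a)
    labf_b = _log_abf(zb, joined["SE_b"].to_numpy(float), sd_b)

    log_s1 = logsumexp(labf_a)
    log_s2 = logsumexp(labf_b)
    log_s4 = logsumexp(labf_a + labf_b)
    # S3 = S1*S2 - S4 (sum over ordered pairs of distinct SNPs)
    diff = log_s4 - (log_s1 + log_s2)
    if diff >= 0:
        if diff > 1e-9:
            warnings.warn("S3 < 0 from floating error; clamped at 0")
        log_s3 = -np.inf
    else:
        log_s3 = log_s1 + log_s2 + np.log1p(-np.exp(diff))

    log_unnorm = np.array([
        0.0,
        np.log(priors.p1) + log_s1,
        np.log(priors.p2) + log_s2,
        np.log(priors.p1) + np.log(priors.p2) + log_s3,
        np.log(priors.p12) + log_s4,
    ])
    pp = np.exp(log_unnorm - logsumexp(log_unnorm))
    pp /= pp.sum()
    return ColocResult(pp=pp, log_abf_a=labf_a, log_abf_b=labf_b,
                       priors=priors, prior_sd_a=sd_a, prior_sd_b=sd_b)


def screen_instruments(instruments: pd.DataFrame,
                       regions: dict[str, tuple[SummaryStatSet, SummaryStatSet]],
                       pp3_threshold: float = 0.5,
                       priors: ColocPriors = ColocPriors(),
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude instruments whose regional colocalisation favours distinct
    causal variants.

    ``regions`` maps each instrument's SNP id to its (exposure, outcome)
    regional summary-statistic pair (typically a 100 kb window around the
    instrument).  An instrument is excluded iff its region's PP3 exceeds
    ``pp3_threshold``; instruments with no regional data are kept with a
    warning.  Returns (kept, excluded) tables; the excluded table carries
    the full PP vector.
    """
    keep_rows, drop_rows = [], []
    for _, row in instruments.iterrows():
        snp = row["SNP"]
        pair = regions.get(snp)
        if pair is None:
            warnings.warn(f"no regional data for instrument {snp}; kept")
            keep_rows.append(row)
            continue
        res = coloc_abf(pair[0], pair[1], priors=priors)
        if res.pp3 > pp3_threshold:
            out = row.copy()
            for h in range(5):
                out[f"PP{h}"] = res.pp[h]
            drop_rows.append(out)
        else:
            keep_rows.append(row)
    kept = pd.DataFrame(keep_rows).reset_index(drop=True)
    excluded = pd.DataFrame(drop_rows).reset_index(drop=True)
    return kept, excluded
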