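"""Gene-set enrichment of GWAS signal by order statistics and resampling.

The test asks whether SNPs in (peri-)genic regions of a designated gene set
(e.g. genes harbouring rare variants causal for Mendelian inborn errors of
immunity) carry more association signal than SNPs around equally sized random
gene sets.  Per-SNP test statistics are the chi-squared values implied by the
two-sided p (z²); the observed 50th/90th/95th/99th percentiles of member-SNP
statistics are compared with the same percentiles in ``B`` resampled gene
sets of the same size, and the per-level p-value is the plain proportion of
resamples whose percentile equals or exceeds the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SummaryStatSet

__all__ = ["EnrichmentResult", "build_regions", "annotate_membership",
           "enrichment_test", "DEFAULT_LEVELS", "DEFAULT_FLANK_BP",
           "DEFAULT_REALISATIONS"]

DEFAULT_LEVELS = (50.0, 90.0, 95.0, 99.0)
DEFAULT_FLANK_BP = 50_000
DEFAULT_REALISATIONS = 5_000
#: refuse resampling workloads beyond this many (realisation x gene) pairs
WORKLOAD_CAP = 50_000_000


@dataclass
class EnrichmentResult:
    """Observed region percentiles, resampled null percentiles and empirical
    p-values per percentile level."""

    percentile_levels: tuple
    observed: np.ndarray          # per-level observed percentile of z²
    null_samples: np.ndarray      # B x levels matrix
    p_values: np.ndarray          # per-level plain proportion (0 -> "<1/B")
    n_in_region: int
    B: int
    seed: int

    def p_strings(self) -> list[str]:
        """Per-level p as printed: exact zeroes reported as '< 1/B'."""
        return [f"< {1.0 / self.B:g}" if p == 0.0 else f"{p:g}"
                for p in self.p_values]


def build_regions(genes: pd.DataFrame, flank_bp: int = DEFAULT_FLANK_BP,
                  ) -> pd.DataFrame:
    """Extend each gene body by ``flank_bp`` on both sides, clipped at 1.

    Regions are not merged; overlap is handled at membership time with
    union semantics.
    """
    out = genes.copy()
    out["START"] = np.maximum(1, out["START"] - flank_bp)
    out["END"] = out["END"] + flank_bp
    return out


def annotate_membership(s: SummaryStatSet, regions: pd.DataFrame) -> np.ndarray:
    """Boolean per-SNP flag: inside at least one region (inclusive bounds)."""
    df = s.df
    member = np.zeros(len(df), dtype=bool)
    bp = df["BP"].to_numpy()
    chrom = df["CHR"].astype(str).to_numpy()
    for c, grp in regions.groupby("CHR"):
        on_c = chrom == str(c)
        if not on_c.any():
            continue
        # per-region OR; gene tables are small enough that this is cheap
        for sN, eN in zip(grp["START"].to_numpy(), grp["END"].to_numpy()):
            member |= on_c & (bp >= sN) & (bp <= eN)
    return member


def _member_union_stats(stat: np.ndarray, per_gene_idx: list[np.ndarray],
                        gene_ids: np.ndarray) -> np.ndarray:
    """Statistics of the de-duplicated union of member SNPs of the chosen
    genes (each SNP counted once regardless of multiplicity)."""
    if len(gene_ids) == 0:
        return np.empty(0)
    parts = [per_gene_idx[g] for g in gene_ids]
    idx = np.unique(np.concatenate(parts)) if parts else np.empty(0, int)
    return stat[idx]


def _per_gene_snp_indices(s: SummaryStatSet, regions: pd.DataFrame,
                          ) -> list[np.ndarray]:
    df = s.df
    bp = df["BP"].to_numpy()
    chrom = df["CHR"].astype(str).to_numpy()
    out = []
    by_chrom = {c: np.flatnonzero(chrom == str(c)) for c in regions["CHR"].unique()}
    for c, start, end in zip(regions["CHR"], regions["START"], regions["END"]):
        idx = by_chrom.get(str(c))
        if idx is None or len(idx) == 0:
            out.append(np.empty(0, dtype=np.int64))
            continue
        sub = bp[idx]
        lo = np.searchsorted(sub, start, side="left")
        hi = np.searchsorted(sub, end, side="right")
        out.append(idx[lo:hi])
    return out


def enrichment_test(s: SummaryStatSet, special_genes: pd.DataFrame,
                    all_genes: pd.DataFrame, flank_bp: int = DEFAULT_FLANK_BP,
                    B: int = DEFAULT_REALISATIONS, seed: int = 0,
                    levels: tuple = DEFAULT_LEVELS,
                    exclude_special_from_frame: bool = False,
                    add_one: bool = False) -> EnrichmentResult:
    """Resampling enrichment test of the special gene set.

    Each of ``B`` realisations samples ``len(special_genes)`` genes uniformly
    without replacement from the frame (which includes the special genes
    unless ``exclude_special_from_frame``), rebuilds flanked regions and the
    membership union, and recomputes the percentiles.  ``p_level`` is the
    proportion of realisations whose percentile equals or exceeds the
    observed one (plain proportion by default; ``add_one`` applies the
    (B+1)-denominator correction).  Results are invariant to gene order and
    duplicated gene records.
    """
    if B < 1:
        raise ValueError("need at least one realisation")
    special = special_genes.drop_duplicates(subset="GENE").sort_values("GENE")
    frame = all_genes.drop_duplicates(subset="GENE").sort_values("GENE")
    if exclude_special_from_frame:
        frame = frame[~frame["GENE"].isin(set(special["GENE"]))]
    k = len(special)
    if len(frame) < k:
        raise ValueError("sampling frame smaller than the special set")
    if B * len(frame) > WORKLOAD_CAP:
        raise ValueError(
            f"workload B*|genes| = {B * len(frame)} exceeds the configured cap "
            f"({WORKLOAD_CAP}); lower B or split the frame")

    p = s.df["P"].to_numpy(float)
    stat = stats.chi2.isf(np.clip(p, np.finfo(float).tiny, 1.0), 1)

    frame_regions = build_regions(frame.reset_index(drop=True), flank_bp)
    per_gene_idx = _per_gene_snp_indices(s, frame_regions)

    special_regions = build_regions(special, flank_bp)
    member = annotate_membership(s, special_regions)
    n_in = int(member.sum())
    if n_in == 0:
        raise ValueError("no SNPs fall inside the special regions")
    observed = np.percentile(stat[member], levels)

    rng = np.random.default_rng(seed)
    null_samples = np.empty((B, len(levels)))
    n_frame = len(frame)
    for b in range(B):
        pick = rng.choice(n_frame, size=k, replace=False)
        vals = _member_union_stats(stat, per_gene_idx, pick)
        if len(vals) == 0:
            null_samples[b] = np.nan
            continue
        null_samples[b] = np.percentile(vals, levels)

    valid = ~np.isnan(null_samples[:, 0])
    exceed = (null_samples[valid] >= observed).sum(axis=0)
    denom = valid.sum() + (1 if add_one else 0)
    p_values = (exceed + (1 if add_one else 0)) / denom
    return EnrichmentResult(tuple(levels), observed, null_samples,
                            p_values.astype(float), n_in, B, seed)
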