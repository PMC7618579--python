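"""Synthetic GWAS summary statistics with controllable shared architecture.

The generator emulates the statistical structure that the downstream methods
assume, without simulating individual-level genotypes:

* a variant panel on two chromosomes with uniform MAFs and contiguous LD
  blocks, within which haplotype dosage correlation follows an AR(1) process
  (``corr(i, j) = rho^|i-j|``) and across which r² is exactly 0;
* a gene catalogue with a designated "special" subset (emulating genes that
  harbour Mendelian immune-disorder variants) in which the causal-variant
  probability can be boosted;
* paired traits whose causal effects at shared causal variants are drawn
  bivariate-normal with correlation ``rho_shared``, propagated through block
  LD to marginal effects, and observed with sampling noise at the standard
  error implied by the sample size and allele frequency;
* small regional fixtures for colocalisation and instrument tables for
  Mendelian randomisation.

Everything is bit-reproducible given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SummaryStatSet, VariantPanel

__all__ = [
    "SimConfig",
    "SyntheticGenome",
    "simulate_genome",
    "simulate_trait_pair",
    "simulate_coloc_region",
    "simulate_mr_data",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study.

    Defaults describe the desk-scale study conditions used throughout the
    test-suite: 10,000 SNPs in 500 AR(1) blocks of 20 on two chromosomes,
    1% causal variants, trait heritability proxy 0.2, independent effects
    across the trait pair, quantitative sample size 20,000 per trait and a
    400-gene catalogue with a 40-gene special subset.
    """

    n_snps: int = 10_000
    n_blocks: int = 500
    block_rho: float = 0.9
    maf_range: tuple[float, float] = (0.01, 0.5)
    pi_causal: float = 0.01
    h2_a: float = 0.2
    h2_b: float = 0.2
    rho_shared: float = 0.0
    trait_type_a: str = "quantitative"
    trait_type_b: str = "quantitative"
    n_a: int = 20_000
    n_b: int = 20_000
    n_cases_a: int = 2_000
    n_controls_a: int = 20_000
    n_cases_b: int = 2_000
    n_controls_b: int = 20_000
    n_genes: int = 400
    n_special_genes: int = 40
    enrichment_boost: float = 1.0
    gene_length: int = 20_000
    gene_spacing: int = 110_000
    mean_snp_gap: int = 6_000
    n_chromosomes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_snps, self.n_blocks, self.n_genes) <= 0:
            raise ValueError("counts must be positive")
        if not (0 <= self.block_rho < 1):
            raise ValueError("block_rho must lie in [0, 1)")
        if not (0 <= self.pi_causal <= 1):
            raise ValueError("pi_causal must lie in [0, 1]")
        if not (-1 <= self.rho_shared <= 1):
            raise ValueError("rho_shared must lie in [-1, 1]")
        if self.n_special_genes > self.n_genes:
            raise ValueError("special subset larger than gene catalogue")


@dataclass
class SyntheticGenome:
    """Panel + LD-block partition + gene catalogue for one synthetic study."""

    panel: VariantPanel
    block_id: np.ndarray          # per-SNP block label, blocks contiguous
    block_rho: float
    genes: pd.DataFrame           # CHR, START, END, GENE (1-based inclusive)
    special_genes: list[str]
    config: SimConfig = field(repr=False, default=None)

    @property
    def n_snps(self) -> int:
        return len(self.panel.df)

    def block_slices(self) -> list[slice]:
        """Contiguous index ranges of the LD blocks, in panel order."""
        ids = self.block_id
        starts = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
        ends = np.r_[starts[1:], len(ids)]
        return [slice(int(a), int(b)) for a, b in zip(starts, ends)]


def _effective_n(cfg: SimConfig, which: str) -> float:
    ttype = getattr(cfg, f"trait_type_{which}")
    if ttype == "quantitative":
        return float(getattr(cfg, f"n_{which}"))
    nca, nco = getattr(cfg, f"n_cases_{which}"), getattr(cfg, f"n_controls_{which}")
    return 1.0 / (1.0 / nca + 1.0 / nco)


def _se_per_allele(maf: np.ndarray, cfg: SimConfig, which: str) -> np.ndarray:
    """Standard error of the per-allele effect estimate.

    Quantitative (standardised phenotype): se = 1/sqrt(2 n maf (1-maf)).
    Case-control (log-odds scale): se = sqrt((1/n_case + 1/n_control)
    / (2 maf (1-maf))).
    """
    het = 2.0 * maf * (1.0 - maf)
    ttype = getattr(cfg, f"trait_type_{which}")
    if ttype == "quantitative":
        n = getattr(cfg, f"n_{which}")
        return 1.0 / np.sqrt(n * het)
    nca, nco = getattr(cfg, f"n_cases_{which}"), getattr(cfg, f"n_controls_{which}")
    return np.sqrt((1.0 / nca + 1.0 / nco) / het)


def simulate_genome(cfg: SimConfig) -> SyntheticGenome:
    """Build the variant panel, LD-block partition and gene catalogue.

    Genes are placed non-overlapping with at least ``gene_spacing`` (default
    110 kb) between bodies so that 50 kb flanks never bridge neighbours.
    Raises a configuration error when the catalogue cannot fit on the
    simulated chromosomes.
    """
    rng = np.random.default_rng(cfg.seed)
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1

    chroms, positions = [], []
    chrom_lengths = {}
    for c in range(cfg.n_chromosomes):
        n = int(per_chrom[c])
        gaps = rng.integers(cfg.mean_snp_gap // 2, cfg.mean_snp_gap * 3 // 2 + 1, size=n)
        pos = np.cumsum(gaps)
        chroms.append(np.full(n, str(c + 1)))
        positions.append(pos)
        chrom_lengths[str(c + 1)] = int(pos[-1] + cfg.mean_snp_gap)

    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions).astype(np.int64)

    ref_idx = rng.integers(0, 4, size=cfg.n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=cfg.n_snps)) % 4
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)

    panel = VariantPanel(pd.DataFrame({
        "CHR": chrom, "BP": pos,
        "REF": _BASES[ref_idx], "ALT": _BASES[alt_idx],
        "MAF": maf,
    }))

    # blocks contiguous, proportional per chromosome, never crossing one
    block_id = np.empty(cfg.n_snps, dtype=np.int64)
    next_block = 0
    offset = 0
    for c in range(cfg.n_chromosomes):
        n = int(per_chrom[c])
        n_blk = max(1, round(cfg.n_blocks * n / cfg.n_snps))
        bounds = np.linspace(0, n, n_blk + 1).astype(int)
        for k in range(n_blk):
            block_id[offset + bounds[k]: offset + bounds[k + 1]] = next_block
            next_block += 1
        offset += n

    # gene placement on a deterministic grid with guaranteed spacing
    stride = cfg.gene_length + cfg.gene_spacing
    capacity = sum(max(0, (L - cfg.gene_length) // stride + 1)
                   for L in chrom_lengths.values())
    if capacity < cfg.n_genes:
        raise ValueError(
            f"cannot place {cfg.n_genes} genes with spacing {cfg.gene_spacing} "
            f"on chromosomes of total length {sum(chrom_lengths.values())}")
    slots = []
    for c, L in chrom_lengths.items():
        n_slots = max(0, (L - cfg.gene_length) // stride + 1)
        for k in range(n_slots):
            slots.append((c, 1 + k * stride))
    pick = rng.choice(len(slots), size=cfg.n_genes, replace=False)
    pick.sort()
    genes = pd.DataFrame(
        [{"CHR": slots[i][0], "START": slots[i][1],
          "END": slots[i][1] + cfg.gene_length - 1,
          "GENE": f"G{j:04d}"} for j, i in enumerate(pick)])
    special = rng.choice(genes["GENE"].to_numpy(), size=cfg.n_special_genes,
                         replace=False)
    return SyntheticGenome(panel, block_id, cfg.block_rho, genes,
                           sorted(special.tolist()), cfg)


def _ar1_noise(rng: np.random.Generator, slices: list[slice], n: int,
               rho: float) -> np.ndarray:
    """Standard-normal noise with AR(1) correlation within each block."""
    xi = rng.standard_normal(n)
    if rho == 0.0:
        return xi
    e = np.empty(n)
    w = np.sqrt(1.0 - rho * rho)
    for sl in slices:
        seg = xi[sl]
        out = np.empty(len(seg))
        out[0] = seg[0]
        for i in range(1, len(seg)):
            out[i] = rho * out[i - 1] + w * seg[i]
        e[sl] = out
    return e


def _propagate_through_ld(gamma: np.ndarray, slices: list[slice],
                          rho: float) -> np.ndarray:
    """Marginal standardised effects: lam_j = sum_k rho^|j-k| gamma_k.

    Computed per block with two linear recursions (forward/backward sweep),
    O(n) overall.
    """
    lam = np.empty_like(gamma)
    for sl in slices:
        g = gamma[sl]
        m = len(g)
        fwd = np.empty(m)
        bwd = np.empty(m)
        fwd[0] = g[0]
        for i in range(1, m):
            fwd[i] = rho * fwd[i - 1] + g[i]
        bwd[m - 1] = g[m - 1]
        for i in range(m - 2, -1, -1):
            bwd[i] = rho * bwd[i + 1] + g[i]
        lam[sl] = fwd + bwd - g
    return lam


def _gene_member_mask(genome: SyntheticGenome, gene_names) -> np.ndarray:
    genes = genome.genes[genome.genes["GENE"].isin(set(gene_names))]
    df = genome.panel.df
    mask = np.zeros(len(df), dtype=bool)
    for c, grp in genes.groupby("CHR"):
        on_c = (df["CHR"] == c).to_numpy()
        bp = df["BP"].to_numpy()
        for s, e in zip(grp["START"], grp["END"]):
            mask |= on_c & (bp >= s) & (bp <= e)
    return mask


def simulate_trait_pair(genome: SyntheticGenome, cfg: SimConfig | None = None,
                        seed: int | None = None,
                        ) -> tuple[SummaryStatSet, SummaryStatSet]:
    """Generate paired summary-statistic sets with shared causal effects.

    A common causal set is drawn with per-SNP probability ``pi_causal``
    (multiplied by ``enrichment_boost``, capped at 1, inside special genes).
    Standardised causal effects (per trait) are bivariate normal with
    correlation ``rho_shared`` and variance ``h2 / E[n_causal]``; marginal
    effects propagate through block LD; observed z-scores add unit-variance
    noise sharing the block AR(1) correlation (noise independent across
    traits, as for non-overlapping cohorts).  BETA/SE are reported on the
    per-allele scale implied by the trait type and sample size.
    """
    cfg = cfg or genome.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    n = genome.n_snps
    slices = genome.block_slices()
    maf = genome.panel.df["MAF"].to_numpy()

    prob = np.full(n, cfg.pi_causal)
    if cfg.enrichment_boost != 1.0 and genome.special_genes:
        special = _gene_member_mask(genome, genome.special_genes)
        prob[special] = np.minimum(1.0, cfg.pi_causal * cfg.enrichment_boost)
    causal = rng.random(n) < prob
    n_causal = int(causal.sum())

    gamma_a = np.zeros(n)
    gamma_b = np.zeros(n)
    if n_causal and (cfg.h2_a > 0 or cfg.h2_b > 0):
        expected_causal = max(1.0, float(n * cfg.pi_causal))
        sd_a = np.sqrt(cfg.h2_a / expected_causal)
        sd_b = np.sqrt(cfg.h2_b / expected_causal)
        z2 = rng.standard_normal((n_causal, 2))
        r = cfg.rho_shared
        ga = z2[:, 0]
        gb = r * z2[:, 0] + np.sqrt(max(0.0, 1 - r * r)) * z2[:, 1]
        gamma_a[causal] = sd_a * ga
        gamma_b[causal] = sd_b * gb

    out = []
    for which, gamma in (("a", gamma_a), ("b", gamma_b)):
        lam = _propagate_through_ld(gamma, slices, genome.block_rho)
        z = np.sqrt(_effective_n(cfg, which)) * lam + _ar1_noise(
            rng, slices, n, genome.block_rho)
        se = _se_per_allele(maf, cfg, which)
        beta = z * se
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        df = genome.panel.df[["CHR", "BP", "REF", "ALT"]].copy()
        df["BETA"] = beta
        df["SE"] = se
        df["P"] = p
        df["EAF"] = maf
        ttype = getattr(cfg, f"trait_type_{which}")
        if ttype == "quantitative":
            df["N"] = getattr(cfg, f"n_{which}")
        else:
            df["N_CASES"] = getattr(cfg, f"n_cases_{which}")
            df["N_CONTROLS"] = getattr(cfg, f"n_controls_{which}")
        out.append(SummaryStatSet(df, trait_name=f"trait_{which}",
                                  trait_type=ttype, validate=False))
    return out[0], out[1]


def simulate_coloc_region(shared: bool, n_snps: int = 50, z_top: float = 8.0,
                          rho: float = 0.2, maf: float = 0.3,
                          n_a: int = 20_000, n_b: int = 20_000,
                          seed: int = 0,
                          ) -> tuple[SummaryStatSet, SummaryStatSet]:
    """Regional fixture for colocalisation.

    ``shared=True`` places one causal variant (centre SNP) driving both
    traits with peak z-score ``z_top``; ``shared=False`` places two distinct
    causal variants at the region's quarter points, one per trait.  LD in the
    region is AR(1) with parameter ``rho`` (weak by default so the causal
    variants are distinguishable).
    """
    if n_snps < 2:
        raise ValueError("a region needs at least 2 SNPs")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_snps)
    if shared:
        c_a = c_b = n_snps // 2
    else:
        c_a, c_b = n_snps // 4, (3 * n_snps) // 4
    corr_a = rho ** np.abs(idx - c_a)
    corr_b = rho ** np.abs(idx - c_b)

    sl = [slice(0, n_snps)]
    dfs = []
    for mean_z, n_t in ((z_top * corr_a, n_a), (z_top * corr_b, n_b)):
        z = mean_z + _ar1_noise(rng, sl, n_snps, rho)
        se = 1.0 / np.sqrt(2.0 * n_t * maf * (1.0 - maf))
        df = pd.DataFrame({
            "CHR": "1", "BP": 100_000 + idx * 1_000,
            "REF": "A", "ALT": "G",
            "BETA": z * se, "SE": se,
            "P": np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0),
            "EAF": maf, "N": n_t,
        })
        dfs.append(df)
    return (SummaryStatSet(dfs[0], "region_a", "quantitative", validate=False),
            SummaryStatSet(dfs[1], "region_b", "quantitative", validate=False))


def simulate_mr_data(n_instruments: int, theta: float,
                     pleiotropy_sd: float = 0.0, seed: int = 0,
                     se_exposure: float = 0.01, se_outcome: float = 0.02,
                     noise: bool = True) -> pd.DataFrame:
    """Instrument table for two-sample Mendelian randomisation.

    True exposure effects are drawn uniformly in ±[0.05, 0.2]; the outcome
    effect is ``theta * beta_exposure`` plus a pleiotropic perturbation of
    scale ``pleiotropy_sd`` plus estimation noise.  ``noise=False`` returns
    the noiseless identities (useful as an exact-recovery fixture).
    """
    if n_instruments < 1:
        raise ValueError("need at least one instrument")
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.05, 0.2, size=n_instruments) * rng.choice(
        [-1.0, 1.0], size=n_instruments)
    by = theta * bx + rng.normal(0.0, pleiotropy_sd, size=n_instruments)
    bx_hat, by_hat = bx.copy(), by.copy()
    if noise:
        bx_hat += rng.normal(0.0, se_exposure, size=n_instruments)
        by_hat += rng.normal(0.0, se_outcome, size=n_instruments)
    return pd.DataFrame({
        "SNP": [f"rs{seed}_{i}" for i in range(n_instruments)],
        "BETA_EXPOSURE": bx_hat,
        "SE_EXPOSURE": se_exposure,
        "BETA_OUTCOME": by_hat,
        "SE_OUTCOME": se_outcome,
    })


def sample_dosages(genome: SyntheticGenome, n_samples: int = 500,
                   seed: int = 0) -> np.ndarray:
    """Sample standardised dosage vectors with the genome's block AR(1)
    correlation (Gaussian working model).

    Only used to test that the exact model r² is what sampled haplotypes
    reproduce; the analysis path never estimates LD from samples.
    """
    rng = np.random.default_rng(seed)
    n = genome.n_snps
    x = np.empty((n_samples, n))
    rho = genome.block_rho
    w = np.sqrt(1.0 - rho * rho)
    for sl in genome.block_slices():
        seg = rng.standard_normal((n_samples, sl.stop - sl.start))
        out = np.empty_like(seg)
        out[:, 0] = seg[:, 0]
        for i in range(1, seg.shape[1]):
            out[:, i] = rho * out[:, i - 1] + w * seg[:, i]
        x[:, sl] = out
    return x
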