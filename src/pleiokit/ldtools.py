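"""Pairwise r² within LD blocks and greedy pruning at an r² threshold.

Under the generator's AR(1) dosage-correlation model, r² between SNPs i and
j in the same block is ``rho^(2|i-j|)`` (index distance within the block) and
exactly 0 across blocks, so the matrix is block-sparse and never estimated.
An estimation route from sampled haplotype dosages exists for testing the
estimator itself.
"""

from __future__ import annotations

import numpy as np

from .sumstats import SummaryStatSet

__all__ = ["LDMatrix", "r2_matrix", "r2_from_dosages", "greedy_prune",
           "greedy_prune_mask"]


class LDMatrix:
    """Block-sparse symmetric matrix of pairwise r² values.

    Stores the block label per variant (aligned to panel / SummaryStatSet
    row order) and the per-block AR(1) correlation; entries are evaluated
    lazily from ``r2(i, j) = rho^(2|i-j|)`` within a block, 0 across blocks.
    """

    def __init__(self, block_id: np.ndarray, rho: float,
                 index: np.ndarray | None = None):
        if not (0 <= rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        self.block_id = np.asarray(block_id)
        self.rho = float(rho)
        # original panel index: AR(1) distance survives row subsetting
        self.index = (np.arange(len(self.block_id)) if index is None
                      else np.asarray(index))
        if len(self.index) != len(self.block_id):
            raise ValueError("index not aligned with block_id")

    @property
    def n(self) -> int:
        return len(self.block_id)

    def r2(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        if self.block_id[i] != self.block_id[j]:
            return 0.0
        return self.rho ** (2 * abs(int(self.index[i]) - int(self.index[j])))

    def r2_submatrix(self, idx: np.ndarray) -> np.ndarray:
        """Dense r² matrix for the given variant rows."""
        idx = np.asarray(idx)
        same = self.block_id[idx][:, None] == self.block_id[idx][None, :]
        pos = self.index[idx]
        dist = np.abs(pos[:, None] - pos[None, :])
        with np.errstate(over="ignore"):
            r2 = np.where(same, self.rho ** (2 * dist), 0.0)
        np.fill_diagonal(r2, 1.0)
        return r2

    def subset(self, rows: np.ndarray) -> "LDMatrix":
        """Row-subset LD matrix (e.g. after QC filtering) that keeps the
        original index distances."""
        rows = np.asarray(rows)
        return LDMatrix(self.block_id[rows], self.rho, self.index[rows])


def r2_matrix(genome) -> LDMatrix:
    """Exact LD matrix of a synthetic genome (generative-model r²)."""
    return LDMatrix(genome.block_id, genome.block_rho)


def r2_from_dosages(dosages: np.ndarray) -> np.ndarray:
    """Estimate pairwise r² as squared Pearson correlation of dosage columns.

    Only used to test that sampled haplotypes reproduce the model r²; the
    analysis path uses the exact matrix.
    """
    c = np.corrcoef(dosages, rowvar=False)
    return c * c


def greedy_prune_mask(order: np.ndarray, ld: LDMatrix, r2_max: float,
                      ) -> np.ndarray:
    """Keep-mask of greedy pruning when variants are visited in ``order``."""
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must lie in (0, 1]")
    n = ld.n
    # max index distance at which r2 can still reach the threshold;
    # r2_max == 1 conflicts with nothing (pairs always have r2 < 1)
    if r2_max == 1.0:
        reach = -1
    elif ld.rho == 0.0:
        reach = 0
    else:
        reach = int(np.floor(np.log(r2_max) / (2 * np.log(ld.rho))))

    keep = np.zeros(n, dtype=bool)
    kept_in_block: dict[int, list[int]] = {}
    for i in order:
        i = int(i)
        b = int(ld.block_id[i])
        ok = True
        for j in kept_in_block.get(b, ()):
            d = abs(int(ld.index[i]) - int(ld.index[j]))
            if d <= reach and ld.rho ** (2 * d) >= r2_max:
                ok = False
                break
        if ok:
            keep[i] = True
            kept_in_block.setdefault(b, []).append(i)
    return keep


def prune_order(s: SummaryStatSet, priority: str = "p-value") -> np.ndarray:
    """Visit order for pruning: ascending p (ties by chrom, position) or
    plain position order."""
    df = s.df
    if priority == "p-value":
        return np.lexsort((df["BP"].to_numpy(), df["CHR"].to_numpy(),
                           df["P"].to_numpy()))
    if priority == "position":
        return np.lexsort((df["BP"].to_numpy(), df["CHR"].to_numpy()))
    raise ValueError(f"unknown priority {priority!r}")


def greedy_prune(s: SummaryStatSet, ld: LDMatrix, r2_max: float,
                 priority: str = "p-value") -> SummaryStatSet:
    """Thin a set so that no retained pair has r² >= ``r2_max``.

    Variants are visited in priority order — ascending p (most significant
    retained first) — and kept when compatible with everything already kept.
    Deterministic for fixed input.  The LD matrix must be row-aligned with
    ``s``.
    """
    if ld.n != len(s):
        raise ValueError("LD matrix not aligned with summary-statistic set")
    keep = greedy_prune_mask(prune_order(s, priority), ld, r2_max)
    return s.copy(s.df[keep].reset_index(drop=True))
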