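"""Boost discovery power in an under-powered GWAS with the iterative cFDR.

A weakly powered principal trait is conditioned on three better-powered
auxiliary traits that share part of its genetic architecture.  Each
iteration fits the two-groups null of the auxiliary p-values at
principal-null SNPs (on an r² < 0.2 pruned subset), converts each SNP's
(principal, auxiliary) pair into a v-value — the null mass of the
empirical-cFDR sub-level region through that pair — and feeds the v-values
forward as the next iteration's principal input.
"""

import numpy as np

from pleiokit import GENOME_WIDE_SIG, CfdrConfig, SimConfig, iterate_cfdr, simulate_genome, simulate_trait_pair
from pleiokit.ldtools import r2_matrix

cfg = SimConfig(n_snps=8000, n_blocks=400, pi_causal=0.01,
                h2_a=0.12, h2_b=0.35, rho_shared=0.9,
                trait_type_a="case-control", n_cases_a=2000,
                n_controls_a=20_000, n_genes=60, n_special_genes=6, seed=8)
genome = simulate_genome(cfg)
ld = r2_matrix(genome)

principal, aux1 = simulate_trait_pair(genome, cfg, seed=9)
_, aux2 = simulate_trait_pair(genome, cfg, seed=10)
_, aux3 = simulate_trait_pair(genome, cfg, seed=11)

run = iterate_cfdr(principal, [aux1, aux2, aux3], ld, CfdrConfig())

p_in = run.iterations[0].per_snp["P_IN"].to_numpy()
print(f"genomic-control lambda: {run.lambda_gc:.3f}")
print(f"genome-wide significant before conditioning: "
      f"{int((p_in < GENOME_WIDE_SIG).sum())}")
for k, it in enumerate(run.iterations, start=1):
    v = it.per_snp["V"].to_numpy()
    print(f"after iteration {k} ({it.aux_name}): "
          f"{int((v < GENOME_WIDE_SIG).sum())} significant; "
          f"fitted null pi0 = {it.fit.pi0:.3f}, sigma = {it.fit.sigma:.2f}")
# Each conditioning step shrinks v at SNPs whose auxiliary p-values are
# unusually small, lifting shared sub-threshold signals past the
# genome-wide line while the joint-null calibration keeps v a valid
# p-value analogue.
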