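# Demo configuration for the end-to-end synthetic pipeline:
#   pleiokit run --config examples/demo_config.yaml --out-dir out --seed 1
# Two case-control studies of a rare immune trait are simulated on a
# 4,000-SNP panel, meta-analysed, tested for gene-set enrichment and
# signal sharing with a quantitative auxiliary trait, conditioned on three
# auxiliaries with the iterative cFDR, and finished with a colocalisation-
# screened IVW Mendelian randomisation.
n_snps: 4000
n_blocks: 200
block_rho: 0.9
pi_causal: 0.01
h2: 0.3
rho_shared: 0.8
n_cases: 2000
n_controls: 20000
n_quant: 50000
n_genes: 150
n_special_genes: 30
enrichment_boost: 8.0
enrich_realisations: 500
gps_n_perm: 500
cfdr_grid: 500
seed: 1
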