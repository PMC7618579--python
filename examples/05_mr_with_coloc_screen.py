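"""Two-sample IVW Mendelian randomisation with a colocalisation screen.

Estimates the causal effect of an exposure on an outcome from per-variant
instrument effects.  Before pooling, each instrument's 100 kb region is
checked by approximate-Bayes-factor colocalisation: a region where exposure
and outcome are driven by distinct causal variants (high PP3) indicates an
outcome effect not mediated by the exposure, so that instrument is dropped.
"""

from pleiokit import mr_ivw, screen_instruments, simulate_coloc_region, simulate_mr_data

true_theta = 0.5
inst = simulate_mr_data(20, theta=true_theta, pleiotropy_sd=0.0, seed=14)

# regional summary statistics around each instrument: the first two loci
# harbour distinct causal variants for exposure and outcome
regions = {}
for i, snp in enumerate(inst["SNP"]):
    regions[snp] = simulate_coloc_region(shared=i >= 2, z_top=8.0,
                                         seed=100 + i)

kept, excluded = screen_instruments(inst, regions, pp3_threshold=0.5)
print(f"instruments: {len(inst)} simulated, {len(excluded)} excluded by the "
      f"colocalisation screen: {excluded['SNP'].tolist()}")

naive = mr_ivw(inst)
screened = mr_ivw(kept)
for label, res in (("naive", naive), ("screened", screened)):
    lo, hi = res.confint()
    print(f"{label:>9}: theta = {res.theta:.3f} "
          f"(95% CI {lo:.3f} to {hi:.3f}), p = {res.p:.3g}, "
          f"k = {res.n_instruments}")
print(f"true causal effect: {true_theta}")
# The IVW estimate pools per-instrument Wald ratios weighted by inverse
# variance; dropping loci with distinct causal variants protects the
# estimate from horizontal pleiotropy.
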