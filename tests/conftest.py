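import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pleiokit import SimConfig, SummaryStatSet, simulate_genome

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def make_set(chrom, bp, ref=None, alt=None, **cols) -> SummaryStatSet:
    """Small literal summary-statistic set for micro-examples."""
    n = len(bp)
    df = pd.DataFrame({
        "CHR": [str(c) for c in (chrom if isinstance(chrom, (list, tuple))
                                 else [chrom] * n)],
        "BP": list(bp),
        "REF": ref if ref is not None else ["A"] * n,
        "ALT": alt if alt is not None else ["G"] * n,
    })
    for k, v in cols.items():
        df[k.upper()] = v
    return SummaryStatSet(df, validate=False)


@pytest.fixture(scope="session")
def small_genome():
    """2,000-SNP genome shared by tests that only need structure."""
    cfg = SimConfig(n_snps=2000, n_blocks=100, n_genes=60,
                    n_special_genes=12, seed=42)
    return cfg, simulate_genome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
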