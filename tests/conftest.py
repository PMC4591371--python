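import numpy as np
import pandas as pd
import pytest

import stratinteract as si


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_study_table(n=50, seed=0, beta=0.0, chrom=1):
    """A well-formed single-study summary table with null or fixed effects."""
    rng = np.random.default_rng(seed)
    pos = 1_000_000 + np.arange(n) * 1_000_000
    se = np.full(n, 0.02)
    b = beta + rng.normal(0, se)
    from scipy import stats
    return pd.DataFrame({
        "MARKER": [f"{chrom}:{p}" for p in pos],
        "CHR": chrom, "POS": pos,
        "EA": "A", "OA": "G",
        "EAF": rng.uniform(0.1, 0.9, n),
        "BETA": b, "SE": se,
        "P": 2 * stats.norm.sf(np.abs(b / se)),
        "N": 10_000, "INFO": 0.95, "IMPUTED": True,
    })


@pytest.fixture(scope="session")
def planted_consortium():
    """A seeded miniature consortium with 20 women-only loci and one
    opposite-by-sex locus, fitted once and shared across tests."""
    config = si.women_specific_config(seed=1)
    model = si.StratifiedGWAMA.from_simulation(config)
    results = model.fit()
    return config, model, results
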