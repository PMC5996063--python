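import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_mutations():
    """Five records over four distinct (gene, position) keys, two cell lines."""
    return pd.DataFrame({
        "cell_line_id": ["CL1", "CL1", "CL1", "CL2", "CL2"],
        "cancer_type": ["BRCA"] * 3 + ["LUAD"] * 2,
        "gene": ["TP53", "TP53", "KRAS", "TP53", "EGFR"],
        "position": [100, 200, 50, 100, 7],
        "ref": ["A", "C", "G", "A", "T"],
        "alt": ["T", "G", "T", "C", "A"],
    })


@pytest.fixture(scope="session")
def toy_xy():
    """Tiny binary fingerprint matrix with an additive planted response."""
    rng = np.random.default_rng(42)
    n, gw, dw = 120, 12, 10
    X = (rng.random((n, gw + dw)) < 0.4).astype(np.uint8)
    y = 1.0 - 2.0 * X[:, 2] * X[:, gw + 3] + 0.5 * X[:, gw + 1]
    return X, y, gw


@pytest.fixture(scope="session")
def benchmark_small():
    """A reduced planted-signal corpus for fast end-to-end checks."""
    from drugscan.synthetic import make_benchmark

    return make_benchmark(seed=11, n_types=3, lines_per_type=12, vocab_size=300,
                          n_drugs=8, n_drivers=4, noise_sd=0.3)
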