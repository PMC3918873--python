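import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from betcore import ExperimentConfig, generate_expression_bundle

settings.register_profile("deterministic", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("deterministic")

SMALL_EXPR = ExperimentConfig(n_genes=1200, private_de_per_line=40, seed=11)


@pytest.fixture(scope="session")
def small_bundle():
    """Small seeded expression bundle shared across read-only tests."""
    bundle, truth = generate_expression_bundle(SMALL_EXPR)
    return bundle, truth


def make_de_frame(rng, n_genes=1000, n_sig=50, seed_ids=None):
    """Random DE-result-shaped frame with a planted set of significant genes."""
    ids = seed_ids if seed_ids is not None else [f"G{i:04d}" for i in range(n_genes)]
    log2fc = rng.normal(0, 0.3, n_genes)
    q = rng.uniform(0.1, 1.0, n_genes)
    sig = rng.choice(n_genes, size=n_sig, replace=False)
    log2fc[sig] = rng.choice([-1, 1], n_sig) * rng.uniform(1.5, 3.0, n_sig)
    q[sig] = rng.uniform(0, 0.04, n_sig)
    return pd.DataFrame({"log2fc": log2fc, "t_mod": 0.0, "p": q, "q": q,
                         "mean_expr": 8.0}, index=ids)
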