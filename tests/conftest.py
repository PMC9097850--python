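import numpy as np
import pandas as pd
import pytest

from refstab import AnalysisBlock, CtMatrix, simulate, tmcao_preset


def make_matrix(ct_array, genes, conditions, time_points, regions,
                sample_ids=None) -> CtMatrix:
    """Build a CtMatrix from plain arrays (test helper)."""
    ct_array = np.asarray(ct_array, dtype=float)
    n = ct_array.shape[0]
    if sample_ids is None:
        sample_ids = [f"s{i:03d}" for i in range(n)]
    idx = pd.Index(sample_ids, name="sample_id")
    ct = pd.DataFrame(ct_array, index=idx, columns=list(genes))
    meta = pd.DataFrame({
        "condition": _expand(conditions, n),
        "time_point": _expand(time_points, n),
        "region": _expand(regions, n),
    }, index=idx)
    return CtMatrix(ct=ct, meta=meta)


def _expand(val, n):
    return [val] * n if isinstance(val, str) else list(val)


def make_block(ct_array, genes, conditions=None, region="CX",
               time_point="12h") -> AnalysisBlock:
    """Build a one-block CtMatrix wrapped as an AnalysisBlock."""
    n = np.asarray(ct_array).shape[0]
    if conditions is None:
        conditions = ["SHAM"] * (n // 2) + ["tMCAO"] * (n - n // 2)
    m = make_matrix(ct_array, genes, conditions, time_point, region)
    return AnalysisBlock(matrix=m, region=region, time_point=time_point)


def random_block(rng, n_samples, n_genes, loading_sd=0.4, noise_sd=0.6):
    """A random but qPCR-plausible block: baselines + loading + noise."""
    base = rng.uniform(16, 30, size=n_genes)
    loading = rng.normal(0, loading_sd, size=(n_samples, 1))
    noise = rng.normal(0, noise_sd, size=(n_samples, n_genes))
    ct = base + loading + noise
    genes = [f"g{j}" for j in range(n_genes)]
    return make_block(ct, genes)


@pytest.fixture(scope="session")
def preset_matrix():
    """One realization of the synthetic tMCAO study."""
    return simulate(tmcao_preset(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20220422)
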