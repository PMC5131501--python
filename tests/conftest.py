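import numpy as np
import pandas as pd
import pytest

from coexmap import ExpressionMatrix, SyntheticSpec


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A fast study: 300 genes, 5 chromosomes, 42 pairs."""
    return SyntheticSpec(seed=7, n_genes=300, n_chromosomes=5, cis_block_size=4)


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=11)


@pytest.fixture()
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with simple hand-checkable values."""
    df = pd.DataFrame(
        {
            "S1": [1.0, 2.0, 5.0],
            "S2": [2.0, 4.0, 4.0],
            "S3": [3.0, 6.0, 3.0],
            "S4": [4.0, 8.0, 1.0],
        },
        index=["GA", "GB", "GC"],
    )
    df.index.name = "gene"
    return ExpressionMatrix(df)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def exact_r_vectors(r: float, n: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two n-vectors whose sample Pearson correlation is exactly r.

    Built by orthogonalizing one random vector against another and mixing
    the standardized parts as r*x + sqrt(1-r^2)*z.
    """
    g = np.random.default_rng(seed)
    x = g.standard_normal(n)
    z = g.standard_normal(n)
    xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
    zc = z - z.mean()
    zc -= (zc @ xc) * xc
    zc /= np.linalg.norm(zc)
    y = r * xc + np.sqrt(1 - r * r) * zc
    return x, y
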