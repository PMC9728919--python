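import numpy as np
import pytest

from bpfs import ExpressionMatrix, Orientation, generate


def make_matrix(values, orientation=Orientation.SAMPLES_BY_GENES,
                row_prefix="S", col_prefix="G"):
    """Wrap a plain array in an ExpressionMatrix with generated IDs."""
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        row_ids=tuple(f"{row_prefix}{i}" for i in range(values.shape[0])),
        col_ids=tuple(f"{col_prefix}{j}" for j in range(values.shape[1])),
        orientation=orientation,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def planted_dataset():
    """One default planted-signal dataset (500 samples x 2000 genes)."""
    return generate(seed=11)


@pytest.fixture(scope="session")
def random_100x1000():
    """A signal-free 100 x 1000 matrix for pipeline plumbing tests."""
    values = np.random.default_rng(42).lognormal(1.0, 1.0, (100, 1000))
    return ExpressionMatrix(
        values=values,
        row_ids=tuple(f"S{i:03d}" for i in range(100)),
        col_ids=tuple(f"G{j:04d}" for j in range(1000)),
        orientation=Orientation.SAMPLES_BY_GENES,
    )
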