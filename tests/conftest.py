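import numpy as np
import pandas as pd
import pytest

from cernet import simulate
from cernet.types import CountMatrix


@pytest.fixture(scope="session")
def ref():
    """Default synthetic reference, seed-fixed (shared read-only)."""
    return simulate.generate_reference(seed=11)


@pytest.fixture(scope="session")
def planted():
    """Reference with planted regulation plus its ground truth."""
    r = simulate.generate_reference(seed=11)
    truth = simulate.plant_regulation(r, n_triples=8, seed=12)
    return r, truth


def make_count_matrix(counts: np.ndarray, n_per_group: int | None = None,
                      features=None) -> CountMatrix:
    """Wrap an integer array into a two-group CountMatrix (C first)."""
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.shape[1] // 2 if n_per_group is None else n_per_group
    samples = [f"C{i + 1}" for i in range(n)] + [
        f"G{i + 1}" for i in range(counts.shape[1] - n)]
    feats = features if features is not None else [
        f"f{i + 1}" for i in range(counts.shape[0])]
    df = pd.DataFrame(counts, index=feats, columns=samples)
    return CountMatrix(df, {s: s[0] for s in samples},
                       df.sum(axis=0))
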