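import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from annmat import AnnMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_ann(rng) -> AnnMatrix:
    """20×10 sparse count matrix with annotations on both axes and nested uns."""
    X = sp.random(20, 10, density=0.4, format="csr", random_state=0)
    X.data = np.round(X.data * 10)
    return AnnMatrix(
        X,
        obs_names=[f"c{i}" for i in range(20)],
        var_names=[f"g{j}" for j in range(10)],
        obs={
            "depth": rng.integers(1, 100, 20).astype(np.int64),
            "batch": pd.Categorical(rng.choice(["a", "b"], 20)),
            "flagged": rng.random(20) > 0.5,
        },
        var={"symbol": [f"SYM{j}" for j in range(10)]},
        uns={
            "title": "toy",
            "count": 3,
            "ratio": 0.25,
            "ok": True,
            "labels": ["x", "y"],
            "arr": np.arange(4.0),
            "nested": {"k": np.ones(2), "deep": {"s": "v"}},
            "graph": sp.eye(4, format="csr"),
        },
    )


def dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
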