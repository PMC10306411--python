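"""Shared fixtures: random projection instances and small synthetic scenes."""

import numpy as np
import pytest

from pepc import Curve, ScatteringDataset, TrivialSet


def random_projection_instance(rng: np.random.Generator):
    """A random dataset + trivial set; ~1/3 of the sets are rank-deficient."""
    n_q = int(rng.integers(3, 51))
    n_t = int(rng.integers(1, 8))
    m = int(rng.integers(1, 6))
    q = np.sort(rng.uniform(0.1, 10.0, n_q))
    q += np.arange(n_q) * 1e-6  # enforce strict monotonicity
    t = np.sort(rng.uniform(-10, 1e4, n_t))
    t += np.arange(n_t) * 1e-9
    matrix = rng.standard_normal((n_q, n_t))
    comps = []
    for i in range(m):
        if i > 0 and rng.random() < 0.35:
            # duplicate/linear-combination component -> rank deficiency
            base = sum(rng.standard_normal() * c.values for c in comps)
            vals = base if np.linalg.norm(base) > 1e-9 else rng.standard_normal(n_q)
        else:
            vals = rng.standard_normal(n_q)
        comps.append(Curve(q, vals, label=f"trv{i+1}"))
    ds = ScatteringDataset(q, t, matrix)
    return ds, TrivialSet(comps)


@pytest.fixture(scope="session")
def projection_instances():
    rng = np.random.default_rng(20230627)
    return [random_projection_instance(rng) for _ in range(100)]


@pytest.fixture()
def simple_grid():
    return np.array([1.0, 2.0, 3.0])


@pytest.fixture()
def tiny_dataset(simple_grid):
    return ScatteringDataset(
        q=simple_grid,
        t=np.array([10.0, 100.0]),
        matrix=np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
        meta={"solvent": "water"},
    )
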