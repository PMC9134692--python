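import numpy as np
import pytest

from hyperpaths import GenSpec, random_hypergraph, worked_examples


@pytest.fixture(scope="session")
def examples():
    """The fixed micro-instances with fully known behavior."""
    return worked_examples()


@pytest.fixture
def make_random():
    """Factory for seeded random instances: make_random(seed, n_max, m_max)."""

    def _make(seed, n_max=12, m_max=10, **kwargs):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, n_max + 1))
        m = int(rng.integers(2, m_max + 1))
        spec = GenSpec(
            n=n,
            m=m,
            tail_size_range=kwargs.pop("tail_size_range", (1, 3)),
            head_size_range=kwargs.pop("head_size_range", (1, 3)),
            seed=seed,
            **kwargs,
        )
        return random_hypergraph(spec)

    return _make
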