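import numpy as np
import pytest

import wcna
from wcna.simulate import SyntheticSpec, default_effect_map, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_adjacency(rng, n):
    """Random valid adjacency matrix: symmetric, [0,1], unit diagonal."""
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


@pytest.fixture
def small_abundance():
    return wcna.AbundanceMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        feature_ids=["fA", "fB", "fC"],
        values=np.array(
            [[1.0, 10.0, 5.0], [2.0, 20.0, 5.5], [3.0, 15.0, 4.5], [4.0, 5.0, 6.0]]
        ),
    )


@pytest.fixture(scope="session")
def synthetic_default():
    spec = SyntheticSpec(seed=7, effect_map=default_effect_map(1.5))
    return generate(spec)


@pytest.fixture(scope="session")
def pipeline_results(synthetic_default, tmp_path_factory):
    abundance, traits, truth = synthetic_default
    cfg = wcna.RunConfig(
        out_dir=str(tmp_path_factory.mktemp("pipe")),
        factors=["genotype"],
        seed=7,
    )
    results = wcna.run_pipeline(cfg, abundance=abundance, traits=traits)
    results["truth"] = truth
    return results
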