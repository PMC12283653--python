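import numpy as np
import pytest

from crownprof import pipeline, synthetic


@pytest.fixture(scope="session")
def small_stand():
    """Two 60-tree plots with competition and directional asymmetry."""
    params = synthetic.StandParams(n_trees=60, seed=11)
    plots, truths = synthetic.generate_stands(params, 2, seed=11)
    return plots, truths


@pytest.fixture(scope="session")
def prepared(small_stand):
    plots, _ = small_stand
    return pipeline.prepare_stand(plots)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
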