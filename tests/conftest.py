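import numpy as np
import pytest
from hypothesis import settings

import jipflux as jf

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_experiment():
    """The default simulated field campaign (8 cells × 10 replicates),
    analyzed: (transients, metadata, truth, params, rejects)."""
    design = jf.paper_like_design(seed=1)
    transients, metadata, truth = jf.simulate_experiment(design)
    params, rejects = jf.analyze_transients(transients)
    return transients, metadata, truth, params, rejects


@pytest.fixture(scope="session")
def default_groups(default_experiment):
    _, metadata, _, params, _ = default_experiment
    meta = metadata.loc[params.index]
    return (meta["population"] + "/" + meta["season"] + "/" + meta["period"]).to_numpy()


def make_transient(times, values, sample_id="s"):
    return jf.FluorescenceTransient(sample_id=sample_id,
                                    times=np.asarray(times, float),
                                    fluorescence=np.asarray(values, float))
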