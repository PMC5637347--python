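import numpy as np
import pytest

import srbmrank as sr
from srbmrank.rbm import BB, GB, RBMParameters


@pytest.fixture
def toy_matrix():
    """3 genes x 2 samples, unstandardized."""
    return sr.ExpressionMatrix(
        ["gA", "gB", "gC"], ["s1", "s2"],
        np.array([[1.0, 2.0], [3.0, 5.0], [0.5, 0.5]]),
    )


@pytest.fixture
def small_bb():
    """Small random Bernoulli RBM (3 hidden x 4 visible)."""
    rng = np.random.default_rng(3)
    return RBMParameters(rng.normal(0, 0.5, (3, 4)), rng.normal(0, 0.5, 4),
                         rng.normal(0, 0.5, 3), BB)


@pytest.fixture
def small_gb():
    rng = np.random.default_rng(4)
    return RBMParameters(rng.normal(0, 0.5, (2, 3)), rng.normal(0, 0.5, 3),
                         rng.normal(0, 0.5, 2), GB)


@pytest.fixture(scope="session")
def easy_dataset():
    """The default planted-signal scenario, seed 0."""
    return sr.generate(sr.SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def easy_fit(easy_dataset):
    """A fitted SRBM-II ranker on the easy scenario (benchmark protocol)."""
    from srbmrank.synthetic_data import benchmark_protocol

    spec = easy_dataset.spec
    proto = benchmark_protocol(spec, seed=0)
    model = sr.SRBMGeneRanker(
        easy_dataset.period1, easy_dataset.period2, variant="SRBM-II",
        n_hidden1=proto["n_hidden1"], n_hidden2=proto["n_hidden2"],
        config1=proto["cfg1"], config2=proto["cfg2"], seed=0,
    )
    return model.fit()


def enumerated_hidden_conditional(summary, v_index, k):
    """P(h_k=1 | V) from an enumerated joint distribution (oracle)."""
    probs = summary.probabilities[v_index]
    on = summary.hidden_states[:, k] == 1
    return probs[on].sum() / probs.sum()
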