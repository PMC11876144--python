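import numpy as np
import pytest

from talsrx import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_class_data():
    """Small well-separated dataset: scores 100 / 50 / 0, 20 plates each."""
    data = synth.generate_dataset({100: 20, 50: 20, 0: 20}, 7)
    return data.feature_matrix(), data.class_indices()


@pytest.fixture(scope="session")
def extreme_plates():
    """Zero-noise class-100 plates vs fully-diffuse class-0 plates.

    The clean class is maximally separated from the diffuse class, so a sound
    pipeline should classify held-out plates essentially perfectly.  Returns
    (X_train, y_train, X_test, y_test) with 50 + 50 plates in each split.
    """
    from dataclasses import replace

    from talsrx.plate import Dataset

    rng = np.random.default_rng(3)
    clean = replace(synth.default_spec(100), cluster_sd=0.0, ntc_sd=0.0)
    diffuse = synth.default_spec(0)

    def build(n):
        recs = [synth.sample_plate(clean, rng) for _ in range(n)]
        recs += [synth.sample_plate(diffuse, rng) for _ in range(n)]
        d = Dataset(records=recs)
        return d.feature_matrix(), d.class_indices()

    X_train, y_train = build(50)
    X_test, y_test = build(50)
    return X_train, y_train, X_test, y_test
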