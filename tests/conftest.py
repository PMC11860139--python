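import numpy as np
import pytest

from gaitguard.synthetic import BenchmarkConfig, make_benchmark


@pytest.fixture(scope="session")
def tiny_config() -> BenchmarkConfig:
    """A small benchmark: every split/section populated, fast to build."""
    return BenchmarkConfig(
        n_seen_subjects=6, n_unseen_subjects=3,
        n_seen_phones=2, n_unseen_phones=2,
        gait_duration_s=24.0, aw_duration_s=24.0,
        aw_sessions_seen=2, aw_sessions_unseen=1,
        overtime_sessions=1,
    )


@pytest.fixture(scope="session")
def tiny_benchmark(tiny_config):
    return make_benchmark(tiny_config, seed=123)


@pytest.fixture(scope="session")
def tiny_features(tiny_benchmark):
    from gaitguard.features import feature_matrix

    return feature_matrix(tiny_benchmark)


@pytest.fixture(scope="session")
def tiny_hybrid(tiny_benchmark):
    from gaitguard.models import CnnHyper, train_hybrid

    train = tiny_benchmark.in_split("train")
    return train_hybrid(train.windows, train.multiclass_labels(),
                        hyper=CnnHyper(seed=7), mode="preset", seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
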