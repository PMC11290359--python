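import numpy as np
import pytest
import threadpoolctl

from compound_embed import (
    EmbedConfig,
    FixtureSpec,
    SampleCollection,
    SampleData,
    generate_multisample,
)


def make_sample(sample_id, pca, labels=None):
    pca = np.asarray(pca, float)
    return SampleData(sample_id, [f"{sample_id}_c{i}" for i in range(len(pca))],
                      pca, labels)


def blob_sample(sample_id, means, n_per, sd, rng, labels=True):
    """Gaussian blobs at the given means; one label code per blob."""
    means = np.asarray(means, float)
    X, lab = [], []
    for code, mu in enumerate(means):
        X.append(rng.normal(loc=mu, scale=sd, size=(n_per, means.shape[1])))
        lab.extend([code] * n_per)
    return make_sample(sample_id, np.vstack(X),
                       np.array(lab) if labels else None)


@pytest.fixture(scope="session", autouse=True)
def single_threaded_blas():
    """Bit-reproducibility is only contracted for single-threaded runs;
    pin BLAS threads so embeddings are identical across machines."""
    with threadpoolctl.threadpool_limits(limits=1):
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_collection():
    """3 well-separated types, 2 samples, modest size, fully labeled."""
    spec = FixtureSpec(n_samples=2, n_cells=(120, 120), n_types=3, P=8,
                       batch_rotation_angle=(0.0, 0.4),
                       batch_scale=(1.0, 1.1), seed=7)
    collection, truth = generate_multisample(spec)
    return collection, truth


@pytest.fixture
def quick_config():
    """Short optimization schedule for unit tests of mechanics."""
    return EmbedConfig(perplexity=15, n_iter_early=50, n_iter_main=100, seed=0)
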