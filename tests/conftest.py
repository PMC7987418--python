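import warnings

import numpy as np
import pytest
from hypothesis import settings

from ecgcast import (
    HybridConfig,
    SynthEcgSpec,
    VmdConfig,
    evaluate,
    fit,
    split_series,
    synth_ecg,
)
from ecgcast.embedding import EmbeddingParams, embed, select_embedding_dim
from ecgcast import rbf

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ecg_signal():
    """The reference synthetic ECG study signal (seed 42, defaults)."""
    return synth_ecg(SynthEcgSpec(seed=42))


@pytest.fixture(scope="session")
def ecg_model(ecg_signal):
    """Hybrid model fitted on the reference signal with K=10 modes.

    Rank-deficiency warnings from the wide-kernel design matrices are
    expected on smooth modes and silenced here.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit(ecg_signal, HybridConfig(vmd=VmdConfig(K=10)))


@pytest.fixture(scope="session")
def raw_rbf_baseline(ecg_signal):
    """One-step RBF forecast of the raw (undecomposed) series under the
    same embedding policy (tau=1, FNN-selected m) and spread."""
    x = ecg_signal.samples
    n_train, n_test = split_series(x.size, 2.0 / 3.0)
    m = select_embedding_dim(x[:n_train], 1, 8).selected
    emb = embed(x[:n_train], EmbeddingParams(m=m, tau=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = rbf.train_exact(emb.X[: emb.M_usable], emb.Y, 0.5)
    start = n_train - 1 - (m - 1)
    rows = np.arange(n_test)[:, None] + start + np.arange(m)[None, :]
    pred = rbf.predict(model, x[rows])
    return evaluate(pred, x[n_train:])
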