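import numpy as np
import pytest

import surgphase as sp
from surgphase import pipeline as pl


@pytest.fixture(scope="session")
def catalog():
    return sp.build_phase_catalog()


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small clean dataset: 4 videos, no noise/nuisance, canonical texts."""
    return sp.generate_dataset(
        n_videos=4, fps=0.012, noise_level=0.0, variability=0.0,
        nuisance=False, seed=42,
    )


@pytest.fixture(scope="session")
def tiny_trained(tiny_dataset):
    """A short two-tower training run on the tiny dataset (shared by tests
    that need *some* trained weights but not converged ones)."""
    ds = tiny_dataset
    manifest = ds.manifest.reset_index(drop=True)
    vocab = sp.build_vocab(manifest["text"])
    model = pl.TwoTowerModel(vocab, seed=3)
    frames, toks, labels = pl.prepare_arrays(ds, manifest, vocab)
    cfg = pl.TrainConfig.desk_preset(seed=3, epochs=20, warmup_epochs=1)
    trace = pl.train_towers(frames, toks, model, cfg)
    return {
        "dataset": ds, "manifest": manifest, "vocab": vocab, "model": model,
        "frames": frames, "token_lists": toks, "labels": labels,
        "config": cfg, "trace": trace,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
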