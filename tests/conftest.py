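"""Shared fixtures: one synthetic dataset and a handful of trained models,
built once per session (training the small transformer takes ~1 min)."""

import numpy as np
import pytest

from tsapred.model import ModelConfig
from tsapred.synthetic import SimConfig, fixture_datasets, make_fixture
from tsapred.train import TrainConfig, fit_model, make_splits

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fx():
    return make_fixture(SimConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def son_datasets(fx):
    return fixture_datasets(fx, "SON")


@pytest.fixture(scope="session")
def lmnb_datasets(fx):
    return fixture_datasets(fx, "LMNB")


@pytest.fixture(scope="session")
def split(fx):
    return make_splits(fx.bins, fold=0)


@pytest.fixture(scope="session")
def model_cfg():
    return ModelConfig(encoder_hidden=32, encoder_out=16, n_heads=4,
                       n_layers=2, ffn_dim=64, dropout=0.0, window=10)


@pytest.fixture(scope="session")
def train_cfg():
    return TrainConfig(batch_size=32, max_epochs=80, patience=20,
                       warmup_steps=80, lr_scale=1.0, seed=0)


@pytest.fixture(scope="session")
def trained_son(son_datasets, split, model_cfg, train_cfg):
    model, hist = fit_model({"CT1": son_datasets["CT1"]}, split, model_cfg,
                            train_cfg, n_restarts=3, refit=True)
    return model, hist


@pytest.fixture(scope="session")
def trained_lmnb(lmnb_datasets, split, model_cfg, train_cfg):
    model, hist = fit_model({"CT1": lmnb_datasets["CT1"]}, split, model_cfg,
                            train_cfg, n_restarts=3, refit=True)
    return model, hist


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
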