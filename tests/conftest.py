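"""Shared fixtures: the scaled-down training study used by the end-to-end tests.

Training the full 512-dim detector on 60,000 half-second windows is out of
reach for a test suite, so the expensive fixtures here train a reduced
detector (hidden dim 64, one encoder and one decoder layer, 8 queries,
narrow backbone) on an easy slice of the synthetic grid (SNR 4, long
pulses) cut into 0.25 s windows.  They are session scoped: the detector
and counter are trained once and reused by every test that needs a trained
model.
"""

import numpy as np
import pytest

import pulsedet as pdt
from pulsedet import model as mdl, train as tr

# -- study conditions for the reduced runs ----------------------------------
EASY_GRID = pdt.ParameterGrid(diameters_nm=(5.0, 6.0, 8.0, 10.0, 12.0, 14.0, 15.0, 16.0),
                              concentrations_nm=(0.15, 0.2, 0.3),
                              durations_ms=(3.0, 5.0))
EASY_SNR = 4.0
TRACE_SECONDS = 10.0
WINDOW_SECONDS = 0.25
DATA_SEED = 7

REDUCED_MODEL = mdl.ModelConfig(hidden_dim=64, n_queries=10, encoder_layers=1,
                                decoder_layers=2, attention_heads=4, ffn_dim=128,
                                backbone_base_width=8, backbone_blocks=(1, 1, 1, 1),
                                backbone_stage_strides=(1, 2, 2, 1))
REDUCED_TRAIN = tr.TrainConfig(learning_rate=5e-4, lr_decay_factor=10.0,
                               decay_period_epochs=90, batch_size=6,
                               backbone_lr_multiplier=1.0,  # from-scratch backbone
                               val_first_epoch=50, val_second_epoch=90,
                               val_every=15, max_epochs=165, seed=0)
N_TRAIN_WINDOWS = 580
N_VAL_WINDOWS = 40


def easy_dataset_windows(base_seed=DATA_SEED):
    windows = []
    for trace in pdt.iter_dataset(EASY_GRID, TRACE_SECONDS, base_seed, EASY_SNR):
        windows.extend(pdt.split_windows(trace, WINDOW_SECONDS))
    return windows


@pytest.fixture(scope="session")
def easy_windows():
    return easy_dataset_windows()


@pytest.fixture(scope="session")
def easy_split(easy_windows):
    """(train, validation) split of the non-empty windows."""
    nonempty = pdt.filter_nonempty(easy_windows)
    rng = np.random.default_rng(0)
    order = rng.permutation(len(nonempty))
    train = [nonempty[i] for i in order[:N_TRAIN_WINDOWS]]
    val = [nonempty[i] for i in order[N_TRAIN_WINDOWS:N_TRAIN_WINDOWS + N_VAL_WINDOWS]]
    return train, val


@pytest.fixture(scope="session")
def test_windows():
    """Non-empty windows from fresh traces never seen in training."""
    return pdt.filter_nonempty(easy_dataset_windows(DATA_SEED + 1))


@pytest.fixture(scope="session")
def trained_detector(easy_split):
    """Reduced detector trained on the easy study conditions (minutes)."""
    train_w, val = easy_split
    model, log = tr.train_detector(train_w, val, REDUCED_MODEL, REDUCED_TRAIN)
    return model, log


@pytest.fixture(scope="session")
def trained_counter(easy_windows):
    """Reduced pulse counter trained on all (empty included) easy windows."""
    config = tr.TrainConfig(learning_rate=1e-3, decay_period_epochs=25,
                            batch_size=6, max_epochs=35, seed=0)
    windows = easy_windows[:500]
    return tr.train_counter(windows, config, base_width=8, blocks=(1, 1, 1, 1))
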