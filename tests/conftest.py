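import numpy as np
import pytest

import lfea

# Desk-scale study conditions used throughout the suite: 4 layers with
# h widths (16, 12, 10, 8), z width 2, windows of 50 samples x 4 channels.
REDUCED = dict(T=50, C=4, h_dims=(16, 12, 10, 8), z_dim=2)


def reduced_configs(T=50, C=4):
    return lfea.default_layer_configs(
        T, C, h_dims=REDUCED["h_dims"], z_dim=REDUCED["z_dim"],
        enc_hidden_first=(64,), enc_hidden_rest=(32,),
        dec_hidden=(64,), disc_hidden=(32, 32))


def train_reduced(ws, seed, epochs=20, beta=0.2, lambda_=0.1):
    model = lfea.init_model(ws.window_len, ws.n_channels,
                            reduced_configs(ws.window_len, ws.n_channels),
                            seed=seed)
    opts = lfea.TrainOptions(epochs_per_layer=epochs, batch_size=128,
                             seed=seed, beta=beta, lambda_=lambda_)
    model, hists = lfea.fit(model, ws, opts)
    return model, hists


@pytest.fixture(scope="session")
def gesture_data():
    """Standardized 5-gesture dataset at desk scale (n=2000, noise 0.05)."""
    ds = lfea.make_gesture_dataset(2000, 5, T=50, C=4, noise_sd=0.05, seed=1)
    return lfea.standardize(ds.to_windowset()), ds


@pytest.fixture(scope="session")
def trained_gesture_model(gesture_data):
    ws, _ = gesture_data
    model, _ = train_reduced(ws, seed=0)
    return model, ws
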