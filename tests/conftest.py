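"""Shared fixtures: tiny synthetic datasets and a trained small network."""

from __future__ import annotations

import numpy as np
import pytest

from mifnet import TrainConfig, assemble_mifnet, get_preset, train
from mifnet.nn import Network
from mifnet.synthetic import default_scan_spec, make_patch_dataset


@pytest.fixture(scope="session")
def separable_data():
    """Well-separated synthetic patches: (train X, y), (test X, y)."""
    Xtr, ytr = make_patch_dataset(80, separation=8.0, noise_sd=0.05, seed=11)
    Xte, yte = make_patch_dataset(40, separation=8.0, noise_sd=0.05, seed=12)
    return (Xtr, ytr), (Xte, yte)


@pytest.fixture(scope="session")
def trained_mifnet10(separable_data):
    """mifnet10 trained 5 epochs with ADAM on the separable patches.

    Session-scoped: training takes ~half a minute and several tests reuse
    the same fitted network and history.
    """
    (Xtr, ytr), _ = separable_data
    config = get_preset("mifnet10")
    network = Network(assemble_mifnet(config), seed=3,
                      input_size=config.input_size)
    history = train(network, Xtr, ytr,
                    TrainConfig(optimizer="adam", learning_rate=0.001,
                                batch_size=32, epochs=5, seed=3))
    return network, history


@pytest.fixture(scope="session")
def synthetic_scan(tmp_path_factory):
    """A written synthetic MetaImage scan + candidates table."""
    from mifnet.synthetic import make_synthetic_scan

    out = tmp_path_factory.mktemp("scan")
    spec = default_scan_spec(seed=7, n_nodules=3, n_negatives=15)
    header, csv = make_synthetic_scan(spec, out)
    return spec, header, csv
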