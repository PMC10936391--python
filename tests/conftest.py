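"""Shared fixtures: small synthetic studies and a quickly trained model.

Everything is generated programmatically at test time; patch sizes are
scaled down (64/128 px) from the 500-px full scale to keep CPU runtime
small, with structural sizes scaling proportionally inside the generator.
"""

from __future__ import annotations

import numpy as np
import pytest

from synemclass import dataset as dsm
from synemclass import model as mm
from synemclass.synthetic_em import (
    ClassParams,
    SynthConfig,
    _default_class_params,
    generate_dataset,
)


def strong_class_params() -> dict:
    """Strongly separable valence classes: vesicle-count means 10 vs 40
    (sd 3) and a 0.3 offset in PSD intensity."""
    cp = _default_class_params()
    cp["excitatory"] = ClassParams((40.0, 3.0), (0.018, 0.004), 0.45)
    cp["inhibitory"] = ClassParams((10.0, 3.0), (0.025, 0.005), 0.15)
    return cp


def null_class_params() -> dict:
    """Identical class-conditional distributions: no signal by construction."""
    cp = _default_class_params()
    cp["excitatory"] = cp["inhibitory"] = ClassParams((24.0, 6.0), (0.020, 0.005), 0.25)
    return cp


def make_study(seed: int, *, class_params=None, patch_size=128, n_cells=20,
               synapses_per_cell=(3, 5), frames_per_synapse=(3, 4),
               labels=("excitatory", "inhibitory")):
    """Generate, deduplicate and cell-split one synthetic study."""
    cfg = SynthConfig(
        patch_size=patch_size, n_cells=n_cells,
        synapses_per_cell=synapses_per_cell,
        frames_per_synapse=frames_per_synapse,
        class_params=class_params or strong_class_params(),
        labels=labels, seed=seed,
    )
    ds = generate_dataset(cfg)
    patches = dsm.deduplicate(ds.patches)
    spec = dsm.SplitSpec(fractions=(0.5, 0.25, 0.25), seed=seed + 1)
    return dsm.split_by_cell(patches, spec)


@pytest.fixture(scope="session")
def tiny_study():
    """Small 64-px strong-effect study shared across tests."""
    return make_study(3, patch_size=64, n_cells=12, synapses_per_cell=(2, 3),
                      frames_per_synapse=(3, 3))


@pytest.fixture(scope="session")
def trained_model(tiny_study):
    """A briefly but genuinely trained small CNN plus its config."""
    train, val, _ = tiny_study
    cfg = mm.ModelConfig(input_size=64, epochs_phase1=3, epochs_phase2=5, seed=0)
    net = mm.build_model(cfg)
    report = mm.train_two_phase(net, train, val, cfg)
    return net, cfg, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
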