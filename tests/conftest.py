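"""Shared fixtures: small synthetic scenes and a trained model.

Everything is generated programmatically with fixed seeds so the suite
is deterministic and needs no data files.
"""

import numpy as np
import pytest

from seedhsi import (EndmemberSpec, RunConfig, default_grid, render_scene,
                     simulate_dataset)
from seedhsi.workflow import scenes_to_table, train_viability_model


@pytest.fixture(scope="session")
def spec():
    return EndmemberSpec()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_scene(spec):
    """A 12-seed scene with moderate noise, plus its references and truth."""
    return render_scene(12, spec, rng=7)


@pytest.fixture(scope="session")
def clean_scene(spec):
    """Noise-free scene: unit scatter, no baseline shift, no sensor noise."""
    return render_scene(8, spec, rng=11, scatter_sigma=0.0,
                        baseline_sigma=0.0, tilt_sigma=0.0, noise_counts=0.0)


@pytest.fixture(scope="session")
def labelled_table(spec, config):
    """Mean-spectra table from a 2 x 40 seed batch, both camera sides."""
    scenes = simulate_dataset(40, spec, rng=3, seeds_per_scene=40)
    return scenes_to_table(scenes, config)


@pytest.fixture(scope="session")
def trained(labelled_table):
    """A trained, threshold-shifted PLS-DA model and its training result."""
    return train_viability_model(labelled_table, "mean_norm", max_lv=8, rng=5)
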