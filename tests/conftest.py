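"""Shared fixtures: small synthetic complexes built once per session."""

import numpy as np
import pytest

from gfdyn.synthetic import (PlantedBridge, SyntheticSpec, build_toy_complex,
                             sample_trajectory)


@pytest.fixture(scope="session")
def bridged_spec():
    return SyntheticSpec(
        planted_bridges=[PlantedBridge(2, 2, 0.9), PlantedBridge(5, 5, 0.6)],
        n_frames=120, frame_spacing=100.0, seed=42)


@pytest.fixture(scope="session")
def bridged_system(bridged_spec):
    model, ff = build_toy_complex(bridged_spec)
    return model, ff


@pytest.fixture(scope="session")
def bridged_trajectory(bridged_spec, bridged_system):
    model, _ = bridged_system
    return sample_trajectory(model, bridged_spec)


@pytest.fixture(scope="session")
def plain_system():
    """A bridge-free 8+8 complex with its force field."""
    spec = SyntheticSpec(n_ligand_residues=8, n_receptor_residues=8,
                         n_frames=10, seed=7)
    model, ff = build_toy_complex(spec)
    return spec, model, ff


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
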