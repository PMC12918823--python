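"""Shared synthetic fixtures. Everything is generated at test time from
fixed seeds; nothing is read from disk."""

import numpy as np
import pytest

from tglow import simulate as sim


@pytest.fixture(scope="session")
def plate_field():
    """One noise-free field with full cells, nuclei and masks."""
    data, manifest = sim.simulate_plate_fields(
        n_plates=1, n_fields=1, cells_per_field=10, seed=7,
        shape=(6, 128, 128), cell_radius_um=(4, 7), edge_margin_px=10)
    (addr, (stack, masks)), = data.items()
    return addr, stack, masks, manifest


@pytest.fixture(scope="session")
def bead_stack():
    stack, manifest = sim.simulate_beads(
        n_beads=5, sigmas=(2.0, 1.0, 1.0), seed=5)
    return stack, manifest


@pytest.fixture(scope="session")
def flatfield_images():
    coeffs = sim.quartic_field_coefficients(0.4)
    images, manifest = sim.simulate_flatfield_images(
        n_images=40, flatfield_coeffs=coeffs, seed=2)
    return images, coeffs, manifest


@pytest.fixture(scope="session")
def feature_fixture():
    table, manifest = sim.simulate_feature_table(
        n_cells=3000, blocks=[(10, 0.9), (10, 0.9), (10, 0.9)],
        group_effects={"cell_intensity_b0f0_dna": 0.5},
        phase_structure={"G0": 0.6, "G1": 0.3, "S": 0.1},
        seed=12)
    return table, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(0)
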