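"""Shared fixtures: small synthetic systems generated at test time."""

import numpy as np
import pytest

from hydrashell import synthetic_data as synth


@pytest.fixture(scope="session")
def small_sphere_spec():
    """A fast sphere system for unit-level checks (not the study conditions)."""
    return synth.SyntheticSpec(
        solute_shape="sphere",
        solute_radius_or_length=8.0,
        n_solute_atoms=200,
        electrons_per_solute_atom=6.0,
        box=(46.0, 46.0, 46.0),
        n_frames=20,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_sphere_system(small_sphere_spec):
    solute = synth.make_solute(small_sphere_spec)
    system, truth = synth.hydrate(solute, small_sphere_spec)
    return solute, system, truth


@pytest.fixture(scope="session")
def small_buffer(small_sphere_spec):
    return synth.make_water_box(small_sphere_spec.box, seed=102,
                                n_frames=small_sphere_spec.n_frames)


@pytest.fixture(scope="session")
def point_table():
    """Form-factor table including the synthetic bead pseudo-element."""
    spec = synth.SyntheticSpec()
    return synth.formfactor_table_for(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
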