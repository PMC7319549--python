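import numpy as np
import pytest

from waterloan.synth_fixtures import (
    FixtureSpec,
    family_reference_db,
    generate_bundle,
    generate_family,
    plant_waters,
)


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    """A compact family: quick to generate, still has a real pore."""
    return FixtureSpec(
        seed=11,
        n_helices=7,
        helix_length=24,
        family_size=4,
        n_cavity_waters=5,
        n_surface_waters=3,
    )


@pytest.fixture(scope="session")
def small_family(small_spec):
    return generate_family(small_spec)


@pytest.fixture(scope="session")
def small_db(small_family):
    return family_reference_db(small_family)


@pytest.fixture(scope="session")
def bundle_with_waters():
    spec = FixtureSpec(seed=7, n_helices=7, helix_length=24,
                       n_cavity_waters=4, n_surface_waters=2)
    bundle = generate_bundle(spec)
    model, labels, coords = plant_waters(bundle, spec)
    return spec, model, labels, coords


def rigid_move_model(model, rotation: np.ndarray, translation: np.ndarray):
    """Apply a rigid motion to every atom of a model copy."""
    out = model.copy()
    for _, atom in out.iter_atoms():
        atom.coords = rotation @ atom.coords + translation
    return out
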