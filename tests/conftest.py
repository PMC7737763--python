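import numpy as np
import pytest
from hypothesis import settings

from chainview import fixtures as fx
from chainview import model_io

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def helix_spec():
    return fx.FixtureSpec(
        seed=11,
        n_residues=8,
        sequence="ASVLG",
        torsion_regime="helix",
        b_base=20.0,
        chi_angles={1: [62.0], 3: [-65.0, 170.0]},
        resolution=2.0,
    )


@pytest.fixture(scope="session")
def helix_model(helix_spec):
    """In-memory model (full coordinate precision, no file round-trip)."""
    return model_io.structure_to_model(fx.synthetic_model(helix_spec))


@pytest.fixture(scope="session")
def helix_pdb(tmp_path_factory, helix_spec):
    """The same helix written to PDB and re-read (file precision)."""
    path = tmp_path_factory.mktemp("models") / "helix.pdb"
    model = fx.write_model_pdb(fx.synthetic_model(helix_spec), path)
    return path, model


@pytest.fixture(scope="session")
def helix_map(helix_model, helix_spec):
    return fx.synthetic_map(helix_model, helix_spec)


@pytest.fixture(scope="session")
def rotamer_reference():
    return fx.synthetic_rotamer_reference(seed=5)


def random_grid_spec(rng: np.random.Generator, max_dims: int = 4):
    """Random small contour-grid axis metadata for property tests."""
    n_dims = int(rng.integers(1, max_dims + 1))
    sizes = [int(rng.integers(2, 7)) for _ in range(n_dims)]
    origins = [float(rng.uniform(-180, 180)) for _ in range(n_dims)]
    spacings = [360.0 / s for s in sizes]
    return {"origins": origins, "spacings": spacings, "sizes": sizes}
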