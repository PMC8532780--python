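import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helixcst import StructureModel, build_helix
from helixcst.synthetic_data import HelixSpec


@pytest.fixture(scope="session")
def ala12():
    """Ideal 12-residue polyalanine alpha-helix (phi=-57, psi=-47)."""
    return build_helix(HelixSpec(sequence=("ALA",) * 12))


@pytest.fixture(scope="session")
def alm_model():
    """Ideal-helix model of the 20-residue alamethicin E18 sequence."""
    return build_helix(HelixSpec())


def random_rotation(seed: int) -> np.ndarray:
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


def rigid_motion(model: StructureModel, seed: int) -> tuple[StructureModel, np.ndarray, np.ndarray]:
    """Apply a seeded random rotation + translation; returns (model, R, t)."""
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    moved = StructureModel(cell=model.cell, space_group=model.space_group)
    for a in model.atoms:
        moved.add(type(a)(element=a.element, name=a.name, coords=R @ a.coords + t,
                          residue_index=a.residue_index, residue_name=a.residue_name,
                          chain_id=a.chain_id))
    return moved, R, t
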