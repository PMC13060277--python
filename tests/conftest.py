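import numpy as np
import pytest

from ensrect.structure_io import Structure, StructureEnsemble
from ensrect.synthetic_systems import SyntheticSpec, double_well, synthetic_ca_ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ca_ensemble():
    """10-member Cα ensemble with one planted mode and mild noise."""
    ens, coeffs = synthetic_ca_ensemble(
        SyntheticSpec(mode_amplitudes=(2.0,), noise_scale=0.05, n_members=10,
                      n_residues=12, seed=7)
    )
    return ens, coeffs


@pytest.fixture
def backbone_structure():
    """One 4-residue structure with full N/CA/C/O backbone."""
    rng = np.random.default_rng(3)
    names, res_ids, coords = [], [], []
    for r in range(1, 5):
        for nm in ("N", "CA", "C", "O"):
            names.append(nm)
            res_ids.append(r)
            coords.append(rng.normal(size=3) + [3.8 * r, 0, 0])
    return Structure(atom_names=names, residue_ids=res_ids,
                     coords=np.asarray(coords), model_id=1)


@pytest.fixture
def symmetric_double_well():
    return double_well(barrier=3.0)


def rigid_move(coords, angle_deg, axis, shift):
    """Apply a rotation (degrees about a unit axis) plus translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * np.asarray(axis, float))
    return coords @ rot.as_matrix().T + np.asarray(shift, float)
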