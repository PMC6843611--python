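import numpy as np
import pytest

from memion.trajectory import AtomRecord, Role, Species, Trajectory


def make_trajectory(atom_specs, coords, box=(6.0, 6.0, 8.0), times=None):
    """Build a Trajectory from (species, name, role, charge, mol_id) tuples.

    ``coords`` has shape (n_frames, n_atoms, 3) or (n_atoms, 3).
    """
    atoms = [
        AtomRecord(
            atom_id=i,
            molecule_id=mol,
            species=Species(sp),
            atom_name=name,
            role=Role(role),
            partial_charge=charge,
        )
        for i, (sp, name, role, charge, mol) in enumerate(atom_specs)
    ]
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_frames = coords.shape[0]
    if times is None:
        times = np.arange(n_frames, dtype=float)
    boxes = np.tile(np.asarray(box, dtype=float), (n_frames, 1))
    return Trajectory(atoms=atoms, coords=coords, times=times, boxes=boxes)


def flat_bilayer_atoms(z=1.8):
    """Two lipid P/N pairs, one per leaflet, centred at z = 0."""
    return (
        [
            ("DOPC", "P", "LIPID_P", -1.0, 0),
            ("DOPC", "N", "LIPID_N", 1.0, 0),
            ("DOPC", "P", "LIPID_P", -1.0, 1),
            ("DOPC", "N", "LIPID_N", 1.0, 1),
        ],
        [
            [0.0, 0.0, z],
            [0.0, 0.0, z + 0.1],
            [1.0, 1.0, -z],
            [1.0, 1.0, -(z + 0.1)],
        ],
    )


@pytest.fixture
def small_system():
    """A modest synthetic bilayer with surfactants and cholesterol."""
    from memion.synthetic import (
        CholesterolSpec, SurfactantSpec, SyntheticSpec, generate_system,
    )

    spec = SyntheticSpec(
        n_lipids_per_leaflet=36,
        surfactants=[SurfactantSpec(species="KOR105", count=20)],
        cholesterol=CholesterolSpec(count=16, offspring_sigma=0.25),
        n_frames=5,
        seed=11,
    )
    return generate_system(spec)
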