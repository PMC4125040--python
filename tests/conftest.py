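import numpy as np
import pytest

from tcrmd.synthetic_data import ToyComplexSpec, build_toy_complex
from tcrmd.trajectory_io import Atom, Ensemble


@pytest.fixture(scope="session")
def toy():
    return build_toy_complex()


@pytest.fixture(scope="session")
def noiseless_toy():
    return build_toy_complex(ToyComplexSpec(sigma_nm=0.0, n_frames=5))


def make_atoms(spec):
    """Atoms from a compact spec: list of (name, element, resid, chain)."""
    return [Atom(name=n, element=e, residue_index=r, residue_name="GLY", chain_id=c)
            for n, e, r, c in spec]


def make_ensemble(atom_spec, frames, sim_id="sim", times=None):
    frames = np.asarray(frames, dtype=float)
    if times is None:
        times = np.arange(frames.shape[0], dtype=float) + 1.0
    return Ensemble(atoms=make_atoms(atom_spec), frames=frames,
                    times=np.asarray(times, dtype=float), sim_id=sim_id)


def random_rigid_transform(rng):
    """Random rotation matrix + translation vector."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    trans = rng.normal(0, 5.0, size=3)
    return rot, trans
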