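import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from redoxscan.model import Atom, Box, Structure, Trajectory, detect_disulfides
from redoxscan.synthetic import ToyProteinSpec, build_toy_protein


@pytest.fixture(scope="session")
def toy_protein() -> Structure:
    return build_toy_protein(ToyProteinSpec(), seed=1)


@pytest.fixture(scope="session")
def toy_bonds(toy_protein):
    return detect_disulfides(toy_protein)


def make_atom(i, name, element, mass, pos, resname="ALA", resid=1, chain="A"):
    return Atom(i, name, element, mass, resname, resid, chain, np.asarray(pos, float))


@pytest.fixture
def two_bond_system():
    """Two isolated disulfides (SG-only cysteines) plus helpers to build
    probe-containing trajectories with scripted probe paths."""
    atoms = [
        make_atom(0, "SG", "S", 32.06, [2.0, 2.0, 2.0], "CYS", 1),
        make_atom(1, "SG", "S", 32.06, [2.205, 2.0, 2.0], "CYS", 2),
        make_atom(2, "SG", "S", 32.06, [6.0, 6.0, 6.0], "CYS", 3),
        make_atom(3, "SG", "S", 32.06, [6.205, 6.0, 6.0], "CYS", 4),
    ]
    box = Box.cubic(10.0)

    def with_probes(probe_paths):
        """probe_paths: list over probes of (n_frames, 3) positions."""
        n_frames = len(probe_paths[0])
        all_atoms = [make_atom(a.index, a.name, a.element, a.mass, a.position,
                               a.residue_name, a.residue_id) for a in atoms]
        for k in range(len(probe_paths)):
            all_atoms.append(make_atom(4 + k, "P", "P", 250.19,
                                       probe_paths[k][0], "TCEP", 10 + k, "X"))
        top = Structure(all_atoms, box=box)
        frames = np.empty((n_frames, len(all_atoms), 3))
        frames[:, :4, :] = top.positions[:4]
        for k, path in enumerate(probe_paths):
            frames[:, 4 + k, :] = np.asarray(path)
        return Trajectory(topology=top, frames=frames,
                          times=np.arange(n_frames, dtype=float) * 10.0,
                          box_per_frame=[box] * n_frames)

    base = Structure(atoms, box=box)
    return base, detect_disulfides(base), with_probes
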