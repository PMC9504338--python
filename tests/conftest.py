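import numpy as np
import pytest

from condyn import trajgen
from condyn.traj_io import Topology, Trajectory, select_atoms


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def peptide_pdb(tmp_path):
    """Hand-written 5-residue Calpha-only PDB across two chains."""
    lines = []
    serial = 1
    for chain, resids in (("A", [1, 2, 3]), ("B", [1, 2])):
        for r in resids:
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA {chain}{r:4d}    "
                f"{float(serial):8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"           C")
            serial += 1
    path = tmp_path / "peptide.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def make_calpha_trajectory(coords: np.ndarray, frame_spacing: float = 1.0) -> Trajectory:
    """Wrap a (frames, n, 3) array as a Calpha trajectory."""
    n = coords.shape[1]
    top = Topology(
        names=["CA"] * n,
        resids=np.arange(1, n + 1),
        resnames=["ALA"] * n,
        chains=["A"] * n,
        masses=np.full(n, 12.011),
        elements=["C"] * n,
    )
    return Trajectory(top, coords, frame_spacing)


@pytest.fixture
def rigid_scaffold(rng):
    """A random, non-degenerate 12-atom structure."""
    return 10.0 * rng.standard_normal((12, 3))


@pytest.fixture(scope="session")
def receptor_run():
    """A moderately long planted 3-state receptor trajectory, shared across tests."""
    spec = trajgen.default_receptor_spec()
    traj, labels = trajgen.generate_receptor_trajectory(spec, 20000, seed=11)
    sel = select_atoms(traj.topology, "name CA")
    return spec, traj, labels, sel
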