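"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from xbtraj.io_structures import Atom, Frame, Trajectory
from xbtraj.synthetic_data import StateSpec, SyntheticSpec, simulate_xb_trajectory


SIMPLE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 20.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 21.50           C
ATOM      3  C   ALA A   1      12.759   7.096  -4.946  1.00 19.00           C
ATOM      4  O   ALA A   1      13.164   7.797  -5.874  1.00 18.20           O
ATOM      5  CB  ALA A   1      12.132   4.654  -4.862  1.00 22.00           C
END
"""


@pytest.fixture
def simple_pdb_text() -> str:
    return SIMPLE_PDB


def build_pocket_trajectory(
    ligand_positions: np.ndarray,
    times_ns: np.ndarray | None = None,
    ligand_names=("C1", "CL1", "C2"),
    ligand_elements=("C", "Cl", "C"),
) -> Trajectory:
    """A trajectory with a static 4-Cα pocket and a caller-supplied ligand.

    ``ligand_positions`` has shape (n_frames, n_ligand_atoms, 3).
    """
    ligand_positions = np.asarray(ligand_positions, dtype=float)
    n_frames, n_lig, _ = ligand_positions.shape
    pocket = np.array(
        [[3.0, 3.5, 2.0], [-3.0, 3.0, -2.5], [2.5, -3.5, -2.0], [-2.8, -3.0, 2.8]]
    )
    topology = []
    for i in range(n_lig):
        topology.append(
            Atom(i + 1, ligand_names[i], ligand_elements[i], "LIG", 1, "L", i,
                 b_factor=20.0, is_ligand=True)
        )
    for k in range(4):
        topology.append(
            Atom(n_lig + k + 1, "CA", "C", "GLY", 10 + k, "A", n_lig + k,
                 b_factor=30.0)
        )
    if times_ns is None:
        times_ns = np.arange(n_frames, dtype=float)
    frames = []
    for f in range(n_frames):
        coords = np.vstack([ligand_positions[f], pocket])
        frames.append(Frame(time_ns=float(times_ns[f]), coordinates=coords))
    return Trajectory(topology=topology, frames=frames, label="test")


@pytest.fixture
def two_state_spec() -> SyntheticSpec:
    """Well-separated bound/broken states (region == state almost surely)."""
    return SyntheticSpec(
        n_frames=1000,
        dt_ns=0.06,
        states=(
            StateSpec(0.6, 3.6, 0.05, 162.0, 2.0),
            StateSpec(0.4, 5.5, 0.2, 110.0, 5.0),
        ),
        seed=42,
    )


@pytest.fixture
def synthetic_trajectory(two_state_spec):
    return simulate_xb_trajectory(two_state_spec)


def crystal_mimic_pdb() -> str:
    """Synthetic stand-in for a crystal D4R–nemonapride-like complex.

    One-model PDB whose ligand Cl → Val193 backbone-O geometry is placed
    exactly at the crystallographic halogen-bond values d = 3.7 Å and
    σ-hole angle = 163.2°.  This is a constructed fixture, not the
    deposited entry.
    """
    from xbtraj.io_structures import write_structure

    spec = SyntheticSpec(
        n_frames=1,
        dt_ns=1.0,
        states=(StateSpec(1.0, 3.7, 0.0, 163.2, 0.0),),
        seed=5,
    )
    traj, _truth = simulate_xb_trajectory(spec)
    return write_structure(traj)


@pytest.fixture
def crystal_mimic_text() -> str:
    return crystal_mimic_pdb()
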