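"""Ground-truthed synthetic trajectories and toy XSAR tables.

Bound-ligand MD shows a halogen bond being formed and broken dynamically:
the geometry switches between a strong (primary-region) state and a weak
or broken state.  :func:`simulate_xb_trajectory` emulates exactly that —
per-frame (d, θ) drawn from per-state Gaussians, with either independent
per-frame state draws or a two-state Markov chain — and realizes the
geometry in coordinates exactly: the acceptor oxygen is placed on a cone
about the C–Cl axis so the generated frame reproduces the drawn distance
and σ-hole angle to machine precision.  Every frame's state, d, θ and
region are emitted as ground truth, so each downstream pipeline stage can
be tested against planted values without any real trajectory.

The minimal topology is a four-heavy-atom chloro-ligand (HETATM), a
valine-like acceptor residue whose backbone O carries the halogen bond,
and four fixed pocket Cα atoms for superposition.  There is no force
field, membrane or solvent — the generator reproduces the statistical
structure the analysis assumes, not physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SyntheticSpecError
from .io_structures import Atom, Frame, Trajectory, write_structure
from .xb_geometry import RegionThresholds, classify_regions
from .xsar import LigandRecord

#: C–Cl covalent bond length (Å) used for the synthetic donor.
C_CL_BOND = 1.74

#: Redraw bound for sampled distances (steric lower bound, Å).
D_MIN = 2.5


@dataclass(frozen=True)
class StateSpec:
    """One geometric state: mixture weight and (d, θ) Gaussian parameters."""

    weight: float
    d_mean: float
    d_sd: float
    theta_mean: float
    theta_sd: float

    def __post_init__(self) -> None:
        if self.d_sd < 0 or self.theta_sd < 0:
            raise SyntheticSpecError("state standard deviations must be >= 0")
        if self.weight < 0:
            raise SyntheticSpecError("state weights must be >= 0")


#: Default two-state model: a bound state at crystal-like geometry that is
#: primary ~60% of the time, and a broken state outside both cutoffs —
#: the occupancy scale reported for the strongest D4 halogen-bond contacts.
DEFAULT_STATES = (
    StateSpec(0.6, 3.8, 0.3, 163.0, 8.0),
    StateSpec(0.4, 5.2, 0.5, 115.0, 15.0),
)


@dataclass
class SyntheticSpec:
    """Full specification of one synthetic halogen-bond trajectory.

    Defaults give a 60 ns trajectory (2000 frames at 30 ps) of the
    two-state bound/broken model.
    """

    n_frames: int = 2000
    dt_ns: float = 0.03
    states: tuple[StateSpec, ...] = DEFAULT_STATES
    transition: str = "iid"  # "iid" or "markov"
    stay_probability: float = 0.95
    seed: int = 0
    thresholds: RegionThresholds = field(default_factory=RegionThresholds)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise SyntheticSpecError("n_frames must be >= 1")
        if self.dt_ns <= 0:
            raise SyntheticSpecError("dt_ns must be positive")
        if not self.states:
            raise SyntheticSpecError("at least one state is required")
        self.states = tuple(
            s if isinstance(s, StateSpec) else StateSpec(*s) for s in self.states
        )
        total = sum(s.weight for s in self.states)
        if abs(total - 1.0) > 1e-8:
            raise SyntheticSpecError(f"state weights must sum to 1, got {total}")
        if self.transition not in ("iid", "markov"):
            raise SyntheticSpecError("transition must be 'iid' or 'markov'")
        if self.transition == "markov" and len(self.states) != 2:
            raise SyntheticSpecError("markov transition requires exactly 2 states")
        if not 0.0 <= self.stay_probability <= 1.0:
            raise SyntheticSpecError("stay_probability must be in [0, 1]")


# ---------------------------------------------------------------------------
# Topology layout (coordinates in Å; ligand and pocket are static)
# ---------------------------------------------------------------------------

_LIGAND_ATOMS = (  # name, element, position
    ("C1", "C", (0.0, 0.0, 0.0)),
    ("CL1", "Cl", (C_CL_BOND, 0.0, 0.0)),
    ("C2", "C", (-1.40, 0.20, 0.10)),
    ("C3", "C", (-2.15, 1.25, -0.30)),
)

_ACCEPTOR_BACKBONE = (  # name, element, offset from the carbonyl O
    ("N", "N", (1.20, 2.90, 1.00)),
    ("CA", "C", (0.80, 1.90, 0.40)),
    ("C", "C", (0.00, 1.23, 0.00)),
)

_POCKET_CA = (  # four glycine Cα within 6 Å of the ligand
    (3.00, 3.50, 2.00),
    (-3.00, 3.00, -2.50),
    (2.50, -3.50, -2.00),
    (-2.80, -3.00, 2.80),
)


def _build_topology() -> list[Atom]:
    atoms: list[Atom] = []
    idx = 0
    for name, elem, _ in _LIGAND_ATOMS:
        atoms.append(
            Atom(idx + 1, name, elem, "LIG", 1, "L", idx, b_factor=20.0,
                 is_ligand=True)
        )
        idx += 1
    for name, elem, _ in _ACCEPTOR_BACKBONE:
        atoms.append(Atom(idx + 1, name, elem, "VAL", 193, "A", idx, b_factor=25.0))
        idx += 1
    atoms.append(Atom(idx + 1, "O", "O", "VAL", 193, "A", idx, b_factor=25.0))
    idx += 1
    for k, _pos in enumerate(_POCKET_CA):
        atoms.append(Atom(idx + 1, "CA", "C", "GLY", 10 + k, "A", idx,
                          b_factor=30.0))
        idx += 1
    return atoms


def _sample_states(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([s.weight for s in spec.states])
    if spec.transition == "iid":
        return rng.choice(len(weights), size=spec.n_frames, p=weights)
    states = np.empty(spec.n_frames, dtype=int)
    states[0] = rng.choice(len(weights), p=weights)
    stay = spec.stay_probability
    flips = rng.random(spec.n_frames - 1) >= stay
    for i in range(1, spec.n_frames):
        states[i] = 1 - states[i - 1] if flips[i - 1] else states[i - 1]
    return states


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Redraw-on-out-of-range truncated Gaussian sample."""
    if sd == 0.0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return float(x)
    raise SyntheticSpecError(
        f"truncated sampling failed for N({mean}, {sd}) on ({lo}, {hi}]"
    )


def simulate_xb_trajectory(
    spec: SyntheticSpec,
) -> tuple[Trajectory, pd.DataFrame]:
    """Generate a synthetic trajectory plus its per-frame ground truth.

    Returns ``(trajectory, truth)`` where ``truth`` has columns
    ``frame, time_ns, state, d, theta, region``.  The acceptor O is placed
    at distance d from the Cl on a cone of half-angle 180° − θ about the
    C–Cl axis (random azimuth), which realizes the drawn (d, θ) exactly;
    d is truncated to > 2.5 Å and θ to [0, 180] by redrawing.
    """
    rng = np.random.default_rng(spec.seed)
    topology = _build_topology()
    states = _sample_states(spec, rng)

    # fixed coordinates
    base = np.zeros((len(topology), 3))
    for i, (_n, _e, pos) in enumerate(_LIGAND_ATOMS):
        base[i] = pos
    o_index = len(_LIGAND_ATOMS) + len(_ACCEPTOR_BACKBONE)
    for k, pos in enumerate(_POCKET_CA):
        base[o_index + 1 + k] = pos

    c_pos = np.array(_LIGAND_ATOMS[0][2])
    x_pos = np.array(_LIGAND_ATOMS[1][2])
    v1 = (c_pos - x_pos) / np.linalg.norm(c_pos - x_pos)  # X -> C direction
    # orthonormal azimuth basis for the cone
    e1 = np.array([0.0, 1.0, 0.0])
    e2 = np.array([0.0, 0.0, 1.0])

    frames: list[Frame] = []
    d_arr = np.empty(spec.n_frames)
    th_arr = np.empty(spec.n_frames)
    for i in range(spec.n_frames):
        st = spec.states[states[i]]
        d = _truncated_normal(rng, st.d_mean, st.d_sd, D_MIN, np.inf)
        theta = _truncated_normal(rng, st.theta_mean, st.theta_sd, 0.0, 180.0)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        w = np.cos(phi) * e1 + np.sin(phi) * e2
        rad = np.radians(theta)
        a_pos = x_pos + d * (np.cos(rad) * v1 + np.sin(rad) * w)
        coords = base.copy()
        coords[o_index] = a_pos
        for j, (_n, _e, off) in enumerate(_ACCEPTOR_BACKBONE):
            coords[len(_LIGAND_ATOMS) + j] = a_pos + np.array(off)
        frames.append(Frame(time_ns=i * spec.dt_ns, coordinates=coords))
        d_arr[i] = d
        th_arr[i] = theta

    truth = pd.DataFrame(
        {
            "frame": np.arange(spec.n_frames),
            "time_ns": np.arange(spec.n_frames) * spec.dt_ns,
            "state": states,
            "d": d_arr,
            "theta": th_arr,
            "region": classify_regions(d_arr, th_arr, spec.thresholds),
        }
    )
    traj = Trajectory(topology=topology, frames=frames, label="synthetic-xb")
    return traj, truth


def write_fixture(
    spec: SyntheticSpec, outdir: str | Path, stem: str = "synthetic_xb"
) -> tuple[Path, Path]:
    """Write a multi-model PDB plus its ground-truth CSV; returns both paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj, truth = simulate_xb_trajectory(spec)
    pdb_path = outdir / f"{stem}.pdb"
    csv_path = outdir / f"{stem}_truth.csv"
    write_structure(traj, pdb_path)
    truth.to_csv(csv_path, index=False)
    return pdb_path, csv_path


# ---------------------------------------------------------------------------
# Toy XSAR tables
# ---------------------------------------------------------------------------

#: (chemotype, parent SMILES, {pattern: derivative SMILES})
_SCAFFOLDS = (
    (
        "arylpiperazine",
        "c1ccc(N2CCNCC2)cc1",
        {
            "2-Cl": "Clc1ccccc1N1CCNCC1",
            "2,3-diCl": "Clc1cccc(N2CCNCC2)c1Cl",
        },
    ),
    (
        "benzylpiperidine",
        "C1CCN(Cc2ccccc2)CC1",
        {
            "2-Cl": "Clc1ccccc1CN1CCCCC1",
        },
    ),
)

#: Planted potency folds per scaffold pattern: the long (arylpiperazine)
#: class gains strongly from chlorination; the short class barely moves.
DEFAULT_FOLDS = {
    ("arylpiperazine", "2,3-diCl"): 122.0,
    ("arylpiperazine", "2-Cl"): 55.0,
    ("benzylpiperidine", "2-Cl"): 1.3,
}


def make_toy_xsar(
    n_parents: int = 2,
    substitution_patterns: dict[tuple[str, str], str] | None = None,
    effect_model: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> list[LigandRecord]:
    """Emit a small activity table with planted Xeffect ground truth.

    Parents cycle through an arylpiperazine and a benzylpiperidine
    scaffold; each derivative's activity is ``parent_activity / fold`` for
    its planted fold, so :func:`xbtraj.xsar.xeffect` recovers the fold
    exactly.  Parent activities are drawn log-normally around ~120 nM.
    """
    if n_parents < 1:
        raise SyntheticSpecError("n_parents must be >= 1")
    folds = dict(DEFAULT_FOLDS if effect_model is None else effect_model)
    rng = np.random.default_rng(seed)
    records: list[LigandRecord] = []
    for p in range(n_parents):
        chem, parent_smiles, derivs = _SCAFFOLDS[p % len(_SCAFFOLDS)]
        activity = float(np.exp(rng.normal(np.log(120.0), 0.5)))
        pid = f"{chem}-{p}"
        records.append(LigandRecord(pid, parent_smiles, activity))
        source = derivs if substitution_patterns is None else {
            pat: smi
            for (c, pat), smi in substitution_patterns.items()
            if c == chem
        }
        for pattern, smiles in source.items():
            fold = folds.get((chem, pattern), 1.0)
            records.append(
                LigandRecord(f"{pid}-{pattern}", smiles, activity / fold)
            )
    return records
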