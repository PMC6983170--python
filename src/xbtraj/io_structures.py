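"""Structure and trajectory I/O.

Reads single- and multi-model PDB files (and, through MDAnalysis format
adapters, binary coordinate series such as DCD/XTC) into a lightweight
in-memory :class:`Trajectory` container that carries per-atom metadata —
serials, names, elements, residues, chains, B-factors and a ligand flag —
alongside one coordinate array per frame.

Conventions: coordinates in Å, times in ns, PDB residue numbering kept
1-based as in the file.  Alternate locations: only altloc ``'A'`` or blank
is kept; occupancy-based selection is not attempted.
"""

from __future__ import annotations

import io
import os
import tempfile
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import (
    EmptyInputError,
    ParseError,
    SerialLookupError,
    TopologyError,
)

# Residue names treated as solvent/ions rather than ligand when flagging
# HETATM records.
WATER_AND_IONS = frozenset(
    {
        "HOH", "WAT", "H2O", "DOD", "TIP", "T3P", "T4P", "SPC",
        "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "NI",
        "CD", "BR", "IOD", "F", "SO4", "PO4", "GOL", "EDO", "ACT",
    }
)

_TWO_LETTER_ELEMENTS = frozenset(
    {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "NI", "CD", "SE", "CA"}
)

_STANDARD_AA = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL", "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
    }
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One topology atom.

    ``coords_index`` addresses this atom's row in every frame's coordinate
    array.  ``b_factor`` holds the crystallographic temperature factor in Å²
    when the source file provides one.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str
    coords_index: int
    b_factor: float | None = None
    is_ligand: bool = False


@dataclass
class Frame:
    """Coordinates (Å) for every topology atom at one time point (ns)."""

    time_ns: float
    coordinates: np.ndarray  # shape (n_atoms, 3)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")


@dataclass
class Trajectory:
    """A topology plus an ordered list of frames."""

    topology: list[Atom]
    frames: list[Frame]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyInputError("a Trajectory requires at least one frame")
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise TopologyError(
                    f"frame {i} has {fr.coordinates.shape[0]} coordinates "
                    f"for a {n}-atom topology"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times_ns(self) -> np.ndarray:
        return np.array([fr.time_ns for fr in self.frames])

    def atom_by_serial(self, serial: int) -> Atom:
        try:
            return self._serial_index[serial]
        except AttributeError:
            self._serial_index = {a.serial: a for a in self.topology}
            try:
                return self._serial_index[serial]
            except KeyError:
                raise SerialLookupError(f"no atom with serial {serial}") from None
        except KeyError:
            raise SerialLookupError(f"no atom with serial {serial}") from None

    def ligand_atoms(self) -> list[Atom]:
        return [a for a in self.topology if a.is_ligand]

    def receptor_atoms(self) -> list[Atom]:
        return [
            a
            for a in self.topology
            if not a.is_ligand and a.residue_name not in WATER_AND_IONS
        ]

    def residue_atoms(self, chain: str, residue_seq: int) -> list[Atom]:
        return [
            a
            for a in self.topology
            if a.chain == chain and a.residue_seq == residue_seq
        ]


@dataclass
class GenericNumberingMap:
    """Lookup table (chain, residue_seq) -> generic residue label.

    Labels follow the helix-by-position scheme used for GPCRs, e.g.
    ``5x40`` for position 40 of transmembrane helix 5.  The map is supplied
    by the user as a TSV table; no alignment is computed.
    """

    entries: dict[tuple[str, int], str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, source: str | Path) -> "GenericNumberingMap":
        """Read a TSV with header ``chain residue_seq label``."""
        text = Path(source).read_text() if os.path.exists(str(source)) else str(source)
        entries: dict[tuple[str, int], str] = {}
        lines = [ln for ln in text.splitlines() if ln.strip()]
        for lineno, line in enumerate(lines, start=1):
            parts = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and parts[0].lower() == "chain":
                continue
            if len(parts) < 3:
                raise ParseError(
                    f"numbering map line {lineno}: expected 3 columns, got {len(parts)}"
                )
            chain, seq, label = parts[0], parts[1], parts[2]
            try:
                entries[(chain, int(seq))] = label
            except ValueError:
                raise ParseError(
                    f"numbering map line {lineno}: residue_seq {seq!r} is not an integer"
                ) from None
        return cls(entries)

    def label_of(self, chain: str, residue_seq: int) -> str | None:
        return self.entries.get((chain, residue_seq))

    def residue_for_label(self, label: str) -> tuple[str, int] | None:
        for key, val in self.entries.items():
            if val == label:
                return key
        return None


def generic_label(
    numbering: GenericNumberingMap, chain: str, residue_seq: int
) -> str | None:
    """Exact lookup of the generic residue label; ``None`` when absent."""
    return numbering.label_of(chain, residue_seq)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _validate_pdb_lines(text: str) -> int:
    """Pre-scan ATOM/HETATM records; return their count.

    Raises :class:`ParseError` naming the 1-based line number of the first
    malformed record.
    """
    n = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise ParseError(f"line {lineno}: ATOM/HETATM record too short")
        try:
            int(line[6:11])
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError:
            raise ParseError(
                f"line {lineno}: malformed ATOM/HETATM record: {line.rstrip()!r}"
            ) from None
        n += 1
    return n


def _element_from_name(name: str, resname: str, het: bool) -> str:
    """Infer the element symbol when the PDB element column is blank.

    Standard amino-acid atom names start with the element's first letter;
    for HETATM/ion names a leading two-letter symbol (CL, BR, ...) is
    preferred.
    """
    alpha = "".join(c for c in name if c.isalpha()).upper()
    if not alpha:
        return "X"
    if (het or resname in WATER_AND_IONS) and alpha[:2] in _TWO_LETTER_ELEMENTS:
        return alpha[:2].capitalize()
    if resname in _STANDARD_AA:
        return alpha[0]
    if alpha[:2] in ("CL", "BR"):
        return alpha[:2].capitalize()
    return alpha[0]


def read_structure(
    text_or_path: str | Path,
    *,
    dt_ns: float = 1.0,
    ligand_resnames: Iterable[str] | None = None,
    label: str = "",
) -> Trajectory:
    """Parse PDB content (text or a path) into a :class:`Trajectory`.

    Each MODEL becomes one frame (one frame if the file has no MODEL
    records); frame times are ``model_index * dt_ns``.  HETATM atoms are
    flagged ``is_ligand`` unless their residue is water/an ion; pass
    ``ligand_resnames`` to flag by residue name instead.  Only altloc 'A'
    or blank atoms are kept.
    """
    path = Path(str(text_or_path))
    try:
        is_file = path.is_file()
    except OSError:
        is_file = False
    text = path.read_text() if is_file else str(text_or_path)

    n_atom_records = _validate_pdb_lines(text)
    if n_atom_records == 0:
        raise EmptyInputError("no ATOM/HETATM records found")

    import MDAnalysis as mda
    from MDAnalysis.lib.util import NamedStream

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stream = NamedStream(io.StringIO(text), "input.pdb")
        u = mda.Universe(stream, format="PDB")

    ag = u.atoms
    if hasattr(ag, "altLocs"):
        keep = np.isin(ag.altLocs, ("", "A"))
        ag = ag[keep]

    names = ag.names
    resnames = ag.resnames
    resids = ag.resids
    serials = ag.ids if hasattr(ag, "ids") else np.arange(1, len(ag) + 1)
    chains = ag.chainIDs if hasattr(ag, "chainIDs") else ag.segids
    bfac = ag.tempfactors if hasattr(ag, "tempfactors") else None
    record = (
        ag.record_types
        if hasattr(ag, "record_types")
        else np.array(["ATOM"] * len(ag))
    )
    if hasattr(ag, "elements"):
        elements = [str(e).capitalize() for e in ag.elements]
    else:
        elements = [
            _element_from_name(nm, rn, rec == "HETATM")
            for nm, rn, rec in zip(names, resnames, record)
        ]

    ligand_set = (
        {r.upper() for r in ligand_resnames} if ligand_resnames is not None else None
    )

    topology: list[Atom] = []
    for i in range(len(ag)):
        resname = str(resnames[i]).upper()
        if ligand_set is not None:
            is_lig = resname in ligand_set
        else:
            is_lig = record[i] == "HETATM" and resname not in WATER_AND_IONS
        topology.append(
            Atom(
                serial=int(serials[i]),
                name=str(names[i]),
                element=elements[i],
                residue_name=resname,
                residue_seq=int(resids[i]),
                chain=str(chains[i]).strip() or "A",
                coords_index=i,
                b_factor=float(bfac[i]) if bfac is not None else None,
                is_ligand=bool(is_lig),
            )
        )

    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, _ts in enumerate(u.trajectory):
            frames.append(Frame(time_ns=k * dt_ns, coordinates=ag.positions.copy()))
    return Trajectory(topology=topology, frames=frames, label=label)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _as_universe(traj: Trajectory):
    """Build an MDAnalysis Universe mirroring a Trajectory (for writers)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    top = traj.topology
    n = len(top)
    reskeys: list[tuple[str, int, str]] = []
    atom_resindex = np.empty(n, dtype=int)
    for i, a in enumerate(top):
        key = (a.chain, a.residue_seq, a.residue_name)
        if not reskeys or reskeys[-1] != key:
            reskeys.append(key)
        atom_resindex[i] = len(reskeys) - 1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n,
            n_residues=len(reskeys),
            atom_resindex=atom_resindex,
            residue_segindex=np.zeros(len(reskeys), dtype=int),
            trajectory=False,
        )
        u.add_TopologyAttr("names", [a.name for a in top])
        u.add_TopologyAttr("elements", [a.element for a in top])
        u.add_TopologyAttr("ids", [a.serial for a in top])
        u.add_TopologyAttr("chainIDs", [a.chain for a in top])
        u.add_TopologyAttr(
            "tempfactors",
            [a.b_factor if a.b_factor is not None else 0.0 for a in top],
        )
        u.add_TopologyAttr("occupancies", [1.0] * n)
        u.add_TopologyAttr(
            "record_types", ["HETATM" if a.is_ligand else "ATOM" for a in top]
        )
        u.add_TopologyAttr("resnames", [k[2] for k in reskeys])
        u.add_TopologyAttr("resids", [k[1] for k in reskeys])
        u.add_TopologyAttr("segids", ["SYS"])
        coords = np.stack([fr.coordinates for fr in traj.frames]).astype(np.float32)
        u.load_new(coords, format=MemoryReader)
    return u


def write_structure(traj: Trajectory, path: str | Path | None = None) -> str:
    """Write a Trajectory as (multi-model) PDB text; optionally to ``path``."""
    import MDAnalysis as mda

    u = _as_universe(traj)
    with tempfile.TemporaryDirectory() as tmp:
        tmpfile = os.path.join(tmp, "out.pdb")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(
                tmpfile, n_atoms=traj.n_atoms, multiframe=traj.n_frames > 1
            ) as w:
                for _ts in u.trajectory:
                    w.write(u.atoms)
        text = Path(tmpfile).read_text()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Coordinate series
# ---------------------------------------------------------------------------

def read_coordinate_series(
    topology: Trajectory,
    source: str | Path | bytes,
    format: str | None = None,
    *,
    times_ns: Sequence[float] | None = None,
    dt_ns: float | None = None,
) -> Trajectory:
    """Attach frames from a coordinate series (DCD/XTC/...) to a topology.

    Frames are appended in file order.  Time stamps come from ``times_ns``
    if given, else ``dt_ns`` spacing, else the reader's own time stamps
    (converted from ps to ns).
    """
    import MDAnalysis as mda

    with tempfile.TemporaryDirectory() as tmp:
        if isinstance(source, bytes):
            ext = (format or "dcd").lower()
            src = os.path.join(tmp, f"series.{ext}")
            with open(src, "wb") as fh:
                fh.write(source)
        else:
            src = str(source)
        toppdb = os.path.join(tmp, "top.pdb")
        write_structure(
            Trajectory(topology.topology, [topology.frames[0]], topology.label),
            toppdb,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                u = mda.Universe(toppdb, src, format=format)
            except ValueError as exc:
                raise TopologyError(str(exc)) from exc
            if u.atoms.n_atoms != topology.n_atoms:
                raise TopologyError(
                    f"series has {u.atoms.n_atoms} atoms; topology has "
                    f"{topology.n_atoms}"
                )
            frames = []
            for k, ts in enumerate(u.trajectory):
                if times_ns is not None:
                    t = float(times_ns[k])
                elif dt_ns is not None:
                    t = k * dt_ns
                else:
                    t = float(ts.time) / 1000.0  # reader time is ps
                frames.append(Frame(time_ns=t, coordinates=u.atoms.positions.copy()))
    times = [fr.time_ns for fr in frames]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        # fall back to uniform spacing when the reader lacks real times
        for k, fr in enumerate(frames):
            fr.time_ns = k * (dt_ns if dt_ns is not None else 1.0)
    return Trajectory(topology=topology.topology, frames=frames, label=topology.label)


def write_coordinate_series(
    traj: Trajectory, path: str | Path, format: str | None = None
) -> None:
    """Write trajectory frames to a coordinate file (format from extension)."""
    import MDAnalysis as mda

    u = _as_universe(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(
            str(path), n_atoms=traj.n_atoms, multiframe=True, format=format
        ) as w:
            for _ts in u.trajectory:
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# B-factors
# ---------------------------------------------------------------------------

def bfactors_of(structure: Trajectory, serials: Iterable[int]) -> list[float]:
    """Crystallographic B-factors (Å²) for the given atom serials, in order.

    Low B-factors on the atoms of a halogen bond indicate a well-ordered,
    stable interaction in the crystal.
    """
    out = []
    for s in serials:
        atom = structure.atom_by_serial(int(s))
        out.append(atom.b_factor if atom.b_factor is not None else float("nan"))
    return out
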