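"""Halogen-bond donor/acceptor perception.

A halogen-bond donor is a ligand carbon–halogen pair where the halogen is
Cl, Br or I (fluorine is too weakly polarizable to develop a usable σ-hole
and is excluded).  Acceptors are Lewis-basic receptor atoms, classified as
``"c"`` (backbone carbonyl oxygen) or ``"s"`` (side-chain oxygen or
nitrogen), following the c/s acceptor-labelling convention for GPCR
binding-pocket contacts.

Covalent C–X bonds are inferred from interatomic distance (1.6–2.2 Å
window) rather than CONECT records, which are frequently absent or
unreliable in PDB files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import PerceptionError, SelectionError
from .io_structures import Atom, GenericNumberingMap, Trajectory

XB_HALOGENS = ("Cl", "Br", "I")

#: C–X covalent bond length window (Å) used to find the donor carbon.
BOND_WINDOW = (1.6, 2.2)

#: Side-chain O/N acceptor atom names per residue type.
SIDE_CHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "HSD": ("ND1", "NE2"),
    "HSE": ("ND1", "NE2"),
    "ASN": ("OD1", "ND2"),
    "GLN": ("OE1", "NE2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "TRP": ("NE1",),
}


@dataclass(frozen=True)
class XBDonor:
    """A ligand C–X halogen-bond donor (X ∈ {Cl, Br, I})."""

    carbon: Atom
    halogen: Atom
    halogen_element: str
    position_tag: str = ""

    def __post_init__(self) -> None:
        if self.halogen_element not in XB_HALOGENS:
            raise PerceptionError(
                f"{self.halogen_element} is not a halogen-bond donor element"
            )


@dataclass(frozen=True)
class XBAcceptor:
    """A receptor acceptor atom with its c/s class and residue label."""

    atom: Atom
    residue_label: str
    acceptor_class: str  # "c" (backbone carbonyl O) or "s" (side chain)

    def __post_init__(self) -> None:
        if self.acceptor_class not in ("c", "s"):
            raise PerceptionError(
                f"acceptor class must be 'c' or 's', got {self.acceptor_class!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.residue_label}({self.acceptor_class})"


@dataclass(frozen=True)
class XBContact:
    """A tracked donor–acceptor pair."""

    donor: XBDonor
    acceptor: XBAcceptor
    label: str = ""

    def __post_init__(self) -> None:
        if self.donor.halogen.serial == self.acceptor.atom.serial:
            raise PerceptionError("donor halogen and acceptor atom coincide")
        if not self.label:
            object.__setattr__(
                self,
                "label",
                f"{self.donor.position_tag or self.donor.halogen_element}"
                f" -> {self.acceptor.label}",
            )


def find_donors(
    structure: Trajectory,
    ligand_resnames: Iterable[str] | None = None,
    frame_index: int = 0,
) -> list[XBDonor]:
    """Find every ligand Cl/Br/I with its covalently bonded carbon.

    The donor carbon is the nearest ligand carbon within the 1.6–2.2 Å
    covalent window in the given frame.  Fluorine is skipped: it does not
    form halogen bonds.
    """
    coords = structure.frames[frame_index].coordinates
    if ligand_resnames is not None:
        names = {r.upper() for r in ligand_resnames}
        ligand = [a for a in structure.topology if a.residue_name in names]
    else:
        ligand = structure.ligand_atoms()
    if not ligand:
        raise PerceptionError("no ligand atoms found")

    halogens = [a for a in ligand if a.element in XB_HALOGENS]
    carbons = [a for a in ligand if a.element == "C"]
    donors: list[XBDonor] = []
    lo, hi = BOND_WINDOW
    for hal in halogens:
        if not carbons:
            raise PerceptionError(
                f"halogen {hal.name} (serial {hal.serial}) has no ligand carbons"
            )
        d = np.linalg.norm(
            coords[[c.coords_index for c in carbons]] - coords[hal.coords_index],
            axis=1,
        )
        i = int(np.argmin(d))
        if not (lo <= d[i] <= hi):
            raise PerceptionError(
                f"halogen {hal.name} (serial {hal.serial}): nearest carbon at "
                f"{d[i]:.2f} Å is outside the covalent window {lo}-{hi} Å"
            )
        donors.append(
            XBDonor(
                carbon=carbons[i],
                halogen=hal,
                halogen_element=hal.element,
                position_tag=hal.name,
            )
        )
    return donors


def _resolve_residue(
    structure: Trajectory,
    selector: str,
    numbering: GenericNumberingMap | None,
) -> tuple[str, int, str]:
    """Resolve ``chain:resseq`` or a generic label to (chain, seq, label)."""
    if ":" in selector:
        chain, seq = selector.split(":", 1)
        try:
            seq_i = int(seq)
        except ValueError:
            raise SelectionError(f"bad residue selector {selector!r}") from None
        label = numbering.label_of(chain, seq_i) if numbering else None
        return chain, seq_i, label or f"{chain}:{seq_i}"
    if numbering is None:
        raise SelectionError(
            f"generic label {selector!r} given but no numbering map supplied"
        )
    hit = numbering.residue_for_label(selector)
    if hit is None:
        raise SelectionError(f"generic label {selector!r} not in numbering map")
    return hit[0], hit[1], selector


def find_acceptors(
    structure: Trajectory,
    residues: Sequence[str] | None = None,
    numbering: GenericNumberingMap | None = None,
) -> list[XBAcceptor]:
    """Enumerate c/s acceptors on the selected receptor residues.

    ``residues`` holds selectors (``chain:resseq`` or generic labels such
    as ``5x40``); ``None`` selects every protein residue.  Each residue
    yields its backbone carbonyl O as class "c" plus any side-chain O/N
    acceptors as class "s" (for His both ring nitrogens are kept as
    candidates; downstream reporting picks the more occupied one).
    """
    receptor = structure.receptor_atoms()
    if not receptor:
        raise PerceptionError("no receptor atoms found")

    if residues is None:
        seen: list[tuple[str, int]] = []
        targets = []
        for a in receptor:
            key = (a.chain, a.residue_seq)
            if key not in seen:
                seen.append(key)
                label = numbering.label_of(*key) if numbering else None
                targets.append((key[0], key[1], label or f"{key[0]}:{key[1]}"))
    else:
        targets = [_resolve_residue(structure, sel, numbering) for sel in residues]

    by_res: dict[tuple[str, int], list[Atom]] = {}
    for a in receptor:
        by_res.setdefault((a.chain, a.residue_seq), []).append(a)

    acceptors: list[XBAcceptor] = []
    for chain, seq, label in targets:
        atoms = by_res.get((chain, seq))
        if not atoms:
            raise PerceptionError(f"residue {label} ({chain}:{seq}) not found")
        resname = atoms[0].residue_name
        prefix = resname[0] if resname else "?"
        display = label if ":" not in label else f"{resname}{seq}"
        if label and "x" in label and ":" not in label:
            display = f"{prefix}{label}"
        found_any = False
        for a in atoms:
            if a.name == "O":
                acceptors.append(XBAcceptor(a, display, "c"))
                found_any = True
        sc_names = SIDE_CHAIN_ACCEPTORS.get(resname, ())
        for a in atoms:
            if a.name in sc_names:
                acceptors.append(XBAcceptor(a, display, "s"))
                found_any = True
        if residues is not None and not found_any:
            raise PerceptionError(
                f"residue {display} ({chain}:{seq}) has no acceptor atoms"
            )
    return acceptors


def auto_contacts(
    traj: Trajectory,
    donors: Sequence[XBDonor],
    acceptors: Sequence[XBAcceptor],
    detect_cutoff: float = 5.5,
    min_fraction: float = 0.10,
) -> list[XBContact]:
    """Pair donors with acceptors that come close often enough to track.

    A contact is kept when the halogen–acceptor distance is within
    ``detect_cutoff`` (Å) in at least ``min_fraction`` of frames.  This
    automates the by-eye contact shortlist a modeller would make from a
    distance time series.
    """
    n = traj.n_frames
    contacts = []
    for don in donors:
        hx = np.stack([fr.coordinates[don.halogen.coords_index] for fr in traj.frames])
        for acc in acceptors:
            ax = np.stack(
                [fr.coordinates[acc.atom.coords_index] for fr in traj.frames]
            )
            frac = float(np.mean(np.linalg.norm(hx - ax, axis=1) <= detect_cutoff))
            if frac >= min_fraction and n > 0:
                contacts.append(XBContact(donor=don, acceptor=acc))
    return contacts
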