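"""XSAR matched-pair analysis: Xeffect and PI–AR chemotype classes.

An XSAR set groups a non-halogenated parent ligand with its aryl-halogenated
analogues (matched molecular pairs under halogen→H replacement).  The
Xeffect of a derivative is the fold-change of potency on halogenation::

    Xeffect = activity(parent) / activity(derivative)

on a lower-is-better activity scale (Ki/IC50 in nM), so Xeffect > 1 means
halogenation improved potency and values in (0, 1) mean it hurt.  Callers
working in pKi must convert to nM first; the module does not guess units.

D4-receptor ligand chemotypes split into two classes by the distance
between the two key pharmacophore features — the basic, positively
ionizable nitrogen (PI) and the centroid of the (candidate) halogenated
aromatic ring (AR): a long class near 5.6 Å (arylpiperazines) and a short
class near 3.9 Å (benzylpiperidines).  The PI–AR distance is computed as
the median over a seeded embedded conformer ensemble.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ActivityDomainError, PharmacophoreError

logger = logging.getLogger(__name__)

XB_HALOGEN_NUMS = {17: "Cl", 35: "Br", 53: "I"}  # F (9) excluded by default

#: Midpoint between the two printed class distances (5.6 and 3.9 Å).
CHEMOTYPE_THRESHOLD = 4.75


@dataclass(frozen=True)
class LigandRecord:
    """One ligand: identifier, SMILES and activity (nM, lower = more potent)."""

    id: str
    smiles: str
    activity_nm: float

    def __post_init__(self) -> None:
        if not self.activity_nm > 0:
            raise ActivityDomainError(
                f"ligand {self.id}: activity must be positive, got {self.activity_nm}"
            )


@dataclass
class XSARSet:
    """A parent ligand with its halogenated derivatives and Xeffects."""

    parent: LigandRecord
    derivatives: list[tuple[LigandRecord, str]] = field(default_factory=list)
    xeffects: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "parent": self.parent.id,
            "parent_smiles": self.parent.smiles,
            "derivatives": [
                {
                    "id": rec.id,
                    "smiles": rec.smiles,
                    "substitution": desc,
                    "xeffect": xe,
                }
                for (rec, desc), xe in zip(self.derivatives, self.xeffects)
            ],
        }


# ---------------------------------------------------------------------------
# Matched-pair discovery
# ---------------------------------------------------------------------------

def _mol_from_smiles(smiles: str):
    from rdkit import Chem

    return Chem.MolFromSmiles(smiles)


def _dehalogenate(mol, halogen_nums=tuple(XB_HALOGEN_NUMS), aryl_only: bool = True):
    """Replace the selected aryl-bound halogens with H.

    Returns (canonical SMILES of the stripped scaffold, per-element counts
    of removed halogens).
    """
    from rdkit import Chem

    rw = Chem.RWMol(mol)
    removed: dict[str, int] = {}
    to_delete = []
    for atom in rw.GetAtoms():
        z = atom.GetAtomicNum()
        if z not in halogen_nums:
            continue
        nbrs = atom.GetNeighbors()
        if len(nbrs) != 1:
            continue
        if aryl_only and not nbrs[0].GetIsAromatic():
            continue
        sym = Chem.Atom(z).GetSymbol()
        removed[sym] = removed.get(sym, 0) + 1
        to_delete.append(atom.GetIdx())
    for idx in sorted(to_delete, reverse=True):
        nbr = rw.GetAtomWithIdx(idx).GetNeighbors()[0]
        nbr.SetNumExplicitHs(nbr.GetNumExplicitHs() + 0)  # implicit H restored
        rw.RemoveAtom(idx)
    scaffold = rw.GetMol()
    Chem.SanitizeMol(scaffold)
    return Chem.MolToSmiles(scaffold), removed


def _substitution_descriptor(removed: dict[str, int]) -> str:
    return " + ".join(f"{el} x{n}" for el, n in sorted(removed.items()))


def find_xsar_sets(
    records: list[LigandRecord],
    halogens: tuple[str, ...] = ("Cl", "Br", "I"),
    aryl_only: bool = True,
) -> list[XSARSet]:
    """Group ligands into parent + aryl-halogenated-derivative sets.

    Each record is canonicalized; records carrying aryl-bound halogens from
    the chosen set are stripped back to their scaffold, and a set is formed
    for every parent whose canonical graph equals at least one derivative's
    stripped scaffold.  Multi-substituted derivatives are allowed.
    Unparseable SMILES are skipped with a logged warning.  The default
    halogen set {Cl, Br, I} excludes fluorine, which does not form halogen
    bonds.
    """
    from rdkit import Chem

    num_for = {"F": 9, "Cl": 17, "Br": 35, "I": 53}
    halogen_nums = tuple(num_for[h] for h in halogens)

    parsed = []
    for rec in records:
        mol = _mol_from_smiles(rec.smiles)
        if mol is None:
            logger.warning("skipping %s: unparseable SMILES %r", rec.id, rec.smiles)
            continue
        canonical = Chem.MolToSmiles(mol)
        scaffold, removed = _dehalogenate(mol, halogen_nums, aryl_only)
        parsed.append((rec, canonical, scaffold, removed))

    sets: list[XSARSet] = []
    for rec, canonical, _scaffold, removed in parsed:
        if removed:  # halogenated molecules cannot be parents
            continue
        xset = XSARSet(parent=rec)
        for other, _can, oscaffold, oremoved in parsed:
            if not oremoved or other.id == rec.id:
                continue
            if oscaffold == canonical:
                xset.derivatives.append((other, _substitution_descriptor(oremoved)))
                xset.xeffects.append(xeffect(rec, other))
        if xset.derivatives:
            sets.append(xset)
    return sets


def xeffect(parent: LigandRecord, derivative: LigandRecord) -> float:
    """Fold-change of potency on halogenation (parent / derivative activity)."""
    if not (parent.activity_nm > 0 and derivative.activity_nm > 0):
        raise ActivityDomainError("activities must be positive")
    return parent.activity_nm / derivative.activity_nm


# ---------------------------------------------------------------------------
# PI–AR pharmacophore distance
# ---------------------------------------------------------------------------

def _basic_nitrogen(mol) -> int:
    """Atom index of the PI feature: the most basic aliphatic amine N.

    Aromatic nitrogens, aryl-conjugated (aniline-type) nitrogens and amide
    nitrogens are excluded; ring amines are preferred over acyclic ones.
    """
    candidates = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 7 or atom.GetIsAromatic():
            continue
        nbrs = atom.GetNeighbors()
        if any(nb.GetIsAromatic() for nb in nbrs):
            continue  # aniline-type N: lone pair conjugated, not basic
        amide = False
        for nb in nbrs:
            if nb.GetAtomicNum() == 6:
                for bond in nb.GetBonds():
                    other = bond.GetOtherAtom(nb)
                    if other.GetAtomicNum() in (7, 8) and bond.GetBondTypeAsDouble() == 2.0:
                        amide = True
        if amide:
            continue
        candidates.append(atom)
    if not candidates:
        raise PharmacophoreError("no basic aliphatic amine nitrogen found")
    candidates.sort(key=lambda a: (not a.IsInRing(), -a.GetTotalNumHs(), a.GetIdx()))
    return candidates[0].GetIdx()


def _aromatic_ring(mol) -> tuple[int, ...]:
    """Atom indices of the AR feature ring.

    Prefers the aromatic ring bearing Cl/Br/I substituents (the halogenated
    or candidate-halogenation ring); ties and the unsubstituted case fall
    back to the first ring by atom order.
    """
    rings = [
        r
        for r in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)
    ]
    if not rings:
        raise PharmacophoreError("no aromatic ring found")

    def halogen_load(ring) -> int:
        count = 0
        for i in ring:
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                if nb.GetAtomicNum() in XB_HALOGEN_NUMS:
                    count += 1
        return count

    return max(rings, key=lambda r: (halogen_load(r), -min(r)))


def pi_ar_distance(smiles: str, n_conformers: int = 20, seed: int = 20) -> float:
    """Median PI–AR distance (Å) over a seeded conformer ensemble.

    Embeds ``n_conformers`` 3D conformers (ETKDG, fixed seed), force-field
    relaxes them (MMFF94), and reports the median distance from the basic
    nitrogen to the aromatic-ring centroid.  The ensemble median is robust
    to occasional poorly embedded conformers and is deterministic for a
    given seed.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = _mol_from_smiles(smiles)
    if mol is None:
        raise PharmacophoreError(f"unparseable SMILES {smiles!r}")
    pi = _basic_nitrogen(mol)
    ring = _aromatic_ring(mol)

    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=int(n_conformers), params=params)
    if len(conf_ids) == 0:
        raise PharmacophoreError(f"conformer embedding failed for {smiles!r}")
    try:
        AllChem.MMFFOptimizeMoleculeConfs(molh)
    except Exception:  # pragma: no cover - MMFF typing failures are rare
        logger.warning("MMFF optimization failed; using raw ETKDG geometry")

    dists = []
    for cid in conf_ids:
        pos = molh.GetConformer(cid).GetPositions()
        centroid = pos[list(ring)].mean(axis=0)
        dists.append(float(np.linalg.norm(pos[pi] - centroid)))
    return float(np.median(dists))


def classify_chemotype(distance: float, threshold: float = CHEMOTYPE_THRESHOLD) -> str:
    """Classify a PI–AR distance as the long or short chemotype class."""
    if not distance > 0:
        raise PharmacophoreError("PI-AR distance must be positive")
    return "long" if distance >= threshold else "short"


# ---------------------------------------------------------------------------
# Table I/O and reporting
# ---------------------------------------------------------------------------

def read_activity_table(source: str | Path) -> list[LigandRecord]:
    """Read a CSV with columns ``id,smiles,activity_nM``."""
    df = pd.read_csv(source)
    cols = {c.lower(): c for c in df.columns}
    try:
        id_c, smi_c, act_c = cols["id"], cols["smiles"], cols["activity_nm"]
    except KeyError as exc:
        raise ActivityDomainError(
            f"activity table must have columns id,smiles,activity_nM; got "
            f"{list(df.columns)}"
        ) from exc
    return [
        LigandRecord(str(r[id_c]), str(r[smi_c]), float(r[act_c]))
        for _, r in df.iterrows()
    ]


def xsar_report(
    sets: list[XSARSet], n_conformers: int = 20, seed: int = 20
) -> dict:
    """JSON-ready report: sets with Xeffects plus per-parent chemotype class."""
    out = []
    for xset in sets:
        entry = xset.to_dict()
        try:
            dist = pi_ar_distance(xset.parent.smiles, n_conformers, seed)
            entry["pi_ar_distance_A"] = dist
            entry["chemotype"] = classify_chemotype(dist)
        except PharmacophoreError as exc:
            entry["pi_ar_distance_A"] = None
            entry["chemotype"] = None
            entry["chemotype_note"] = str(exc)
        out.append(entry)
    return {"n_sets": len(out), "sets": out}


def write_xsar_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
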