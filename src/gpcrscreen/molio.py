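"""Molecular and tabular I/O plus the shared structural data model.

Receptors come in as PDB files (Biopython parser underneath), docked poses
as SDF records carrying a named docking-score property (RDKit underneath),
and ligand libraries as delimited tables of SMILES with optional
agonist/antagonist labels and predicted pKd values.

Coordinates are in angstroms throughout.  Residue numbering is the author
numbering from the PDB record, never a re-index, because binding-site
residues are referred to by author numbers (e.g. ASN253) everywhere
downstream.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from rdkit import Chem

logger = logging.getLogger(__name__)

RECEPTOR_STATES = ("active", "inactive", "intermediate")

#: elements treated as metals for the metal-coordination interaction bit
METAL_ELEMENTS = frozenset(
    {"ZN", "MG", "MN", "FE", "CA", "NA", "K", "CU", "NI", "CO", "CD", "HG"}
)

_POSITIVE_RESIDUES = {"ARG", "LYS", "HIS"}
_NEGATIVE_RESIDUES = {"ASP", "GLU"}

#: aromatic side-chain ring atom names per residue type
_AROMATIC_RING_ATOMS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [["CG", "CD1", "CD2", "NE1", "CE2"],
            ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class EmptyInputError(ValueError):
    """Raised when an input contains no usable records."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass
class Residue:
    """A receptor residue with idealized chemistry annotations.

    ``number`` is the author numbering from the PDB record.
    ``formal_charge_class`` classifies the side chain at pH 7.
    ``aromatic_ring_atoms`` lists the atom names of each aromatic ring
    (a residue may carry more than one ring, e.g. tryptophan).
    """

    chain: str
    number: int
    name: str
    atoms: list[Atom]
    formal_charge_class: str = "neutral"
    aromatic_ring_atoms: Optional[list[list[str]]] = None

    def __post_init__(self) -> None:
        if self.formal_charge_class not in ("positive", "negative", "neutral"):
            raise ValueError(
                f"bad formal_charge_class {self.formal_charge_class!r}")
        if self.aromatic_ring_atoms is not None:
            names = {a.name for a in self.atoms}
            for ring in self.aromatic_ring_atoms:
                if len(ring) < 5:
                    raise ValueError("aromatic ring needs >= 5 atoms")
                missing = set(ring) - names
                if missing:
                    raise ValueError(
                        f"ring atoms {sorted(missing)} absent from residue")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.name)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.name}{self.number} has no atom {name!r}")

    def coords(self, names: Optional[Iterable[str]] = None) -> np.ndarray:
        if names is None:
            return np.array([a.xyz for a in self.atoms], dtype=float)
        return np.array([self.atom(n).xyz for n in names], dtype=float)


@dataclass
class Receptor:
    id: str
    residues: list[Residue]
    state_label: str = "inactive"

    def __post_init__(self) -> None:
        if self.state_label not in RECEPTOR_STATES:
            raise ValueError(f"state_label must be one of {RECEPTOR_STATES}")
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue identifiers in receptor")


@dataclass
class Molecule:
    id: str
    smiles: str
    label: Optional[str] = None  # "agonist" or "antagonist"
    predicted_pKd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in ("agonist", "antagonist"):
            raise ValueError(f"bad label {self.label!r}")

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise FormatError(f"molecule {self.id}: invalid SMILES {self.smiles!r}")
        return mol


@dataclass
class PoseAtom:
    element: str
    xyz: tuple[float, float, float]
    formal_charge: int = 0
    aromatic: bool = False

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Pose:
    """One docked ligand conformation against one receptor.

    ``docking_score`` is the energy-like docking scalar; more negative is
    a better pose.
    """

    molecule_id: str
    receptor_id: str
    atoms: list[PoseAtom]
    docking_score: float

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("pose must contain at least one atom")
        if not math.isfinite(self.docking_score):
            raise ValueError("docking_score must be finite")

    def heavy_atoms(self) -> list[PoseAtom]:
        return [a for a in self.atoms if a.is_heavy]


def _classify_residue(name: str) -> str:
    if name in _POSITIVE_RESIDUES:
        return "positive"
    if name in _NEGATIVE_RESIDUES:
        return "negative"
    return "neutral"


def read_receptor(path: str | Path, receptor_id: Optional[str] = None,
                  state_label: str = "inactive") -> Receptor:
    """Parse a PDB file into a :class:`Receptor`.

    Only ATOM records of standard residues are kept: HETATM ligands,
    waters and ions never enter the residue list.  For alternate
    locations the highest-occupancy conformer wins; ties break by altloc
    letter order.  Residues are ordered by (chain, author number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure(receptor_id or path.stem, path)
        except Exception as exc:  # Biopython raises assorted types
            raise FormatError(f"{path}: unparseable PDB ({exc})") from exc

    residues: list[Residue] = []
    for model in structure:
        for chain in model:
            for res in chain:
                hetflag, number, _icode = res.id
                if hetflag.strip():  # HETATM: ligand, water, ion
                    continue
                atoms = []
                for at in res:
                    # keep best altloc; Biopython DisorderedAtom exposes the
                    # selected child, which is the highest-occupancy one
                    if at.is_disordered():
                        children = sorted(
                            at.disordered_get_list(),
                            key=lambda a: (-(a.get_occupancy() or 0.0),
                                           a.get_altloc()),
                        )
                        at = children[0]
                    atoms.append(Atom(at.get_name(),
                                      (at.element or "C").upper(),
                                      tuple(float(x) for x in at.get_coord())))
                name = res.get_resname().strip()
                present = {a.name for a in atoms}
                rings = None
                if name in _AROMATIC_RING_ATOMS:
                    rings = [r for r in _AROMATIC_RING_ATOMS[name]
                             if set(r) <= present]
                    rings = rings or None
                residues.append(Residue(
                    chain=chain.id, number=number, name=name, atoms=atoms,
                    formal_charge_class=_classify_residue(name),
                    aromatic_ring_atoms=rings))
        break  # first model only
    if not residues:
        raise FormatError(f"{path}: no ATOM records found")
    residues.sort(key=lambda r: (r.chain, r.number))
    return Receptor(id=receptor_id or path.stem, residues=residues,
                    state_label=state_label)


def pose_from_rdkit(mol: Chem.Mol, molecule_id: str, receptor_id: str,
                    docking_score: float, conf_id: int = 0) -> Pose:
    """Build a :class:`Pose` from an RDKit molecule with 3D coordinates."""
    conf = mol.GetConformer(conf_id)
    atoms = []
    for atom in mol.GetAtoms():
        p = conf.GetAtomPosition(atom.GetIdx())
        atoms.append(PoseAtom(element=atom.GetSymbol(),
                              xyz=(p.x, p.y, p.z),
                              formal_charge=atom.GetFormalCharge(),
                              aromatic=atom.GetIsAromatic()))
    return Pose(molecule_id=molecule_id, receptor_id=receptor_id,
                atoms=atoms, docking_score=docking_score)


def read_poses(path: str | Path, score_field: str,
               receptor_id: str = "receptor") -> list[Pose]:
    """Read docked poses from an SDF file.

    Each record must carry the named numeric score property; records
    missing it are skipped with a logged warning.  Zero usable records is
    an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    poses: list[Pose] = []
    skipped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            logger.warning("%s: record %d unreadable, skipped", path, i + 1)
            continue
        if not mol.HasProp(score_field):
            skipped += 1
            logger.warning("%s: record %d missing %r, skipped",
                           path, i + 1, score_field)
            continue
        raw = mol.GetProp(score_field)
        try:
            score = float(raw)
        except ValueError as exc:
            raise FormatError(
                f"{path}: record {i + 1} score field {score_field!r} "
                f"non-numeric ({raw!r})") from exc
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i + 1}"
        mol_id = mol_id or f"mol{i + 1}"
        poses.append(pose_from_rdkit(mol, mol_id, receptor_id, score))
    if skipped:
        logger.warning("%s: skipped %d of %d records", path, skipped,
                       len(poses) + skipped)
    if not poses:
        raise EmptyInputError(f"{path}: no records with a usable "
                              f"{score_field!r} property")
    return poses


def read_molecule_table(path: str | Path, sep: Optional[str] = None
                        ) -> list[Molecule]:
    """Read a delimited molecule table with columns id, smiles[, label, pKd].

    Rows with invalid SMILES are rejected and reported with their row
    numbers (header = row 0).  Duplicate ids are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python")
    cols = {c.lower(): c for c in df.columns}
    for required in ("id", "smiles"):
        if required not in cols:
            raise FormatError(f"{path}: missing column {required!r}")
    ids = df[cols["id"]].astype(str)
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"{path}: duplicate molecule ids {dup}")

    molecules: list[Molecule] = []
    bad_rows: list[int] = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=1):
        smiles = str(row[cols["smiles"]])
        if Chem.MolFromSmiles(smiles) is None:
            bad_rows.append(row_no)
            continue
        label = None
        if "label" in cols and not pd.isna(row[cols["label"]]):
            label = str(row[cols["label"]]).strip().lower()
        pkd = None
        if "pkd" in cols and not pd.isna(row[cols["pkd"]]):
            pkd = float(row[cols["pkd"]])
        molecules.append(Molecule(id=str(row[cols["id"]]), smiles=smiles,
                                  label=label, predicted_pKd=pkd))
    if bad_rows:
        logger.warning("%s: rejected rows with invalid SMILES: %s",
                       path, bad_rows)
    return molecules


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a results table; reals carry 12 significant digits so a
    write/read round-trip preserves them."""
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)
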