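"""Per-residue protein-ligand interaction fingerprints (PLIF).

Each binding-site residue contributes an 8-bit block describing how it
interacts with a docked ligand pose:

====  =============================================
bit   interaction
====  =============================================
b0    hydrophobic contact (apolar C/S pair)
b1    aromatic ring face-to-face stacking
b2    aromatic ring edge-to-face stacking
b3    residue acts as hydrogen-bond acceptor
b4    residue acts as hydrogen-bond donor
b5    salt bridge, protein side positively charged
b6    salt bridge, protein side negatively charged
b7    ionic coordination of a ligand metal ion
====  =============================================

Bits are binary presence flags, not counts.  A residue enters a pose's
fingerprint when any of its heavy atoms lies within the largest distance
cutoff plus 1 A of any ligand heavy atom; all other residues are
implicitly all-zero.

Geometric cutoffs follow common interaction-fingerprint practice and are
fully configurable through :class:`InteractionCriteria`.  Donor/acceptor
typing uses the element (plus explicit hydrogens when the pose carries
them) on the ligand side and a per-residue template table on the protein
side, so poses without hydrogens are still classifiable; the H-bond
angle criterion is applied only when explicit hydrogens exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .molio import METAL_ELEMENTS, Pose, PoseAtom, Receptor, Residue

logger = logging.getLogger(__name__)

BIT_NAMES = (
    "hydrophobic",
    "aromatic_face_face",
    "aromatic_edge_face",
    "hbond_acceptor",
    "hbond_donor",
    "saltbridge_positive",
    "saltbridge_negative",
    "metal",
)
N_BITS = len(BIT_NAMES)


@dataclass(frozen=True)
class InteractionCriteria:
    """Distance/angle cutoffs for every interaction class.

    Distances in angstroms, angles in degrees.  The H-bond angle floor is
    applied only when explicit hydrogens are present in the pose.
    """

    hydrophobic_max_dist: float = 4.0
    hbond_max_dist: float = 3.5
    hbond_min_angle: float = 120.0
    saltbridge_max_dist: float = 4.0
    ring_centroid_max_dist: float = 5.0
    face_face_max_normal_angle: float = 30.0
    edge_face_normal_angle_range: tuple[float, float] = (60.0, 90.0)
    metal_max_dist: float = 2.8

    def __post_init__(self) -> None:
        for name in ("hydrophobic_max_dist", "hbond_max_dist",
                     "saltbridge_max_dist", "ring_centroid_max_dist",
                     "metal_max_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.edge_face_normal_angle_range
        for ang in (self.face_face_max_normal_angle, lo, hi):
            if not 0.0 <= ang <= 90.0:
                raise ValueError("angle bounds must lie in [0, 90] degrees")

    @property
    def contact_shell(self) -> float:
        """Residue pre-selection radius: largest distance cutoff + 1 A."""
        return max(self.hydrophobic_max_dist, self.hbond_max_dist,
                   self.saltbridge_max_dist, self.ring_centroid_max_dist,
                   self.metal_max_dist) + 1.0


@dataclass
class ResidueBitBlock:
    residue_key: tuple[str, int, str]
    bits: np.ndarray  # 8 booleans

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.shape != (N_BITS,):
            raise ValueError("a residue block carries exactly 8 bits")


@dataclass
class PLIFVector:
    molecule_id: str
    receptor_id: str
    blocks: list[ResidueBitBlock]
    docking_score_feature: Optional[float] = None


# ---------------------------------------------------------------------------
# Residue chemistry templates (heavy-atom typing at pH 7)
# ---------------------------------------------------------------------------

# backbone: N donates, O accepts, C/CA/CB are apolar carbons
_BACKBONE_DONORS = ("N",)
_BACKBONE_ACCEPTORS = ("O",)
_BACKBONE_APOLAR = ("C", "CA")


@dataclass(frozen=True)
class ResidueChemistry:
    donors: tuple[str, ...] = ()
    acceptors: tuple[str, ...] = ()
    apolar: tuple[str, ...] = ()          # side-chain apolar C/S atoms
    positive_group: tuple[str, ...] = ()  # atoms of the cationic group
    negative_group: tuple[str, ...] = ()  # atoms of the anionic group


RESIDUE_CHEMISTRY: dict[str, ResidueChemistry] = {
    "ALA": ResidueChemistry(apolar=("CB",)),
    "GLY": ResidueChemistry(),
    "VAL": ResidueChemistry(apolar=("CB", "CG1", "CG2")),
    "LEU": ResidueChemistry(apolar=("CB", "CG", "CD1", "CD2")),
    "ILE": ResidueChemistry(apolar=("CB", "CG1", "CG2", "CD1")),
    "PRO": ResidueChemistry(apolar=("CB", "CG", "CD")),
    "MET": ResidueChemistry(apolar=("CB", "CG", "SD", "CE")),
    "PHE": ResidueChemistry(apolar=("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    "TRP": ResidueChemistry(donors=("NE1",),
                            apolar=("CB", "CG", "CD1", "CD2", "CE2", "CE3",
                                    "CZ2", "CZ3", "CH2")),
    "SER": ResidueChemistry(donors=("OG",), acceptors=("OG",)),
    "THR": ResidueChemistry(donors=("OG1",), acceptors=("OG1",), apolar=("CG2",)),
    "CYS": ResidueChemistry(donors=("SG",), apolar=("CB", "SG")),
    "TYR": ResidueChemistry(donors=("OH",), acceptors=("OH",),
                            apolar=("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    "ASN": ResidueChemistry(donors=("ND2",), acceptors=("OD1",), apolar=("CB",)),
    "GLN": ResidueChemistry(donors=("NE2",), acceptors=("OE1",), apolar=("CB", "CG")),
    "ASP": ResidueChemistry(acceptors=("OD1", "OD2"), apolar=("CB",),
                            negative_group=("CG", "OD1", "OD2")),
    "GLU": ResidueChemistry(acceptors=("OE1", "OE2"), apolar=("CB", "CG"),
                            negative_group=("CD", "OE1", "OE2")),
    "LYS": ResidueChemistry(donors=("NZ",), apolar=("CB", "CG", "CD"),
                            positive_group=("NZ",)),
    "ARG": ResidueChemistry(donors=("NE", "NH1", "NH2"), apolar=("CB", "CG"),
                            positive_group=("CZ", "NH1", "NH2", "NE")),
    "HIS": ResidueChemistry(donors=("ND1", "NE2"), acceptors=("ND1", "NE2"),
                            apolar=("CB",)),
}

#: residues whose side chain counts as hydrophobic for bit b0
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PRO", "MET", "PHE", "TRP", "CYS", "TYR"}
)


def _present(residue: Residue, names: Iterable[str]) -> list[np.ndarray]:
    have = {a.name: a.coords for a in residue.atoms}
    return [have[n] for n in names if n in have]


# ---------------------------------------------------------------------------
# Ligand atom typing
# ---------------------------------------------------------------------------

def _ligand_typing(pose: Pose) -> dict[str, list[np.ndarray]]:
    """Classify ligand heavy atoms into interaction roles.

    When the pose carries explicit hydrogens, an N/O atom is a donor only
    if an H sits within covalent range (1.3 A); without hydrogens every
    neutral or positive N/O is a potential donor.  Acceptors are neutral
    or negative N/O.  Apolar atoms are uncharged C/S.
    """
    heavy = pose.heavy_atoms()
    hydrogens = [a.coords for a in pose.atoms if not a.is_heavy]
    has_h = len(hydrogens) > 0
    out: dict[str, list] = {"apolar": [], "donor": [], "acceptor": [],
                            "positive": [], "negative": [], "metal": [],
                            "heavy": [a.coords for a in heavy],
                            "donor_h": []}
    for a in heavy:
        el = a.element.upper()
        if el in METAL_ELEMENTS and el not in ("C", "N", "O", "S"):
            out["metal"].append(a.coords)
            continue
        if el in ("C", "S") and a.formal_charge == 0:
            out["apolar"].append(a.coords)
        if el in ("N", "O"):
            if a.formal_charge <= 0:
                out["acceptor"].append(a.coords)
            if has_h:
                bonded_h = [h for h in hydrogens
                            if np.linalg.norm(h - a.coords) <= 1.3]
                if bonded_h:
                    out["donor"].append(a.coords)
                    out["donor_h"].append((a.coords, bonded_h))
            elif a.formal_charge >= 0:
                out["donor"].append(a.coords)
        if a.formal_charge > 0:
            out["positive"].append(a.coords)
        elif a.formal_charge < 0:
            out["negative"].append(a.coords)
    return out


def _ligand_rings(pose: Pose) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group aromatic ligand atoms into rings by covalent proximity.

    Returns (centroid, unit normal) per ring of >= 5 atoms.  Connectivity
    is inferred from inter-atom distance (< 1.75 A) since poses carry no
    bond table.
    """
    arom = [a.coords for a in pose.heavy_atoms() if a.aromatic]
    if len(arom) < 5:
        return []
    pts = np.array(arom)
    n = len(pts)
    adj = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1) < 1.75
    seen = np.zeros(n, dtype=bool)
    rings = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.nonzero(adj[i])[0]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        if len(comp) >= 5:
            rings.append(_ring_plane(pts[comp]))
    return rings


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2] / np.linalg.norm(vt[2])


def _interplane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    cosang = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def _min_dist(a: Sequence[np.ndarray], b: Sequence[np.ndarray]) -> float:
    if not a or not b:
        return np.inf
    aa = np.asarray(a, dtype=float).reshape(len(a), 3)
    bb = np.asarray(b, dtype=float).reshape(len(b), 3)
    return float(np.min(np.linalg.norm(aa[:, None] - bb[None, :], axis=-1)))


def _hbond_angle_ok(donor: np.ndarray, h_list: list[np.ndarray],
                    acceptor: np.ndarray, min_angle: float) -> bool:
    """D-H...A angle criterion over the donor's bonded hydrogens."""
    for h in h_list:
        v1 = donor - h
        v2 = acceptor - h
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            continue
        ang = np.degrees(np.arccos(np.clip(np.dot(v1, v2) / (n1 * n2), -1, 1)))
        if ang >= min_angle:
            return True
    return False


def detect_interactions(pose: Pose, receptor: Receptor,
                        criteria: InteractionCriteria | None = None
                        ) -> list[ResidueBitBlock]:
    """Compute one 8-bit interaction block per contacting receptor residue.

    A bit is set iff its geometric predicate holds for at least one
    atom/group pair.  Residues with no heavy atom inside the contact
    shell are omitted (implicitly all-zero).
    """
    criteria = criteria or InteractionCriteria()
    lig = _ligand_typing(pose)
    if not lig["heavy"]:
        raise ValueError("pose has no heavy atoms")
    lig_rings = _ligand_rings(pose)
    shell = criteria.contact_shell

    blocks: list[ResidueBitBlock] = []
    for res in receptor.residues:
        res_heavy = [a.coords for a in res.atoms if a.element != "H"]
        if _min_dist(res_heavy, lig["heavy"]) > shell:
            continue
        bits = np.zeros(N_BITS, dtype=bool)
        chem = RESIDUE_CHEMISTRY.get(res.name, ResidueChemistry())

        # b0 hydrophobic: apolar C/S pair within cutoff, hydrophobic residue
        if res.name in HYDROPHOBIC_RESIDUES:
            res_apolar = _present(res, chem.apolar + _BACKBONE_APOLAR)
            if _min_dist(res_apolar, lig["apolar"]) <= criteria.hydrophobic_max_dist:
                bits[0] = True

        # b1/b2 aromatic stacking (mutually exclusive per ring pair)
        if res.aromatic_ring_atoms:
            for ring_names in res.aromatic_ring_atoms:
                pts = _present(res, ring_names)
                if len(pts) != len(ring_names):
                    continue
                c_res, n_res = _ring_plane(np.array(pts))
                for c_lig, n_lig in lig_rings:
                    if np.linalg.norm(c_res - c_lig) > criteria.ring_centroid_max_dist:
                        continue
                    ang = _interplane_angle(n_res, n_lig)
                    if ang <= criteria.face_face_max_normal_angle:
                        bits[1] = True
                    elif (criteria.edge_face_normal_angle_range[0] <= ang
                          <= criteria.edge_face_normal_angle_range[1]):
                        bits[2] = True

        # b3 residue acceptor vs ligand donor; b4 residue donor vs acceptor
        res_acc = _present(res, chem.acceptors + _BACKBONE_ACCEPTORS)
        res_don = _present(res, chem.donors + _BACKBONE_DONORS)
        if lig["donor_h"]:
            for acc in res_acc:
                for donor, h_list in lig["donor_h"]:
                    if (np.linalg.norm(acc - donor) <= criteria.hbond_max_dist
                            and _hbond_angle_ok(donor, h_list, acc,
                                                criteria.hbond_min_angle)):
                        bits[3] = True
        elif _min_dist(res_acc, lig["donor"]) <= criteria.hbond_max_dist:
            bits[3] = True
        if _min_dist(res_don, lig["acceptor"]) <= criteria.hbond_max_dist:
            bits[4] = True

        # b5/b6 salt bridges between charged-group centers
        if chem.positive_group:
            pts = _present(res, chem.positive_group)
            if pts:
                center = np.mean(pts, axis=0)
                if _min_dist([center], lig["negative"]) <= criteria.saltbridge_max_dist:
                    bits[5] = True
        if chem.negative_group:
            pts = _present(res, chem.negative_group)
            if pts:
                center = np.mean(pts, axis=0)
                if _min_dist([center], lig["positive"]) <= criteria.saltbridge_max_dist:
                    bits[6] = True

        # b7 coordination of a ligand metal by residue N/O
        res_no = [a.coords for a in res.atoms if a.element in ("N", "O")]
        if _min_dist(res_no, lig["metal"]) <= criteria.metal_max_dist:
            bits[7] = True

        blocks.append(ResidueBitBlock(residue_key=res.key, bits=bits))
    return blocks


# ---------------------------------------------------------------------------
# Feature-matrix assembly
# ---------------------------------------------------------------------------

def residue_order_from_plifs(plifs: Sequence[PLIFVector]
                             ) -> list[tuple[str, int, str]]:
    """Deterministic column order: every residue contacted by any pose,
    sorted by (chain, number, name)."""
    keys = {b.residue_key for v in plifs for b in v.blocks}
    return sorted(keys)


def column_names(residue_order: Sequence[tuple[str, int, str]],
                 include_score: bool = False) -> list[str]:
    names = [f"{chain}:{name}{number}:{bit}"
             for chain, number, name in residue_order
             for bit in BIT_NAMES]
    if include_score:
        names.append("docking_score")
    return names


def build_feature_matrix(plifs: Sequence[PLIFVector],
                         residue_order: Sequence[tuple[str, int, str]],
                         include_score: bool = False) -> pd.DataFrame:
    """Assemble the pose x feature matrix (rows = poses, 8 columns per
    residue, optional trailing docking-score column).

    Residues absent from a vector contribute zero bits; vector residues
    not in ``residue_order`` are dropped with a logged count.
    """
    if not plifs:
        raise ValueError("empty PLIF list")
    index = {key: i for i, key in enumerate(residue_order)}
    n_cols = N_BITS * len(residue_order) + (1 if include_score else 0)
    rows = np.zeros((len(plifs), n_cols), dtype=float)
    dropped = 0
    for r, vec in enumerate(plifs):
        for block in vec.blocks:
            i = index.get(block.residue_key)
            if i is None:
                dropped += 1
                continue
            rows[r, N_BITS * i:N_BITS * (i + 1)] = block.bits
        if include_score:
            if vec.docking_score_feature is None:
                raise ValueError(
                    f"pose of {vec.molecule_id} lacks a docking-score feature")
            rows[r, -1] = vec.docking_score_feature
    if dropped:
        logger.warning("dropped %d residue blocks outside the residue order",
                       dropped)
    return pd.DataFrame(rows, columns=column_names(residue_order, include_score))


def summarize_bit_frequencies(matrix: pd.DataFrame,
                              labels: Sequence[str]) -> pd.DataFrame:
    """Per-class fraction of poses with each interaction bit set.

    This is the PLIF frequency histogram view: one row per class, one
    column per residue bit.  The docking-score column, if present, is
    excluded.
    """
    labels = np.asarray(labels)
    if len(labels) != len(matrix):
        raise ValueError("labels length must match matrix rows")
    bit_cols = [c for c in matrix.columns if c != "docking_score"]
    out = {}
    for cls in pd.unique(labels):
        mask = labels == cls
        if not mask.any():
            raise ValueError(f"class {cls!r} has zero rows")
        out[cls] = (matrix.loc[mask, bit_cols] != 0).mean(axis=0)
    return pd.DataFrame(out).T
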