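"""Synthetic fixtures for every pipeline stage.

Three generators, all pure functions of (spec, seed):

* pocket/pose fixtures — idealized residue side chains plus ligand probe
  atoms placed to realize (or miss) a chosen interaction geometry, with a
  self-validating manifest of the bits that must be set;
* two-class ligand libraries — pose-level interaction-bit matrices and
  molecule-level circular-fingerprint-style bit matrices whose classes
  differ in designated signature bits and in docking-score
  distributions (agonists score better against the active-state
  receptor, antagonists against the inactive state, mirroring how real
  agonist/antagonist libraries separate);
* planted fingerprint blobs — archetype bit vectors with bounded
  pairwise similarity whose members are noisy copies, for clustering
  recovery tests.

The library generator's defaults are the study conditions used across
the test-suite: 50 molecules per class, 5 poses per molecule against
each of 3 receptor states, 30 % signature-bit overlap between classes,
and score distributions weak enough (~0.75 accuracy alone) that a
classifier must also exploit the interaction bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chemfp import BitFingerprint, tanimoto
from .molio import Atom, Pose, PoseAtom, Receptor, Residue
from .plif import (BIT_NAMES, N_BITS, InteractionCriteria, RESIDUE_CHEMISTRY,
                   HYDROPHOBIC_RESIDUES, _BACKBONE_ACCEPTORS,
                   _BACKBONE_APOLAR, _BACKBONE_DONORS)

# ---------------------------------------------------------------------------
# Idealized residue templates (local coordinates, side chain along -y)
# ---------------------------------------------------------------------------

_BACKBONE = [("N", "N", (-1.2, 0.9, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
             ("C", "C", (1.3, 0.6, 0.0)), ("O", "O", (1.5, 1.8, 0.0))]

RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "ALA": _BACKBONE + [("CB", "C", (0.0, -1.5, 0.0))],
    "SER": _BACKBONE + [("CB", "C", (0.0, -1.5, 0.0)),
                        ("OG", "O", (0.0, -2.9, 0.0))],
    "ASN": _BACKBONE + [("CB", "C", (0.0, -1.5, 0.0)),
                        ("CG", "C", (0.0, -2.9, 0.0)),
                        ("OD1", "O", (1.1, -3.5, 0.0)),
                        ("ND2", "N", (-1.1, -3.6, 0.0))],
    "ASP": _BACKBONE + [("CB", "C", (0.0, -1.5, 0.0)),
                        ("CG", "C", (0.0, -2.9, 0.0)),
                        ("OD1", "O", (1.1, -3.5, 0.0)),
                        ("OD2", "O", (-1.1, -3.5, 0.0))],
    "ARG": _BACKBONE + [("CB", "C", (0.0, -1.5, 0.0)),
                        ("CG", "C", (0.0, -2.9, 0.0)),
                        ("CD", "C", (0.0, -4.4, 0.0)),
                        ("NE", "N", (0.0, -5.8, 0.0)),
                        ("CZ", "C", (0.0, -7.1, 0.0)),
                        ("NH1", "N", (1.1, -7.8, 0.0)),
                        ("NH2", "N", (-1.1, -7.8, 0.0))],
    "PHE": _BACKBONE + [("CB", "C", (0.0, -1.5, 0.0)),
                        ("CG", "C", (0.0, -2.9, 0.0)),
                        ("CD1", "C", (1.2, -3.6, 0.0)),
                        ("CD2", "C", (-1.2, -3.6, 0.0)),
                        ("CE1", "C", (1.2, -5.0, 0.0)),
                        ("CE2", "C", (-1.2, -5.0, 0.0)),
                        ("CZ", "C", (0.0, -5.7, 0.0))],
}

_RING_ATOMS = {"PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]}
_CHARGE_CLASS = {"ARG": "positive", "ASP": "negative"}

#: safe target distances per interaction kind; chosen away from every
#: cutoff boundary so fixture manifests are unambiguous
SAFE_DISTANCES = {
    "hydrophobic": {"in": (3.0, 3.4, 3.7), "out": (4.5, 5.5)},
    "hbond_acceptor": {"in": (2.7, 2.9, 3.2), "out": (4.2, 5.0)},
    "hbond_donor": {"in": (2.7, 2.9, 3.2), "out": (4.2, 5.0)},
    "saltbridge_positive": {"in": (2.6, 3.0, 3.3), "out": (4.6, 5.5)},
    "saltbridge_negative": {"in": (2.6, 3.0, 3.3), "out": (4.6, 5.5)},
    "metal": {"in": (2.0, 2.3, 2.6), "out": (3.4, 4.2)},
    "aromatic_face_face": {"in": (3.6, 4.0), "out": (6.0, 7.0)},
    "aromatic_edge_face": {"in": (4.4, 4.8), "out": (6.0, 7.0)},
}

_BIT_TEMPLATE = {
    "hydrophobic": "ALA",
    "aromatic_face_face": "PHE",
    "aromatic_edge_face": "PHE",
    "hbond_acceptor": "ASN",
    "hbond_donor": "ASN",
    "saltbridge_positive": "ARG",
    "saltbridge_negative": "ASP",
    "metal": "ASP",
}


@dataclass(frozen=True)
class InteractionSpec:
    """One requested interaction geometry in a pocket fixture."""

    residue_template: str
    bit: str                      # a BIT_NAMES entry
    distance: float               # target distance in angstroms
    angle: float = 0.0            # ring tilt for aromatic bits, degrees
    expect_set: bool = True       # False for negative (out-of-range) fixtures

    def __post_init__(self) -> None:
        if self.bit not in BIT_NAMES:
            raise ValueError(f"unknown bit {self.bit!r}")
        if self.residue_template not in RESIDUE_TEMPLATES:
            raise ValueError(f"no template for {self.residue_template!r}")


@dataclass
class PocketFixture:
    receptor: Receptor
    pose: Pose
    #: expected 8-bit vector per residue key; absent residues are all-zero
    manifest: dict[tuple[str, int, str], np.ndarray]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _make_residue(template: str, index: int, offset: np.ndarray) -> Residue:
    atoms = [Atom(name, el, tuple(np.asarray(xyz) + offset))
             for name, el, xyz in RESIDUE_TEMPLATES[template]]
    rings = [_RING_ATOMS[template]] if template in _RING_ATOMS else None
    return Residue(chain="A", number=10 + index, name=template, atoms=atoms,
                   formal_charge_class=_CHARGE_CLASS.get(template, "neutral"),
                   aromatic_ring_atoms=rings)


def _ring_coords(center: np.ndarray, normal: np.ndarray, radius: float = 1.39,
                 n: int = 6) -> np.ndarray:
    normal = _unit(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(normal, ref))
    v = np.cross(normal, u)
    ang = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return center + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


def _probe_atoms(spec: InteractionSpec, residue: Residue
                 ) -> tuple[list[PoseAtom], dict[str, list[np.ndarray]]]:
    """Construct ligand probe atoms realizing the spec geometry.

    Returns the atoms plus their interaction roles (used to derive the
    manifest by construction).
    """
    d = spec.distance
    roles: dict[str, list[np.ndarray]] = {
        "apolar": [], "donor": [], "acceptor": [], "positive": [],
        "negative": [], "metal": [], "ring": []}
    atoms: list[PoseAtom] = []

    def add(element: str, xyz: np.ndarray, charge: int = 0,
            aromatic: bool = False, *role_names: str) -> None:
        atoms.append(PoseAtom(element=element, xyz=tuple(xyz),
                              formal_charge=charge, aromatic=aromatic))
        for rn in role_names:
            roles[rn].append(np.asarray(xyz, dtype=float))

    if spec.bit == "hydrophobic":
        tip = residue.atom("CB").coords
        add("C", tip + d * np.array([0.0, -1.0, 0.0]), 0, False, "apolar")
    elif spec.bit == "hbond_acceptor":
        acc = residue.atom("OD1").coords
        direction = _unit(acc - residue.atom("CG").coords)
        add("O", acc + d * direction, 0, False, "donor", "acceptor")
    elif spec.bit == "hbond_donor":
        don = residue.atom("ND2").coords
        direction = _unit(don - residue.atom("CG").coords)
        add("O", don + d * direction, 0, False, "donor", "acceptor")
    elif spec.bit == "saltbridge_positive":
        names = RESIDUE_CHEMISTRY[residue.name].positive_group
        center = residue.coords(names).mean(axis=0)
        pos = center + d * np.array([0.0, -1.0, 0.0])
        add("O", pos, -1, False, "negative", "acceptor")
    elif spec.bit == "saltbridge_negative":
        names = RESIDUE_CHEMISTRY[residue.name].negative_group
        center = residue.coords(names).mean(axis=0)
        pos = center + d * np.array([0.0, -1.0, 0.0])
        add("N", pos, +1, False, "positive", "donor")
    elif spec.bit == "metal":
        acc = residue.atom("OD1").coords
        direction = _unit(acc - residue.atom("CG").coords)
        add("ZN", acc + d * direction, 2, False, "metal")
    else:  # aromatic face-face / edge-face
        ring_names = _RING_ATOMS[residue.name]
        pts = residue.coords(ring_names)
        centroid = pts.mean(axis=0)
        tilt = math.radians(spec.angle)
        normal = np.array([math.sin(tilt), 0.0, math.cos(tilt)])
        center = centroid + d * np.array([0.0, 0.0, 1.0])
        ring = _ring_coords(center, normal)
        for xyz in ring:
            add("C", xyz, 0, True, "apolar")
        roles["ring"].append((center, normal))
    return atoms, roles


def _expected_bits(spec: InteractionSpec, residue: Residue,
                   roles: dict[str, list[np.ndarray]],
                   criteria: InteractionCriteria) -> np.ndarray:
    """Manifest bits by construction: direct geometry checks on the
    constructed coordinates, ambiguity-guarded near every cutoff."""
    bits = np.zeros(N_BITS, dtype=bool)
    chem = RESIDUE_CHEMISTRY[residue.name]
    guard = 0.1

    def min_dist(res_names: tuple[str, ...], pts: list[np.ndarray]) -> float:
        have = {a.name: a.coords for a in residue.atoms}
        coords = [have[n] for n in res_names if n in have]
        if not coords or not pts:
            return math.inf
        return min(float(np.linalg.norm(c - p)) for c in coords for p in pts)

    def check(dist: float, cutoff: float, what: str) -> bool:
        if abs(dist - cutoff) < guard:
            raise ValueError(
                f"ambiguous fixture: {what} distance {dist:.2f} within "
                f"{guard} of cutoff {cutoff}")
        return dist <= cutoff

    if residue.name in HYDROPHOBIC_RESIDUES:
        dist = min_dist(chem.apolar + _BACKBONE_APOLAR, roles["apolar"])
        if dist < math.inf:
            bits[0] = check(dist, criteria.hydrophobic_max_dist, "hydrophobic")
    if residue.aromatic_ring_atoms and roles["ring"]:
        pts = residue.coords(residue.aromatic_ring_atoms[0])
        centroid = pts.mean(axis=0)
        res_normal = np.array([0.0, 0.0, 1.0])  # templates are planar in z=0
        for center, normal in roles["ring"]:
            cd = float(np.linalg.norm(center - centroid))
            if not check(cd, criteria.ring_centroid_max_dist, "ring centroid"):
                continue
            ang = math.degrees(math.acos(min(1.0, abs(float(
                np.dot(_unit(normal), res_normal))))))
            lo, hi = criteria.edge_face_normal_angle_range
            for bound in (criteria.face_face_max_normal_angle, lo):
                if abs(ang - bound) < 2.0:
                    raise ValueError(f"ambiguous ring angle {ang:.1f}")
            if ang <= criteria.face_face_max_normal_angle:
                bits[1] = True
            elif lo <= ang <= hi:
                bits[2] = True
    dist = min_dist(chem.acceptors + _BACKBONE_ACCEPTORS, roles["donor"])
    if dist < math.inf:
        bits[3] = check(dist, criteria.hbond_max_dist, "hbond acceptor")
    dist = min_dist(chem.donors + _BACKBONE_DONORS, roles["acceptor"])
    if dist < math.inf:
        bits[4] = check(dist, criteria.hbond_max_dist, "hbond donor")
    if chem.positive_group and roles["negative"]:
        center = residue.coords(chem.positive_group).mean(axis=0)
        dist = min(float(np.linalg.norm(center - p)) for p in roles["negative"])
        bits[5] = check(dist, criteria.saltbridge_max_dist, "salt bridge +")
    if chem.negative_group and roles["positive"]:
        center = residue.coords(chem.negative_group).mean(axis=0)
        dist = min(float(np.linalg.norm(center - p)) for p in roles["positive"])
        bits[6] = check(dist, criteria.saltbridge_max_dist, "salt bridge -")
    if roles["metal"]:
        no_names = tuple(a.name for a in residue.atoms if a.element in ("N", "O"))
        dist = min_dist(no_names, roles["metal"])
        if dist < math.inf:
            bits[7] = check(dist, criteria.metal_max_dist, "metal")
    return bits


def make_pocket_fixture(specs: Sequence[InteractionSpec],
                        criteria: InteractionCriteria | None = None,
                        receptor_id: str = "synthetic_pocket",
                        state_label: str = "inactive") -> PocketFixture:
    """Build a (Receptor, Pose) pair realizing each requested interaction.

    Residues are spaced 30 A apart so entries cannot cross-talk; the
    manifest gives the full expected 8-bit vector per residue and the
    generator raises on any geometry ambiguously close to a cutoff.
    """
    if not specs:
        raise ValueError("need at least one interaction spec")
    criteria = criteria or InteractionCriteria()
    residues, all_atoms = [], []
    manifest: dict[tuple[str, int, str], np.ndarray] = {}
    for i, spec in enumerate(specs):
        offset = np.array([30.0 * i, 0.0, 0.0])
        residue = _make_residue(spec.residue_template, i, offset)
        atoms, roles = _probe_atoms(spec, residue)
        bits = _expected_bits(spec, residue, roles, criteria)
        target = BIT_NAMES.index(spec.bit)
        if bool(bits[target]) != spec.expect_set:
            raise ValueError(
                f"spec {i}: constructed geometry gives bit {spec.bit}="
                f"{bool(bits[target])}, expected {spec.expect_set}")
        residues.append(residue)
        all_atoms.extend(atoms)
        manifest[residue.key] = bits
    receptor = Receptor(id=receptor_id, residues=residues,
                        state_label=state_label)
    pose = Pose(molecule_id="probe", receptor_id=receptor_id,
                atoms=all_atoms, docking_score=0.0)
    return PocketFixture(receptor=receptor, pose=pose, manifest=manifest)


def random_interaction_spec(rng: np.random.Generator) -> InteractionSpec:
    """Sample one interaction spec from the safe-distance sets."""
    bit = str(rng.choice(BIT_NAMES))
    expect = bool(rng.random() < 0.7)
    dists = SAFE_DISTANCES[bit]["in" if expect else "out"]
    d = float(rng.choice(dists))
    angle = 0.0
    if bit == "aromatic_face_face":
        angle = float(rng.uniform(0.0, 20.0))
    elif bit == "aromatic_edge_face":
        angle = float(rng.uniform(65.0, 88.0))
    return InteractionSpec(residue_template=_BIT_TEMPLATE[bit], bit=bit,
                           distance=d, angle=angle, expect_set=expect)


# ---------------------------------------------------------------------------
# Two-class labeled libraries
# ---------------------------------------------------------------------------

RECEPTOR_STATE_NAMES = ("active", "inactive", "intermediate")

#: docking-score distributions (mean, sd) per (class, receptor state);
#: agonists score better (more negative) against the active state,
#: antagonists against the inactive state — separations weak enough that
#: the score alone is a mediocre classifier (~0.7 pose-level accuracy),
#: forcing the forest to also exploit the interaction bits
DEFAULT_SCORE_DISTRIBUTIONS: dict[tuple[str, str], tuple[float, float]] = {
    ("agonist", "active"): (-9.0, 0.6),
    ("agonist", "inactive"): (-7.0, 0.6),
    ("agonist", "intermediate"): (-7.4, 0.6),
    ("antagonist", "active"): (-8.4, 0.6),
    ("antagonist", "inactive"): (-9.4, 0.6),
    ("antagonist", "intermediate"): (-9.0, 0.6),
}


@dataclass(frozen=True)
class LibrarySpec:
    """Study conditions for the synthetic two-class ligand library."""

    n_per_class: int = 50
    poses_per_molecule: int = 5
    n_states: int = 3
    overlap: float = 0.3            # fraction of signature bits shared
    n_residues: int = 20            # interaction-bit columns = 8 * this
    n_signature: int = 12           # class-signature interaction bits
    signature_on_prob: float = 0.9
    background_on_prob: float = 0.05
    pose_flip_prob: float = 0.05
    ecfp_bits: int = 512
    ecfp_signature: int = 24
    score_distributions: tuple = tuple(sorted(
        DEFAULT_SCORE_DISTRIBUTIONS.items()))
    pkd_mean: float = 6.5
    pkd_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("need >= 2 molecules per class")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")


@dataclass
class SyntheticLibrary:
    """A generated two-class library with pose-level and molecule-level views."""

    molecule_ids: list[str]
    molecule_labels: np.ndarray        # 1 = agonist, 0 = antagonist
    pkd: np.ndarray                    # predicted affinity per molecule
    ecfp: np.ndarray                   # (n_molecules, ecfp_bits) bool
    X: np.ndarray                      # (n_samples, 8*n_residues + 1) pose rows
    sample_groups: np.ndarray          # molecule id per pose row
    sample_labels: np.ndarray
    sample_states: np.ndarray
    sample_scores: np.ndarray
    feature_names: list[str]
    agonist_signature_bits: np.ndarray
    antagonist_signature_bits: np.ndarray

    @property
    def best_scores(self) -> np.ndarray:
        """Most negative docking score per molecule, over all its poses."""
        return np.array([
            self.sample_scores[self.sample_groups == m].min()
            for m in self.molecule_ids])

    def best_scores_for_state(self, state: str) -> np.ndarray:
        """Best score per molecule restricted to one receptor state.

        An antagonist screen ranks by the inactive-state score, so the
        top-fraction stage should use this view rather than the overall
        best (which agonists dominate via the active state).
        """
        mask = self.sample_states == state
        if not mask.any():
            raise ValueError(f"no poses for state {state!r}")
        return np.array([
            self.sample_scores[(self.sample_groups == m) & mask].min()
            for m in self.molecule_ids])


def _signature_bits(rng: np.random.Generator, n_bits: int, n_signature: int,
                    overlap: float) -> tuple[np.ndarray, np.ndarray]:
    n_shared = int(round(overlap * n_signature))
    n_excl = n_signature - n_shared
    perm = rng.permutation(n_bits)
    shared = perm[:n_shared]
    ag = np.concatenate([shared, perm[n_shared:n_shared + n_excl]])
    an = np.concatenate([shared, perm[n_shared + n_excl:n_shared + 2 * n_excl]])
    return np.sort(ag), np.sort(an)


def make_labeled_library(spec: LibrarySpec | None = None) -> SyntheticLibrary:
    """Generate the two-class library (see module docstring).

    Every pose of a molecule carries the molecule's label and group id;
    pose rows add flip noise on the molecule's latent bit pattern plus a
    per-(class, state) Gaussian docking score in the trailing column.
    """
    spec = spec or LibrarySpec()
    rng = np.random.default_rng(spec.seed)
    if spec.overlap >= 1.0:
        import warnings
        warnings.warn("overlap = 1: classes indistinguishable by bits",
                      RuntimeWarning, stacklevel=2)
    n_plif_bits = N_BITS * spec.n_residues
    ag_bits, an_bits = _signature_bits(rng, n_plif_bits, spec.n_signature,
                                       spec.overlap)
    ag_ecfp, an_ecfp = _signature_bits(rng, spec.ecfp_bits,
                                       spec.ecfp_signature, spec.overlap)
    score_dist = dict(spec.score_distributions)
    states = RECEPTOR_STATE_NAMES[:spec.n_states]

    mol_ids, mol_labels, pkds, ecfps = [], [], [], []
    rows, groups, labels, state_col, scores = [], [], [], [], []
    for cls, cls_name, sig, esig in ((1, "agonist", ag_bits, ag_ecfp),
                                     (0, "antagonist", an_bits, an_ecfp)):
        for m in range(spec.n_per_class):
            mol_id = f"{cls_name[:2]}{m:03d}"
            mol_ids.append(mol_id)
            mol_labels.append(cls)
            pkds.append(float(rng.normal(spec.pkd_mean, spec.pkd_sd)))
            # molecule-level latent interaction pattern
            latent = rng.random(n_plif_bits) < spec.background_on_prob
            latent[sig] = rng.random(len(sig)) < spec.signature_on_prob
            efp = rng.random(spec.ecfp_bits) < spec.background_on_prob
            efp[esig] = rng.random(len(esig)) < spec.signature_on_prob
            ecfps.append(efp)
            for state in states:
                mu, sd = score_dist[(cls_name, state)]
                for p in range(spec.poses_per_molecule):
                    flips = rng.random(n_plif_bits) < spec.pose_flip_prob
                    bits = np.logical_xor(latent, flips)
                    score = float(rng.normal(mu, sd))
                    rows.append(np.concatenate([bits.astype(float), [score]]))
                    groups.append(mol_id)
                    labels.append(cls)
                    state_col.append(state)
                    scores.append(score)
    feature_names = [f"res{r}:{bit}" for r in range(spec.n_residues)
                     for bit in BIT_NAMES] + ["docking_score"]
    return SyntheticLibrary(
        molecule_ids=mol_ids,
        molecule_labels=np.array(mol_labels),
        pkd=np.clip(np.array(pkds), 3.5, 10.0),
        ecfp=np.stack(ecfps),
        X=np.stack(rows),
        sample_groups=np.array(groups),
        sample_labels=np.array(labels),
        sample_states=np.array(state_col),
        sample_scores=np.array(scores),
        feature_names=feature_names,
        agonist_signature_bits=ag_bits,
        antagonist_signature_bits=an_bits,
    )


# ---------------------------------------------------------------------------
# Planted fingerprint blobs
# ---------------------------------------------------------------------------

@dataclass
class FingerprintBlobs:
    fingerprints: list[BitFingerprint]
    labels: np.ndarray
    archetypes: np.ndarray
    archetype_max_tc: float


def make_fingerprint_blobs(k: int, per_cluster: int,
                           within_flip_rate: float = 0.02,
                           between_tc: float = 0.15,
                           n_bits: int = 512, n_on: int = 24,
                           seed: int = 0) -> FingerprintBlobs:
    """Plant ``k`` fingerprint clusters with bounded archetype similarity.

    Each archetype shares a common core (sized to hit the requested
    between-archetype Tanimoto) plus exclusive bits; members flip each
    bit independently at ``within_flip_rate``.  Warns when the noise is
    large enough to blur the planted separation.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    n_core = int(round(2 * n_on * between_tc / max(1.0 - between_tc, 1e-9)))
    need = n_core + k * n_on
    if need > n_bits:
        raise ValueError(f"need {need} bits, have {n_bits}")
    expected_within = 2 * within_flip_rate * n_bits / max(n_on + n_core, 1)
    if expected_within > 1.0 - between_tc:
        import warnings
        warnings.warn("within-cluster noise comparable to between-cluster "
                      "separation; clusters may overlap", RuntimeWarning,
                      stacklevel=2)
    perm = rng.permutation(n_bits)
    core = perm[:n_core]
    archetypes = np.zeros((k, n_bits), dtype=bool)
    for c in range(k):
        excl = perm[n_core + c * n_on:n_core + (c + 1) * n_on]
        archetypes[c, core] = True
        archetypes[c, excl] = True
    max_tc = max(tanimoto(archetypes[i], archetypes[j])
                 for i in range(k) for j in range(i + 1, k))
    fps, labels = [], []
    for c in range(k):
        for m in range(per_cluster):
            flips = rng.random(n_bits) < within_flip_rate
            bits = np.logical_xor(archetypes[c], flips)
            fps.append(BitFingerprint(bits=bits, radius=2,
                                      molecule_id=f"c{c}_m{m:03d}"))
            labels.append(c)
    return FingerprintBlobs(fingerprints=fps, labels=np.array(labels),
                            archetypes=archetypes, archetype_max_tc=max_tc)


#: small real-molecule SMILES set for fingerprint-code tests (adenosine
#: receptor chemotypes: xanthines and nucleosides)
TOY_SMILES: dict[str, str] = {
    "caffeine": "Cn1c(=O)c2c(ncn2C)n(C)c1=O",
    "theophylline": "Cn1c(=O)c2[nH]cnc2n(C)c1=O",
    "theobromine": "Cn1cnc2c1c(=O)[nH]c(=O)n2C",
    "adenosine": "Nc1ncnc2c1ncn2[C@@H]1O[C@H](CO)[C@@H](O)[C@H]1O",
    "neca": "CCNC(=O)[C@H]1O[C@@H](n2cnc3c(N)ncnc32)[C@H](O)[C@@H]1O",
    "ethane": "CC",
    "benzene": "c1ccccc1",
}
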