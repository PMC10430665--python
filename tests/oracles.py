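"""Independent brute-force oracles the tests check the package against.

Everything here is written as plain nested loops and textbook formulas,
deliberately avoiding the package's vectorized/recursive code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from gpcrscreen.molio import METAL_ELEMENTS, Pose, Receptor
from gpcrscreen.plif import (_BACKBONE_ACCEPTORS, _BACKBONE_APOLAR,
                             _BACKBONE_DONORS, HYDROPHOBIC_RESIDUES,
                             RESIDUE_CHEMISTRY, InteractionCriteria,
                             ResidueChemistry)


def _dist(a, b) -> float:
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def _plane_normal(points) -> np.ndarray:
    """Ring-plane normal from the first well-separated atom triple."""
    p0 = np.asarray(points[0], float)
    for i, j in itertools.combinations(range(1, len(points)), 2):
        v1 = np.asarray(points[i], float) - p0
        v2 = np.asarray(points[j], float) - p0
        n = np.cross(v1, v2)
        if np.linalg.norm(n) > 1e-6:
            return n / np.linalg.norm(n)
    raise ValueError("degenerate ring")


def _ligand_ring_groups(pose: Pose) -> list[list]:
    arom = [a for a in pose.heavy_atoms() if a.aromatic]
    groups: list[list] = []
    assigned = [False] * len(arom)
    for i in range(len(arom)):
        if assigned[i]:
            continue
        group = [i]
        assigned[i] = True
        frontier = [i]
        while frontier:
            k = frontier.pop()
            for j in range(len(arom)):
                if not assigned[j] and _dist(arom[k].xyz, arom[j].xyz) < 1.75:
                    assigned[j] = True
                    group.append(j)
                    frontier.append(j)
        if len(group) >= 5:
            groups.append([arom[g] for g in group])
    return groups


def brute_force_plif(pose: Pose, receptor: Receptor,
                     criteria: InteractionCriteria) -> dict:
    """O(atoms^2) re-derivation of every interaction predicate.

    Returns {residue_key: 8-bool list} for every residue within the
    contact shell, mirroring the detector's contract.
    """
    heavy = pose.heavy_atoms()
    hydrogens = [a for a in pose.atoms if not a.is_heavy]
    has_h = bool(hydrogens)

    lig_apolar, lig_donor, lig_acceptor = [], [], []
    lig_pos, lig_neg, lig_metal, donor_h = [], [], [], []
    for a in heavy:
        el = a.element.upper()
        if el in METAL_ELEMENTS and el not in ("C", "N", "O", "S"):
            lig_metal.append(a)
            continue
        if el in ("C", "S") and a.formal_charge == 0:
            lig_apolar.append(a)
        if el in ("N", "O"):
            if a.formal_charge <= 0:
                lig_acceptor.append(a)
            if has_h:
                hs = [h for h in hydrogens if _dist(h.xyz, a.xyz) <= 1.3]
                if hs:
                    lig_donor.append(a)
                    donor_h.append((a, hs))
            elif a.formal_charge >= 0:
                lig_donor.append(a)
        if a.formal_charge > 0:
            lig_pos.append(a)
        elif a.formal_charge < 0:
            lig_neg.append(a)
    rings = _ligand_ring_groups(pose)

    out = {}
    for res in receptor.residues:
        res_heavy = [a for a in res.atoms if a.element != "H"]
        shell = criteria.contact_shell
        if min((_dist(ra.xyz, la.xyz) for ra in res_heavy for la in heavy),
               default=math.inf) > shell:
            continue
        bits = [False] * 8
        chem = RESIDUE_CHEMISTRY.get(res.name, ResidueChemistry())
        by_name = {a.name: a for a in res.atoms}

        if res.name in HYDROPHOBIC_RESIDUES:
            for name in chem.apolar + _BACKBONE_APOLAR:
                if name in by_name:
                    for la in lig_apolar:
                        if _dist(by_name[name].xyz, la.xyz) <= criteria.hydrophobic_max_dist:
                            bits[0] = True

        if res.aromatic_ring_atoms:
            for ring_names in res.aromatic_ring_atoms:
                if not all(n in by_name for n in ring_names):
                    continue
                pts = [by_name[n].xyz for n in ring_names]
                centroid = np.mean(np.asarray(pts, float), axis=0)
                n_res = _plane_normal(pts)
                for lig_ring in rings:
                    lpts = [a.xyz for a in lig_ring]
                    lcent = np.mean(np.asarray(lpts, float), axis=0)
                    if _dist(centroid, lcent) > criteria.ring_centroid_max_dist:
                        continue
                    n_lig = _plane_normal(lpts)
                    cosv = abs(float(np.dot(n_res, n_lig)))
                    ang = math.degrees(math.acos(min(1.0, cosv)))
                    lo, hi = criteria.edge_face_normal_angle_range
                    if ang <= criteria.face_face_max_normal_angle:
                        bits[1] = True
                    elif lo <= ang <= hi:
                        bits[2] = True

        for name in chem.acceptors + _BACKBONE_ACCEPTORS:
            if name not in by_name:
                continue
            acc = by_name[name]
            if has_h:
                for don, hs in donor_h:
                    if _dist(acc.xyz, don.xyz) <= criteria.hbond_max_dist:
                        for h in hs:
                            v1 = np.asarray(don.xyz) - np.asarray(h.xyz)
                            v2 = np.asarray(acc.xyz) - np.asarray(h.xyz)
                            c = float(np.dot(v1, v2) /
                                      (np.linalg.norm(v1) * np.linalg.norm(v2)))
                            if math.degrees(math.acos(max(-1, min(1, c)))) >= criteria.hbond_min_angle:
                                bits[3] = True
            else:
                for don in lig_donor:
                    if _dist(acc.xyz, don.xyz) <= criteria.hbond_max_dist:
                        bits[3] = True
        for name in chem.donors + _BACKBONE_DONORS:
            if name in by_name:
                for acc in lig_acceptor:
                    if _dist(by_name[name].xyz, acc.xyz) <= criteria.hbond_max_dist:
                        bits[4] = True

        if chem.positive_group:
            pts = [by_name[n].xyz for n in chem.positive_group if n in by_name]
            if pts:
                center = np.mean(np.asarray(pts, float), axis=0)
                for la in lig_neg:
                    if _dist(center, la.xyz) <= criteria.saltbridge_max_dist:
                        bits[5] = True
        if chem.negative_group:
            pts = [by_name[n].xyz for n in chem.negative_group if n in by_name]
            if pts:
                center = np.mean(np.asarray(pts, float), axis=0)
                for la in lig_pos:
                    if _dist(center, la.xyz) <= criteria.saltbridge_max_dist:
                        bits[6] = True

        for ra in res.atoms:
            if ra.element in ("N", "O"):
                for la in lig_metal:
                    if _dist(ra.xyz, la.xyz) <= criteria.metal_max_dist:
                        bits[7] = True
        out[res.key] = bits
    return out


# ---------------------------------------------------------------------------
# Exhaustive Shapley enumeration on a tree ensemble
# ---------------------------------------------------------------------------

def tree_expected_value(tree, x, coalition: frozenset, node: int = 0) -> float:
    """Expected tree output with features in the coalition fixed to x and
    the rest marginalized by training cover (recursive descent)."""
    if tree.children_left[node] < 0:
        return float(tree.value[node])
    f = int(tree.feature[node])
    left, right = int(tree.children_left[node]), int(tree.children_right[node])
    if f in coalition:
        child = left if x[f] <= tree.threshold[node] else right
        return tree_expected_value(tree, x, coalition, child)
    wl = tree.cover[left] / tree.cover[node]
    wr = tree.cover[right] / tree.cover[node]
    return (wl * tree_expected_value(tree, x, coalition, left)
            + wr * tree_expected_value(tree, x, coalition, right))


def exhaustive_shapley(trees, x, n_features: int) -> np.ndarray:
    """Shapley values by full coalition enumeration, averaged over trees."""
    phi = np.zeros(n_features)
    all_features = list(range(n_features))
    fact = math.factorial
    for tree in trees:
        for i in all_features:
            others = [f for f in all_features if f != i]
            for r in range(len(others) + 1):
                for subset in itertools.combinations(others, r):
                    s = frozenset(subset)
                    weight = (fact(len(s)) * fact(n_features - len(s) - 1)
                              / fact(n_features))
                    gain = (tree_expected_value(tree, x, s | {i})
                            - tree_expected_value(tree, x, s))
                    phi[i] += weight * gain
    return phi / len(trees)


# ---------------------------------------------------------------------------
# Confusion-matrix metrics by direct counting
# ---------------------------------------------------------------------------

def brute_force_metrics(y_true, y_pred) -> dict:
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "accuracy": (tp + tn) / len(y_true)}


def mann_whitney_auc(y_true, scores) -> float:
    """ROC AUC as the Mann-Whitney U statistic (pairwise comparison)."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_tanimoto(a, b) -> float:
    inter = sum(1 for x, y in zip(a, b) if x and y)
    union = sum(1 for x, y in zip(a, b) if x or y)
    return inter / union if union else 1.0
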