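"""Interaction-fingerprint detection, matrix assembly, bit frequencies."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from gpcrscreen.molio import Pose, PoseAtom, Receptor
from gpcrscreen.plif import (BIT_NAMES, InteractionCriteria, PLIFVector,
                             ResidueBitBlock, build_feature_matrix,
                             detect_interactions, residue_order_from_plifs,
                             summarize_bit_frequencies)
from gpcrscreen.synthetic import (InteractionSpec, make_pocket_fixture,
                                  random_interaction_spec)

from oracles import brute_force_plif


def _bits_for(fixture, key):
    blocks = {b.residue_key: b.bits
              for b in detect_interactions(fixture.pose, fixture.receptor)}
    return blocks.get(key, np.zeros(8, dtype=bool))


@pytest.mark.parametrize("spec, bit_index, expected", [
    (InteractionSpec("ASN", "hbond_acceptor", 2.9), 3, True),
    (InteractionSpec("ASN", "hbond_acceptor", 4.5, expect_set=False), 3, False),
    (InteractionSpec("ASN", "hbond_donor", 2.9), 4, True),
    (InteractionSpec("PHE", "aromatic_face_face", 3.6, angle=5.0), 1, True),
    (InteractionSpec("PHE", "aromatic_edge_face", 4.4, angle=75.0), 2, True),
    (InteractionSpec("ARG", "saltbridge_positive", 3.3), 5, True),
    (InteractionSpec("ASP", "saltbridge_negative", 3.0), 6, True),
    (InteractionSpec("ALA", "hydrophobic", 3.4), 0, True),
    (InteractionSpec("ALA", "hydrophobic", 4.5, expect_set=False), 0, False),
    (InteractionSpec("ASP", "metal", 2.3), 7, True),
])
def test_constructed_geometry_sets_expected_bit(spec, bit_index, expected):
    fixture = make_pocket_fixture([spec])
    key = fixture.receptor.residues[0].key
    bits = _bits_for(fixture, key)
    assert bool(bits[bit_index]) is expected
    # full manifest agreement, not just the target bit
    np.testing.assert_array_equal(bits, fixture.manifest[key])


def test_face_face_and_edge_face_mutually_exclusive():
    fixture = make_pocket_fixture(
        [InteractionSpec("PHE", "aromatic_face_face", 3.6, angle=5.0)])
    bits = _bits_for(fixture, fixture.receptor.residues[0].key)
    assert bits[1] and not bits[2]


def test_explicit_hydrogen_angle_criterion():
    """A donor H pointing away from the acceptor kills the H-bond bit."""
    fixture = make_pocket_fixture([InteractionSpec("ASN", "hbond_acceptor", 2.9)])
    pose = fixture.pose
    donor = np.array(pose.atoms[0].xyz)
    acc = fixture.receptor.residues[0].atom("OD1").coords
    # H on the far side of the donor: D-H...A angle ~ 0 degrees
    away = donor + 1.0 * (donor - acc) / np.linalg.norm(donor - acc)
    bad = Pose(pose.molecule_id, pose.receptor_id,
               pose.atoms + [PoseAtom("H", tuple(away))], 0.0)
    bits = {b.residue_key: b.bits
            for b in detect_interactions(bad, fixture.receptor)}
    assert not bits[fixture.receptor.residues[0].key][3]
    # H placed between donor and acceptor restores it (angle ~ 180)
    toward = donor + 1.0 * (acc - donor) / np.linalg.norm(acc - donor)
    good = Pose(pose.molecule_id, pose.receptor_id,
                pose.atoms + [PoseAtom("H", tuple(toward))], 0.0)
    bits = {b.residue_key: b.bits
            for b in detect_interactions(good, fixture.receptor)}
    assert bits[fixture.receptor.residues[0].key][3]


class TestAgainstBruteForceOracle:
    def test_random_fixtures_match_oracle_and_manifest(self):
        """Detector output == naive O(n^2) predicate oracle == manifest on
        >= 100 randomized pocket fixtures."""
        rng = np.random.default_rng(123)
        criteria = InteractionCriteria()
        n_checked = 0
        while n_checked < 110:
            try:
                specs = [random_interaction_spec(rng)
                         for _ in range(int(rng.integers(1, 4)))]
                fixture = make_pocket_fixture(specs, criteria)
            except ValueError:  # ambiguous geometry resampled
                continue
            n_checked += 1
            detected = {b.residue_key: b.bits for b in detect_interactions(
                fixture.pose, fixture.receptor, criteria)}
            oracle = brute_force_plif(fixture.pose, fixture.receptor, criteria)
            for key, expected in fixture.manifest.items():
                got = detected.get(key, np.zeros(8, dtype=bool))
                np.testing.assert_array_equal(got, expected, err_msg=str(key))
                np.testing.assert_array_equal(
                    got, np.asarray(oracle.get(key, [False] * 8)),
                    err_msg=f"oracle disagreement at {key}")

    def test_rigid_motion_invariance(self):
        """Rotating+translating pose and receptor together changes no bit."""
        rng = np.random.default_rng(5)
        specs = [InteractionSpec("ASN", "hbond_acceptor", 2.9),
                 InteractionSpec("PHE", "aromatic_face_face", 3.6, angle=10.0),
                 InteractionSpec("ARG", "saltbridge_positive", 3.0)]
        fixture = make_pocket_fixture(specs)
        before = {b.residue_key: b.bits.copy() for b in detect_interactions(
            fixture.pose, fixture.receptor)}
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.uniform(-50, 50, 3)

            def move(xyz):
                return tuple(rot @ np.asarray(xyz) + shift)

            pose = Pose(fixture.pose.molecule_id, fixture.pose.receptor_id,
                        [PoseAtom(a.element, move(a.xyz), a.formal_charge,
                                  a.aromatic) for a in fixture.pose.atoms],
                        fixture.pose.docking_score)
            residues = []
            for r in fixture.receptor.residues:
                moved = type(r)(chain=r.chain, number=r.number, name=r.name,
                                atoms=[type(a)(a.name, a.element, move(a.xyz))
                                       for a in r.atoms],
                                formal_charge_class=r.formal_charge_class,
                                aromatic_ring_atoms=r.aromatic_ring_atoms)
                residues.append(moved)
            receptor = Receptor(fixture.receptor.id, residues,
                                fixture.receptor.state_label)
            after = {b.residue_key: b.bits
                     for b in detect_interactions(pose, receptor)}
            assert set(after) == set(before)
            for key in before:
                np.testing.assert_array_equal(after[key], before[key])

    def test_shrinking_cutoffs_never_sets_new_bits(self):
        rng = np.random.default_rng(9)
        loose = InteractionCriteria()
        tight = InteractionCriteria(
            hydrophobic_max_dist=3.0, hbond_max_dist=2.8,
            saltbridge_max_dist=3.0, ring_centroid_max_dist=4.0,
            metal_max_dist=2.2)
        for _ in range(20):
            try:
                fixture = make_pocket_fixture(
                    [random_interaction_spec(rng) for _ in range(2)], loose)
            except ValueError:
                continue
            loose_bits = {b.residue_key: b.bits for b in detect_interactions(
                fixture.pose, fixture.receptor, loose)}
            tight_bits = {b.residue_key: b.bits for b in detect_interactions(
                fixture.pose, fixture.receptor, tight)}
            for key, tb in tight_bits.items():
                lb = loose_bits.get(key, np.zeros(8, dtype=bool))
                assert not np.any(tb & ~lb), f"tightening set a bit at {key}"


def _vec(mol, rid, keys_bits, score=None):
    blocks = [ResidueBitBlock(k, np.array(b, dtype=bool))
              for k, b in keys_bits]
    return PLIFVector(mol, rid, blocks, docking_score_feature=score)


class TestFeatureMatrix:
    KEYS = [("A", 1, "ALA"), ("A", 2, "ASN"), ("A", 3, "PHE")]

    def test_shape_without_score(self):
        v = _vec("m1", "r", [(self.KEYS[0], [1] + [0] * 7)])
        m = build_feature_matrix([v, v], self.KEYS)
        assert m.shape == (2, 24)

    def test_score_column_appended(self):
        v1 = _vec("m1", "r", [(self.KEYS[0], [1] + [0] * 7)], score=-7.5)
        v2 = _vec("m2", "r", [], score=-6.0)
        m = build_feature_matrix([v1, v2], self.KEYS, include_score=True)
        assert m.shape == (2, 25)
        assert list(m["docking_score"]) == [-7.5, -6.0]

    def test_unknown_residue_dropped_with_warning(self, caplog):
        v = _vec("m1", "r", [(("B", 99, "GLY"), [1] * 8)])
        with caplog.at_level("WARNING"):
            m = build_feature_matrix([v], self.KEYS)
        assert m.to_numpy().sum() == 0
        assert any("dropped" in r.message for r in caplog.records)

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            build_feature_matrix([], self.KEYS)

    def test_residue_order_is_sorted_union(self):
        v1 = _vec("m1", "r", [(self.KEYS[2], [1] * 8)])
        v2 = _vec("m2", "r", [(self.KEYS[0], [1] * 8)])
        assert residue_order_from_plifs([v1, v2]) == [self.KEYS[0], self.KEYS[2]]


class TestBitFrequencies:
    def test_count_ratio(self):
        m = pd.DataFrame({"A:ALA1:hydrophobic": [1, 1, 0, 0]})
        freq = summarize_bit_frequencies(m, ["ag", "ag", "ag", "ag"])
        assert freq.loc["ag", "A:ALA1:hydrophobic"] == pytest.approx(0.5)

    def test_all_zero_column(self):
        m = pd.DataFrame({"c": [0, 0, 0]})
        freq = summarize_bit_frequencies(m, ["ag", "ag", "an"])
        assert (freq["c"] == 0).all()

    def test_designated_agonist_bit_reaches_frequency_one(self):
        """Library built with deterministic signature bits: agonists carry
        their signature at frequency 1, counted by brute force."""
        from gpcrscreen.synthetic import LibrarySpec, make_labeled_library
        spec = LibrarySpec(n_per_class=8, signature_on_prob=1.0,
                           pose_flip_prob=0.0, background_on_prob=0.0, seed=1)
        lib = make_labeled_library(spec)
        m = pd.DataFrame(lib.X[:, :-1], columns=lib.feature_names[:-1])
        labels = np.where(lib.sample_labels == 1, "agonist", "antagonist")
        freq = summarize_bit_frequencies(m, labels)
        col = lib.feature_names[lib.agonist_signature_bits[0]]
        brute = np.mean([row[lib.agonist_signature_bits[0]]
                         for row, lab in zip(lib.X, lib.sample_labels)
                         if lab == 1])
        assert freq.loc["agonist", col] == pytest.approx(1.0)
        assert brute == pytest.approx(1.0)

    def test_label_length_mismatch_is_error(self):
        m = pd.DataFrame({"c": [1, 0]})
        with pytest.raises(ValueError):
            summarize_bit_frequencies(m, ["ag"])
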