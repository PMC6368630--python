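"""Contact detection, geometric classification, fingerprints, superposition."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from classf_switch.contacts import (
    AtomRecord,
    ContactPair,
    ResidueRef,
    StructureModel,
    classify_contact,
    detect_contacts,
    fingerprint,
    superpose,
)
from classf_switch.generic_numbering import GenericLabel, HelixSegment, SegmentMap
from classf_switch.simulate import gen_helix_bundle


def brute_force_contacts(model, cutoff=4.5, min_separation=4, interhelical_only=None):
    """Independent all-pairs oracle: nested loops, no spatial index."""
    if interhelical_only is None:
        interhelical_only = model.segment_map is not None
    residues = model.residues()
    keys = sorted(residues)
    found = {}
    for (ka, kb) in itertools.combinations(keys, 2):
        dmin = min(
            math.dist(a.coords, b.coords)
            for a in residues[ka]
            for b in residues[kb]
            if a.is_heavy and b.is_heavy
        )
        if dmin > cutoff:
            continue
        if ka[0] == kb[0] and abs(ka[1] - kb[1]) <= min_separation:
            continue
        if interhelical_only and model.segment_map is not None:
            la, lb = model.label_of(ka[1]), model.label_of(kb[1])
            if la is not None and lb is not None and la.helix == lb.helix:
                continue
        found[(ka, kb)] = dmin
    return found


def atom(chain, res, name, x, y, z, res_name="ALA", element=None):
    return AtomRecord(chain, res, res_name, name, element or name[0], (x, y, z))


class TestDetectContacts:
    def test_two_residues_within_cutoff(self):
        model = StructureModel(
            "toy",
            [atom("A", 1, "CA", 0, 0, 0), atom("A", 20, "CA", 4.0, 0, 0)],
        )
        contacts = detect_contacts(model, heavy_cutoff=4.5)
        assert len(contacts) == 1
        assert contacts[0].min_distance == pytest.approx(4.0)

    def test_sequence_separation_filter_removes_near_neighbors(self):
        """Contacts 4 or fewer residues apart in sequence are disregarded."""
        model = StructureModel(
            "toy",
            [atom("A", 10, "CA", 0, 0, 0), atom("A", 14, "CA", 4.0, 0, 0)],
        )
        assert detect_contacts(model, heavy_cutoff=4.5) == []
        # distance 5 in sequence is retained
        model2 = StructureModel(
            "toy",
            [atom("A", 10, "CA", 0, 0, 0), atom("A", 15, "CA", 4.0, 0, 0)],
        )
        assert len(detect_contacts(model2, heavy_cutoff=4.5)) == 1

    def test_different_chains_ignore_separation(self):
        model = StructureModel(
            "toy",
            [atom("A", 10, "CA", 0, 0, 0), atom("B", 11, "CA", 4.0, 0, 0)],
        )
        assert len(detect_contacts(model)) == 1

    def test_hydrogens_excluded(self):
        model = StructureModel(
            "toy",
            [
                atom("A", 1, "CA", 0, 0, 0),
                atom("A", 20, "CA", 0, 0, 10.0),
                AtomRecord("A", 20, "ALA", "H1", "H", (0, 0, 4.0)),
            ],
        )
        assert detect_contacts(model) == []

    def test_no_heavy_atoms_errors(self):
        model = StructureModel("hs", [AtomRecord("A", 1, "ALA", "H1", "H", (0, 0, 0))])
        with pytest.raises(ValueError, match="no heavy atoms"):
            detect_contacts(model)

    def test_monotone_in_cutoff(self):
        bundle = gen_helix_bundle(
            planted_contacts=[("6.32", "7.55"), ("1.40", "2.47")], seed=11
        )
        small = {(c.res_a, c.res_b) for c in detect_contacts(bundle, heavy_cutoff=4.2)}
        large = {(c.res_a, c.res_b) for c in detect_contacts(bundle, heavy_cutoff=4.8)}
        assert small <= large

    def test_rigid_transform_invariance(self):
        bundle = gen_helix_bundle(planted_contacts=[("6.32", "7.55")], seed=5)
        R = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        moved = bundle.transformed(R, np.array([10.0, -3.0, 7.0]))
        before = {(c.res_a, c.res_b): c.min_distance for c in detect_contacts(bundle)}
        after = {(c.res_a, c.res_b): c.min_distance for c in detect_contacts(moved)}
        assert before.keys() == after.keys()
        for key in before:
            assert before[key] == pytest.approx(after[key], abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_brute_force_oracle_on_bundles(self, seed):
        plants = [("6.32", "7.55"), ("1.40", "2.47"), ("3.30", "4.57")][: seed + 1]
        bundle = gen_helix_bundle(planted_contacts=plants, seed=seed)
        fast = {
            ((c.res_a.chain, c.res_a.res_index), (c.res_b.chain, c.res_b.res_index)):
                c.min_distance
            for c in detect_contacts(bundle)
        }
        slow = brute_force_contacts(bundle)
        assert fast.keys() == slow.keys()
        for key in fast:
            assert fast[key] == pytest.approx(slow[key], abs=1e-9)


def make_arg_trp_model(separation_z):
    """Arg guanidinium centroid at height separation_z over a Trp six-ring
    centroid at the origin (centroids placed by construction)."""
    ring_names = ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")
    ring = [
        atom("A", 30, name, 1.4 * math.cos(k * math.pi / 3),
             1.4 * math.sin(k * math.pi / 3), 0.0, res_name="TRP")
        for k, name in enumerate(ring_names)
    ]
    # three guanidinium atoms arranged to sum to zero in xy
    guan = [
        atom("A", 10, "CZ", 1.0, 0.0, separation_z, res_name="ARG"),
        atom("A", 10, "NH1", -0.5, 0.87, separation_z, res_name="ARG", element="N"),
        atom("A", 10, "NH2", -0.5, -0.87, separation_z, res_name="ARG", element="N"),
    ]
    model = StructureModel("pication", guan + ring)
    pair = ContactPair(
        ResidueRef("A", 10), ResidueRef("A", 30), frozenset({"heavy_atom"}), 4.0
    )
    return model, pair


class TestClassifyContact:
    def test_pi_cation_within_6A_of_ring_centroid(self):
        model, pair = make_arg_trp_model(4.5)
        assert "pi_cation" in classify_contact(model, pair)

    def test_pi_cation_absent_beyond_cutoff(self):
        model, pair = make_arg_trp_model(6.5)
        assert "pi_cation" not in classify_contact(model, pair)

    def test_hydrogen_bond_between_backbone_O_and_sidechain_N(self):
        model = StructureModel(
            "hbond",
            [
                atom("A", 10, "O", 0, 0, 0, element="O"),
                atom("A", 30, "NZ", 0, 0, 2.9, res_name="LYS", element="N"),
            ],
        )
        pair = ContactPair(
            ResidueRef("A", 10), ResidueRef("A", 30), frozenset({"heavy_atom"}), 2.9
        )
        types = classify_contact(model, pair)
        assert "hydrogen_bond" in types

    def test_carbon_only_pair_stays_heavy_atom_only(self):
        model = StructureModel(
            "cc",
            [atom("A", 10, "CA", 0, 0, 0), atom("A", 30, "CA", 0, 0, 4.0)],
        )
        pair = ContactPair(
            ResidueRef("A", 10), ResidueRef("A", 30), frozenset({"heavy_atom"}), 4.0
        )
        assert classify_contact(model, pair) == frozenset({"heavy_atom"})

    def test_missing_criterion_atoms_evaluate_absent(self):
        # ARG without its guanidinium cannot score pi_cation; no exception
        model = StructureModel(
            "partial",
            [
                atom("A", 10, "CB", 0, 0, 4.0, res_name="ARG"),
                atom("A", 30, "CD2", 0, 0, 0, res_name="TRP"),
            ],
        )
        pair = ContactPair(
            ResidueRef("A", 10), ResidueRef("A", 30), frozenset({"heavy_atom"}), 4.0
        )
        assert classify_contact(model, pair) == frozenset({"heavy_atom"})


class TestFingerprint:
    def test_single_model_single_column_all_present(self):
        bundle = gen_helix_bundle(planted_contacts=[("6.32", "7.55")], seed=3)
        fp = fingerprint([bundle])
        assert list(fp.columns) == ["BUNDLE"]
        assert fp.loc["6.32-7.55", "BUNDLE"] == 1
        assert (fp.values == 1).all()

    def test_identical_models_give_identical_columns(self):
        a = gen_helix_bundle(planted_contacts=[("6.32", "7.55")], seed=4,
                             structure_id="A")
        b = gen_helix_bundle(planted_contacts=[("6.32", "7.55")], seed=4,
                             structure_id="B")
        fp = fingerprint([a, b])
        assert (fp["A"] == fp["B"]).all()

    def test_planted_in_3_of_5_models(self):
        """The 6.32-7.55 row is present exactly in the models that plant it."""
        models = []
        for i in range(5):
            plants = [("6.32", "7.55")] if i < 3 else []
            models.append(
                gen_helix_bundle(planted_contacts=plants, seed=20 + i,
                                 structure_id=f"S{i}")
            )
        fp = fingerprint(models, focus="6.32", partner_filter={7, 2})
        assert fp.loc["6.32-7.55"].tolist() == [1, 1, 1, 0, 0]

    def test_focus_unmapped_everywhere_errors(self):
        bundle = gen_helix_bundle(seed=1)
        with pytest.raises(ValueError, match="unmapped"):
            fingerprint([bundle], focus="8.50")

    def test_every_cell_filled(self):
        models = [
            gen_helix_bundle(planted_contacts=[("6.32", "7.55")], seed=30,
                             structure_id="X"),
            gen_helix_bundle(planted_contacts=[("1.40", "2.47")], seed=31,
                             structure_id="Y"),
        ]
        fp = fingerprint(models)
        assert fp.shape == (2, 2)
        assert fp.isin([0, 1]).all().all()


class TestSuperpose:
    def _toy(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(n, 3)) * 5.0
        atoms = [atom("A", i + 1, "CA", *c) for i, c in enumerate(coords)]
        return StructureModel("ref", atoms), coords

    def test_identity_on_self(self):
        model, _ = self._toy()
        R, t, rmsd = superpose(model, model)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0, atol=1e-9)

    def test_recovers_known_rotation(self):
        model, _ = self._toy(seed=1)
        rot = Rotation.from_euler("zyx", [30, 50, -10], degrees=True).as_matrix()
        moved = model.transformed(rot, np.array([1.0, 2.0, 3.0]))
        R, t, rmsd = superpose(model, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        # R must invert the applied rotation
        assert np.allclose(R @ rot, np.eye(3), atol=1e-9)

    def test_rmsd_matches_independent_optimizer(self):
        """Four-atom toy pair: Kabsch RMSD equals scipy's Wahba solution."""
        rng = np.random.default_rng(42)
        P = rng.normal(size=(4, 3)) * 3.0
        Q = rng.normal(size=(4, 3)) * 3.0
        ref = StructureModel("r", [atom("A", i + 1, "CA", *c) for i, c in enumerate(Q)])
        mob = StructureModel("m", [atom("A", i + 1, "CA", *c) for i, c in enumerate(P)])
        _, _, rmsd = superpose(ref, mob)
        _, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert rmsd == pytest.approx(rssd / math.sqrt(len(P)), rel=1e-9)

    def test_too_few_shared_atoms_errors(self):
        ref = StructureModel("r", [atom("A", 1, "CA", 0, 0, 0), atom("A", 2, "CA", 1, 0, 0)])
        with pytest.raises(ValueError, match="3 shared"):
            superpose(ref, ref)

    def test_collinear_selection_errors(self):
        coords = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)]
        ref = StructureModel("r", [atom("A", i + 1, "CA", *c) for i, c in enumerate(coords)])
        with pytest.raises(ValueError, match="degenerate"):
            superpose(ref, ref)
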