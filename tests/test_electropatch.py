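"""Charges, dot surface, screened potential, patches, acidic geometry."""

import numpy as np
import pytest

from ankylotherm.electropatch import (
    COULOMB_KJ_A,
    ChargeModel,
    ChargeSite,
    assign_charges,
    carboxyl_distance_matrix,
    charge_anisotropy,
    debye_length,
    detect_patches,
    sample_surface,
    screened_potential,
)
from ankylotherm.structures import Atom, Residue, StructureModel


def model_with(residues):
    m = StructureModel("fixture")
    for r in residues:
        m.chains.setdefault(r.chain_id, []).append(r)
    return m


def asp(number, od1, od2, chain="A"):
    return Residue(chain, number, "ASP", [
        Atom("CA", "C", np.asarray(od1) + [0, 0, 2]),
        Atom("OD1", "O", np.asarray(od1, float)),
        Atom("OD2", "O", np.asarray(od2, float)),
    ])


def single_charge(q=-1.0, pos=(0.0, 0.0, 0.0)):
    return ChargeModel([ChargeSite("A:ASP1", "A", 1, "ASP", np.asarray(pos, float), q)])


class TestAssignCharges:
    def test_glycine_only_is_empty(self):
        gly = Residue("A", 1, "GLY", [Atom("CA", "C", np.zeros(3))])
        assert len(assign_charges(model_with([gly]))) == 0

    def test_carboxyl_midpoint_by_hand(self):
        cm = assign_charges(model_with([asp(7, (0, 0, 0), (2, 0, 0))]))
        (site,) = cm.sites
        assert site.charge == -1.0
        assert np.allclose(site.position, [1.0, 0.0, 0.0])

    def test_basic_residues_positive(self):
        lys = Residue("A", 2, "LYS", [Atom("CA", "C", np.zeros(3)),
                                      Atom("NZ", "N", np.ones(3))])
        arg = Residue("A", 3, "ARG", [Atom("CA", "C", np.zeros(3)),
                                      Atom("CZ", "C", 2 * np.ones(3))])
        cm = assign_charges(model_with([lys, arg]))
        assert sorted(cm.charges) == [1.0, 1.0]

    def test_missing_side_chain_warns_and_skips(self):
        broken = Residue("A", 9, "ASP", [Atom("CA", "C", np.zeros(3))])
        with pytest.warns(UserWarning, match="skipped"):
            cm = assign_charges(model_with([broken]))
        assert len(cm) == 0

    def test_acidic_cluster_placement_recovered(self):
        from ankylotherm.synthetic import RepeatGeometrySpec, make_repeat_structure
        spec = RepeatGeometrySpec(
            n_repeats=4,
            sequence="G" * 33 * 4,
            acidic_positions=[(3, 28), (4, 28)],
            start_number=1900,
        )
        cm = assign_charges(make_repeat_structure(spec))
        numbers = sorted(s.number for s in cm.sites)
        assert numbers == [1900 + 2 * 33 + 27, 1900 + 3 * 33 + 27]


class TestSurface:
    def test_single_atom_full_sphere(self, single_residue_model):
        pts, areas, owners = sample_surface(single_residue_model,
                                            probe=1.4, dots_per_atom=128)
        r = 1.7 + 1.4
        assert len(pts) == 128
        assert areas.sum() == pytest.approx(4 * np.pi * r**2)
        assert set(owners) == {"A:GLY1"}

    def test_fully_overlapping_atoms_do_not_double_count(self):
        res = Residue("A", 1, "GLY", [Atom("CA", "C", np.zeros(3)),
                                      Atom("CB", "C", np.zeros(3) + 1e-9)])
        pts, areas, _ = sample_surface(model_with([res]), dots_per_atom=128)
        r = 1.7 + 1.4
        # coincident spheres occlude each other entirely in Shrake-Rupley
        # dot terms; total area must not exceed the single-sphere value
        assert areas.sum() <= 4 * np.pi * r**2 + 1e-6

    def test_buried_atom_contributes_no_dots(self):
        cage = [Atom(f"C{i}", "C", 2.0 * np.array(v)) for i, v in enumerate([
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
            (0.7, 0.7, 0), (-0.7, 0.7, 0), (0.7, -0.7, 0), (-0.7, -0.7, 0),
            (0.7, 0, 0.7), (-0.7, 0, 0.7), (0.7, 0, -0.7), (-0.7, 0, -0.7),
            (0, 0.7, 0.7), (0, -0.7, 0.7), (0, 0.7, -0.7), (0, -0.7, -0.7),
        ])]
        buried = Residue("A", 1, "GLY", [Atom("CA", "C", np.zeros(3))])
        shell = Residue("A", 2, "GLY", cage)
        pts, areas, owners = sample_surface(model_with([buried, shell]),
                                            dots_per_atom=64)
        assert "A:GLY1" not in owners

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            sample_surface(StructureModel("empty", {}))


class TestScreenedPotential:
    def test_no_charges_is_identically_zero(self):
        pmap = screened_potential(ChargeModel([]), np.random.rand(20, 3))
        assert np.all(pmap.potentials == 0)

    def test_single_charge_closed_form(self):
        """Independent closed form evaluated by hand from CODATA constants:
        Coulomb constant N_A e^2 / (4 pi eps_0) = 1389.35 kJ*A/(mol*e^2) and
        Debye length 7.8295 A for 150 mM monovalent salt at 298.15 K."""
        r = 6.0
        pmap = screened_potential(
            single_charge(), np.array([[r, 0.0, 0.0]]),
            ionic_strength=0.15, eps=78.0, temperature=298.15,
        )
        assert pmap.potentials[0] == pytest.approx(-1.37960083, rel=1e-7)
        # and against the implementation's own constants to 1e-10
        exact = COULOMB_KJ_A * (-1.0) * np.exp(-r / debye_length(0.15)) / (78.0 * r)
        assert pmap.potentials[0] == pytest.approx(exact, rel=1e-10)

    def test_zero_ionic_strength_recovers_coulomb(self):
        r = 5.0
        pmap = screened_potential(single_charge(), np.array([[0, r, 0.0]]),
                                  ionic_strength=0.0)
        assert pmap.potentials[0] == pytest.approx(
            -COULOMB_KJ_A / (78.0 * r), rel=1e-12
        )

    def test_superposition_and_sign_inversion(self):
        pts = np.array([[4.0, 1.0, 0.0], [-3.0, 2.0, 5.0], [0.0, 6.0, 1.0]])
        q1 = single_charge(-1.0, (0, 0, 0))
        q2 = single_charge(+0.5, (3, 3, 0))
        both = ChargeModel(q1.sites + q2.sites)
        p1 = screened_potential(q1, pts).potentials
        p2 = screened_potential(q2, pts).potentials
        p12 = screened_potential(both, pts).potentials
        assert np.allclose(p12, p1 + p2, rtol=1e-12)
        pneg = screened_potential(both.negated(), pts).potentials
        assert np.allclose(pneg, -p12, rtol=1e-12)

    def test_magnitude_decays_with_distance(self):
        rs = np.array([[r, 0.0, 0.0] for r in (2.0, 4.0, 8.0, 16.0)])
        mags = np.abs(screened_potential(single_charge(), rs).potentials)
        assert np.all(np.diff(mags) < 0)

    def test_coincident_point_excluded_with_warning(self):
        pts = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="coincide"):
            pmap = screened_potential(single_charge(), pts)
        assert len(pmap.potentials) == 1


class TestPatches:
    def test_uniform_near_zero_map_has_no_patches(self):
        pmap = screened_potential(ChargeModel([]), np.random.rand(30, 3))
        assert detect_patches(pmap) == []

    def test_two_planted_clusters_exact_membership(self, two_cluster_fixture):
        model, expected = two_cluster_fixture
        cm = assign_charges(model)
        pts, areas, owners = sample_surface(model)
        pmap = screened_potential(cm, pts, areas, owners)
        patches = detect_patches(pmap, threshold=-5.0, sign="neg")
        assert len(patches) == 2
        assert sorted(map(set, (p.member_residues for p in patches)),
                      key=len) == sorted(map(set, expected), key=len)
        # patches sorted by area, pairwise disjoint, sub-areas bounded
        assert patches[0].area >= patches[1].area
        members0 = set(patches[0].member_points.tolist())
        members1 = set(patches[1].member_points.tolist())
        assert not members0 & members1
        assert patches[0].area + patches[1].area <= pmap.total_area

    def test_sign_selector_separates_clusters(self):
        from ankylotherm.synthetic import make_charge_fixture
        model, expected = make_charge_fixture(
            [((0, 0, 0), 4, -1), ((80, 0, 0), 4, +1)]
        )
        cm = assign_charges(model)
        pts, areas, owners = sample_surface(model)
        pmap = screened_potential(cm, pts, areas, owners)
        neg = detect_patches(pmap, -5.0, "neg")
        pos = detect_patches(pmap, +5.0, "pos")
        assert len(neg) == 1 and set(neg[0].member_residues) == expected[0]
        assert len(pos) == 1 and set(pos[0].member_residues) == expected[1]

    def test_threshold_sign_consistency_enforced(self):
        pmap = screened_potential(ChargeModel([]), np.random.rand(5, 3))
        with pytest.raises(ValueError):
            detect_patches(pmap, threshold=+3.0, sign="neg")


class TestCarboxylGeometry:
    def test_distance_matrix_hand_euclid(self):
        model = model_with([
            asp(1, (-1, 0, 0), (1, 0, 0)),           # midpoint (0,0,0)
            asp(2, (2, 4, 0), (4, 4, 0)),            # midpoint (3,4,0)
        ])
        d = carboxyl_distance_matrix(model, [("A", 1), ("A", 2)])
        assert d.iloc[0, 0] == 0.0
        assert d.iloc[0, 1] == pytest.approx(5.0)
        assert np.allclose(d.values, d.values.T)

    def test_rigid_body_invariance(self):
        model = model_with([
            asp(1, (-1, 0, 0), (1, 0, 0)),
            asp(2, (2, 4, 0), (4, 4, 0)),
            asp(3, (0, 0, 6), (0, 2, 6)),
        ])
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        moved = model.transformed(rot, np.array([5.0, -2.0, 1.0]))
        ids = [("A", 1), ("A", 2), ("A", 3)]
        assert np.allclose(carboxyl_distance_matrix(model, ids).values,
                           carboxyl_distance_matrix(moved, ids).values)

    def test_non_acidic_residue_named_in_error(self):
        gly = Residue("A", 5, "GLY", [Atom("CA", "C", np.zeros(3))])
        with pytest.raises(ValueError, match="GLY5"):
            carboxyl_distance_matrix(model_with([gly]), [("A", 5)])


class TestAnisotropy:
    def test_mirror_symmetric_pairs_vanish(self):
        sites = [
            ChargeSite("p1", "A", 1, "LYS", np.array([1.0, 0, 0]), +1),
            ChargeSite("p2", "A", 2, "LYS", np.array([-1.0, 0, 0]), +1),
            ChargeSite("n1", "A", 3, "ASP", np.array([0, 1.0, 0]), -1),
            ChargeSite("n2", "A", 4, "ASP", np.array([0, -1.0, 0]), -1),
        ]
        mag, unit = charge_anisotropy(ChargeModel(sites))
        assert mag == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(unit, 0)

    def test_single_charge_about_molecular_centroid(self):
        cm = single_charge(-1.0, (10.0, 0.0, 0.0))
        mag, unit = charge_anisotropy(cm, centroid=np.zeros(3))
        assert mag == pytest.approx(10.0)
        assert np.allclose(unit, [-1.0, 0, 0])

    def test_clustered_charges_beat_dispersed(self):
        clustered = ChargeModel([
            ChargeSite(f"c{i}", "A", i, "ASP",
                       np.array([10.0, 0, 0]) + 0.1 * i, -1.0)
            for i in range(4)
        ])
        dispersed = ChargeModel([
            ChargeSite(f"d{i}", "A", i, "ASP", p, -1.0)
            for i, p in enumerate([
                np.array([10.0, 0, 0]), np.array([-10.0, 0, 0]),
                np.array([0, 10.0, 0]), np.array([0, -10.0, 0]),
            ])
        ])
        c0 = np.zeros(3)
        assert charge_anisotropy(clustered, c0)[0] > charge_anisotropy(dispersed, c0)[0]

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            charge_anisotropy(ChargeModel([]))
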