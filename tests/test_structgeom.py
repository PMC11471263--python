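import json
import math

import gemmi
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fabkit.errors import (ArgumentError, GeometryError,
                           InsufficientCorrespondenceError, ParseError)
from fabkit.structgeom import (Atom, ChainCoordinates, Residue, ch1_cl_angle,
                               contact_matrix, disulfide_bonds, elbow_angle,
                               hl_interface, pseudo_dyad_axis, read_structure,
                               sasa)

from oracles import brute_force_contacts, random_rigid_motion


def _labeled(coords):
    return {str(i + 1): np.asarray(c, dtype=float) for i, c in enumerate(coords)}


def _cloud(rng, n=20, scale=6.0):
    return rng.normal(scale=scale, size=(n, 3))


def _rotated(points, axis, angle_deg, translation=(0.0, 0.0, 0.0)):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(axis * math.radians(angle_deg))
    return rot.apply(points) + np.asarray(translation)


def _ca_chain(chain_id, coords, extra_atoms=None):
    residues = []
    for i, xyz in enumerate(coords, start=1):
        atoms = [Atom("CA", "C", tuple(float(v) for v in xyz))]
        residues.append(Residue(seqres_index=i, amino_acid="A", atoms=atoms))
    seq = "A" * len(coords)
    return ChainCoordinates(chain_id=chain_id, seqres_seq=seq, residues=residues)


class TestReadStructure:
    def test_unresolved_span_shortens_atom_seq(self, spec7, tmp_path):
        from fabkit.fixtures import FixtureSpec, make_structure_fixture
        spec = FixtureSpec(seed=7, unresolved_spans=[("H", 20, 24)])
        cif, truth = make_structure_fixture(spec, {"entry_id": "FXGAP"}, tmp_path)
        parsed = read_structure(cif)
        h = parsed.chains["H"]
        assert len(h.seqres_seq) - len(h.atom_seq) == 5
        assert h.resolved_mask[18] and not h.resolved_mask[19]

    def test_mmcif_pdb_round_trip(self, fab_structure, tmp_path):
        cif, _ = fab_structure
        a = read_structure(cif)
        st = gemmi.read_structure(str(cif))
        st.setup_entities()
        pdb_path = tmp_path / "copy.pdb"
        st.write_pdb(str(pdb_path))
        b = read_structure(pdb_path, format="pdb")
        assert set(a.chains) == set(b.chains)
        for cid in a.chains:
            ca, cb = a.chains[cid], b.chains[cid]
            assert ca.seqres_seq == cb.seqres_seq
            assert ca.atom_seq == cb.atom_seq
            for ra, rb in zip(ca.residues, cb.residues):
                assert np.allclose(ra.ca, rb.ca, atol=1e-3)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(ParseError):
            read_structure(tmp_path / "nope.cif")

    def test_garbage_file_rejected(self, tmp_path):
        p = tmp_path / "bad.cif"
        p.write_text("this is not a structure\n")
        with pytest.raises(ParseError):
            read_structure(p)

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        text = """data_ALT
_entry.id ALT
loop_
_entity.id
_entity.type
1 polymer
loop_
_entity_poly.entity_id
_entity_poly.type
_entity_poly.pdbx_strand_id
1 polypeptide(L) A
loop_
_entity_poly_seq.entity_id
_entity_poly_seq.num
_entity_poly_seq.mon_id
1 1 ALA
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C CA A ALA A 1 1 ? 1.000 0.000 0.000 0.40 0.00 1 A 1
ATOM 2 C CA B ALA A 1 1 ? 2.000 0.000 0.000 0.60 0.00 1 A 1
"""
        p = tmp_path / "alt.cif"
        p.write_text(text)
        parsed = read_structure(p)
        assert parsed.chains["A"].residues[0].ca[0] == pytest.approx(2.0)


class TestContactMatrix:
    def test_three_four_five_triangle(self):
        a = _labeled([(0.0, 0.0, 0.0)])
        b = _labeled([(3.0, 4.0, 0.0)])
        cm = contact_matrix(a, b, cutoff=8.0)
        assert cm.distances[0, 0] == pytest.approx(5.0)
        assert cm.contacts[0, 0]

    def test_self_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        d = _labeled(_cloud(rng, 10))
        cm = contact_matrix(d, d)
        assert np.allclose(np.diag(cm.distances), 0.0)
        assert np.allclose(cm.distances, cm.distances.T)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(23)
        a = _labeled(_cloud(rng, 30, scale=8.0))
        b = _labeled(_cloud(rng, 30, scale=8.0))
        cm = contact_matrix(a, b, cutoff=8.0)
        dists, contacts = brute_force_contacts(a, b, 8.0)
        for i, ra in enumerate(cm.row_labels):
            for j, rb in enumerate(cm.col_labels):
                assert cm.distances[i, j] == pytest.approx(dists[(ra, rb)])
        assert cm.contact_pairs() == contacts

    def test_extreme_cutoffs(self):
        rng = np.random.default_rng(1)
        a = _labeled(_cloud(rng, 8))
        b = _labeled(_cloud(rng, 8) + 30.0)
        assert np.all(contact_matrix(a, b, cutoff=np.inf).contacts)
        assert not contact_matrix(a, b, cutoff=1e-9).contacts.any()

    def test_unresolved_positions_give_nan_not_contact(self):
        a = _labeled([(0.0, 0.0, 0.0)])
        a["2"] = None
        b = _labeled([(1.0, 0.0, 0.0)])
        cm = contact_matrix(a, b)
        i = cm.row_labels.index("2")
        assert np.isnan(cm.distances[i, 0])
        assert not cm.contacts[i, 0]

    def test_no_resolved_ca_rejected(self):
        with pytest.raises(ArgumentError):
            contact_matrix({"1": None}, _labeled([(0, 0, 0)]))


class TestPseudoDyadAxis:
    def test_half_turn_about_z(self):
        rng = np.random.default_rng(2)
        p = _cloud(rng, 12)
        d1 = _labeled(p)
        d2 = _labeled(_rotated(p, (0, 0, 1), 180.0))
        res = pseudo_dyad_axis(d1, d2)
        assert res.angle_deg == pytest.approx(180.0, abs=1e-6)
        assert abs(res.axis @ np.array([0, 0, 1.0])) == pytest.approx(1.0, abs=1e-9)

    def test_translation_only_is_degenerate(self):
        rng = np.random.default_rng(3)
        p = _cloud(rng, 10)
        with pytest.raises(GeometryError, match="translation"):
            pseudo_dyad_axis(_labeled(p), _labeled(p + 5.0))

    def test_random_rotation_recovered(self):
        rng = np.random.default_rng(29)
        p = _cloud(rng, 25)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        d2 = _labeled(_rotated(p, axis, 147.0, translation=(7.0, -3.0, 2.0)))
        res = pseudo_dyad_axis(_labeled(p), d2)
        assert res.angle_deg == pytest.approx(147.0, abs=1e-6)
        assert abs(res.axis @ axis) == pytest.approx(1.0, abs=1e-6)

    def test_collinear_points_rejected(self):
        line = _labeled([(float(i), 0.0, 0.0) for i in range(5)])
        rot = _labeled(_rotated(np.array([[float(i), 0, 0] for i in range(5)]),
                                (0, 1, 0), 30.0))
        with pytest.raises(GeometryError, match="collinear"):
            pseudo_dyad_axis(line, rot)

    def test_too_few_shared_labels_rejected(self):
        with pytest.raises(InsufficientCorrespondenceError):
            pseudo_dyad_axis(_labeled([(0, 0, 0), (1, 0, 0)]),
                             _labeled([(0, 0, 0), (1, 0, 0)]))


class TestPackingAngles:
    def _fab(self, rng, elbow_deg, theta_v=160.0, theta_c=150.0, n=20):
        vh = _cloud(rng, n)
        vl = _rotated(vh, (0, 0, 1), theta_v, translation=(12, 0, 0))
        axis_c = (math.sin(math.radians(elbow_deg)), 0.0,
                  math.cos(math.radians(elbow_deg)))
        ch1 = _cloud(rng, n) + np.array([40.0, 0, 0])
        cl = _rotated(ch1 - ch1.mean(0), axis_c, theta_c) + ch1.mean(0) + 10.0
        return (_labeled(vh), _labeled(vl), _labeled(ch1), _labeled(cl))

    def test_right_angle_construction(self):
        rng = np.random.default_rng(4)
        vh, vl, ch1, cl = self._fab(rng, 90.0)
        assert elbow_angle(vh, vl, ch1, cl) == pytest.approx(90.0, abs=1e-6)

    def test_parallel_dyads_fold_convention(self):
        rng = np.random.default_rng(5)
        vh, vl, ch1, cl = self._fab(rng, 0.0)
        theta = elbow_angle(vh, vl, ch1, cl)
        assert min(theta, 180.0 - theta) == pytest.approx(0.0, abs=1e-6)

    def test_literature_convention_unfolds_acute_angles(self):
        rng = np.random.default_rng(6)
        vh, vl, ch1, cl = self._fab(rng, 60.0)
        raw = elbow_angle(vh, vl, ch1, cl, convention="raw")
        lit = elbow_angle(vh, vl, ch1, cl, convention="literature")
        assert raw == pytest.approx(60.0, abs=1e-6)
        assert lit == pytest.approx(300.0, abs=1e-6)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(31)
        vh, vl, ch1, cl = self._fab(rng, 117.0)
        base_elbow = elbow_angle(vh, vl, ch1, cl)
        base_c = ch1_cl_angle(ch1, cl)
        for _ in range(20):
            move = random_rigid_motion(rng)
            moved = [{k: move(v) for k, v in d.items()} for d in (vh, vl, ch1, cl)]
            assert elbow_angle(*moved) == pytest.approx(base_elbow, abs=1e-6)
            assert ch1_cl_angle(moved[2], moved[3]) == pytest.approx(base_c, abs=1e-6)

    def test_noise_robustness_half_degree(self):
        """0.1 A Gaussian coordinate noise moves both packing angles by
        less than half a degree at domain-sized point sets."""
        rng = np.random.default_rng(43)
        for _ in range(50):
            vh, vl, ch1, cl = self._fab(rng, 120.0, n=95)
            noisy = [{k: v + rng.normal(scale=0.1, size=3) for k, v in d.items()}
                     for d in (vh, vl, ch1, cl)]
            assert elbow_angle(*noisy) == pytest.approx(120.0, abs=0.5)
            assert ch1_cl_angle(noisy[2], noisy[3]) == pytest.approx(150.0, abs=0.5)

    def test_ch1_cl_angle_constructed(self):
        rng = np.random.default_rng(7)
        ch1 = _cloud(rng, 15)
        cl = _rotated(ch1, (1, 1, 0), 170.0, translation=(5, 5, 5))
        assert ch1_cl_angle(_labeled(ch1), _labeled(cl)) == pytest.approx(170.0, abs=1e-6)

    def test_identical_domains_degenerate(self):
        rng = np.random.default_rng(8)
        ch1 = _labeled(_cloud(rng, 15))
        with pytest.raises(GeometryError):
            ch1_cl_angle(ch1, dict(ch1))


class TestSasa:
    def test_isolated_carbon_matches_analytic_sphere(self):
        area = sasa([Atom("CA", "C", (0.0, 0.0, 0.0))])
        expected = 4 * math.pi * (1.70 + 1.4) ** 2
        assert area[0] == pytest.approx(expected, rel=0.01)

    def test_coincident_atoms_share_one_sphere(self):
        one = sasa([Atom("CA", "C", (0.0, 0.0, 0.0))]).sum()
        two = sasa([Atom("CA", "C", (0.0, 0.0, 0.0)),
                    Atom("CB", "C", (0.0, 0.0, 0.0))]).sum()
        assert two == pytest.approx(one, rel=0.01)

    def test_cluster_converges_to_high_resolution_oracle(self):
        rng = np.random.default_rng(41)
        atoms = [Atom("CA", "C", tuple(xyz)) for xyz in rng.normal(scale=2.0, size=(10, 3))]
        coarse = sasa(atoms, n_points=960).sum()
        fine = sasa(atoms, n_points=10000).sum()
        assert coarse == pytest.approx(fine, rel=0.02)

    def test_unknown_element_warns_and_defaults(self):
        with pytest.warns(UserWarning, match="van-der-Waals"):
            area = sasa([Atom("X1", "ZZ", (0.0, 0.0, 0.0))])
        assert area[0] == pytest.approx(4 * math.pi * (1.70 + 1.4) ** 2, rel=0.01)


class TestHLInterface:
    def _contact_pair(self, gap=40.0):
        # residues 1-5 of each chain face each other at 4.2 A; the rest sit
        # far away, giving a sharp contact/non-contact split
        h_coords = [(i * 3.8, 0.0, 0.0) for i in range(5)] + \
                   [(i * 3.8, gap, gap) for i in range(5, 10)]
        l_coords = [(i * 3.8, 4.2, 0.0) for i in range(5)] + \
                   [(i * 3.8, 4.2 - gap, gap) for i in range(5, 10)]
        return _ca_chain("H", h_coords), _ca_chain("L", l_coords)

    def test_separated_chains_have_no_interface(self):
        rng = np.random.default_rng(9)
        h = _ca_chain("H", _cloud(rng, 10))
        l = _ca_chain("L", _cloud(rng, 10) + 100.0)
        ann = hl_interface(h, l)
        assert ann.interface_residues == []
        assert ann.buried_area == pytest.approx(0.0, abs=1e-6)

    def test_interface_set_matches_distance_oracle(self):
        h, l = self._contact_pair()
        ann = hl_interface(h, l)
        oracle = set()
        for ch, other in ((h, l), (l, h)):
            for res in ch.residues:
                for partner in other.residues:
                    if np.linalg.norm(res.ca - partner.ca) <= 5.0:
                        oracle.add((ch.chain_id, res.seqres_index))
        assert set(ann.interface_residues) == oracle

    def test_delta_sasa_nonnegative_within_tolerance(self):
        h, l = self._contact_pair()
        ann = hl_interface(h, l)
        assert all(v >= -1e-6 for v in ann.delta_sasa.values())

    def test_buried_area_decreases_with_separation(self):
        h, l = self._contact_pair()
        areas = []
        for step in range(5):
            shifted = _ca_chain("L", [np.asarray(r.ca) + np.array([0.0, 0.4 * step, 0.0])
                                      for r in l.residues])
            areas.append(hl_interface(h, shifted).buried_area)
        assert all(a > b for a, b in zip(areas, areas[1:]))


class TestDisulfideBonds:
    def _structure(self, sg_positions, chain_ids=None):
        from fabkit.structgeom import ParsedStructure
        chains = {}
        chain_ids = chain_ids or ["A"] * len(sg_positions)
        for i, (cid, xyz) in enumerate(zip(chain_ids, sg_positions)):
            res = Residue(seqres_index=i + 1, amino_acid="C",
                          atoms=[Atom("CA", "C", (float(i) * 10, 50.0, 0.0)),
                                 Atom("SG", "S", tuple(map(float, xyz)))])
            if cid not in chains:
                chains[cid] = ChainCoordinates(cid, "", [])
            chains[cid].residues.append(res)
        for c in chains.values():
            c.seqres_seq = "C" * len(c.residues)
        return ParsedStructure(entry_id="DS", chains=chains)

    def test_canonical_bond_found(self):
        st = self._structure([(0, 0, 0), (2.05, 0, 0)])
        bonds = disulfide_bonds(st)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.05)
        assert bonds[0].kind == "intra"

    def test_long_separation_is_not_a_bond(self):
        assert disulfide_bonds(self._structure([(0, 0, 0), (3.5, 0, 0)])) == []

    def test_fixture_layout_found_with_types(self, fab_structure):
        cif, truth_path = fab_structure
        truth = json.loads(open(truth_path).read())
        parsed = read_structure(cif)
        bonds = disulfide_bonds(parsed)
        expected = {(b["chain_a"], b["res_a"], b["chain_b"], b["res_b"], b["kind"])
                    for b in truth["disulfides"]}
        got = {(b.chain_a, b.res_a, b.chain_b, b.res_b, b.kind) for b in bonds}
        assert got == expected
        assert sorted(b.kind for b in bonds) == ["inter", "intra", "intra"]

    def test_rigid_motion_preserves_contacts_and_disulfides(self, fab_structure):
        cif, _ = fab_structure
        parsed = read_structure(cif)
        base = {(b.chain_a, b.res_a, b.chain_b, b.res_b) for b in disulfide_bonds(parsed)}
        rng = np.random.default_rng(37)
        move = random_rigid_motion(rng)
        for chain in parsed.chains.values():
            for res in chain.residues:
                res.atoms = [Atom(a.name, a.element, tuple(move(np.array(a.xyz))))
                             for a in res.atoms]
        moved = {(b.chain_a, b.res_a, b.chain_b, b.res_b) for b in disulfide_bonds(parsed)}
        assert moved == base
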