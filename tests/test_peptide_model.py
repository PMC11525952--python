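import math

import numpy as np
import pytest

from oligoconf.massspec import PHE2_FORMULA, IonFormula
from oligoconf.peptide_model import (
    GeometricCriteria,
    OligomerSpec,
    ProtonationState,
    ResidueTemplate,
    build_oligomer,
    find_hbonds,
    find_pion_contacts,
    has_free_OH,
    initial_conformation,
    peptide_smiles,
    template_from_mol,
    uv_constraint_filter,
)
from oligoconf.synthetic import hbond_toy, pion_toy

from conftest import random_rigid_motion


class TestProtonationState:
    def test_pn_definition(self):
        st = ProtonationState(("protonated", "neutral"))
        assert st.net_charge == 1
        assert st.kind == "pn"

    def test_pz_definition(self):
        st = ProtonationState(("protonated", "zwitterion"))
        assert st.net_charge == 1
        assert st.kind == "pz"

    def test_zwitterion_contributes_zero(self):
        assert ProtonationState(("zwitterion",)).net_charge == 0

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            ProtonationState(("acidic",))


class TestOligomerSpec:
    def test_inconsistent_charge_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            OligomerSpec(2, 2, ProtonationState(("protonated", "neutral")))

    def test_label_count_enforced(self):
        with pytest.raises(ValueError):
            OligomerSpec(3, 1, ProtonationState(("protonated",)))


class TestBuildOligomer:
    def test_protonated_monomer_formula(self):
        spec = OligomerSpec(1, 1, ProtonationState(("protonated",)))
        topo = build_oligomer(spec)
        assert topo.formula == {"C": 18, "H": 21, "N": 2, "O": 3}

    def test_neutral_unit_formula_is_phe2(self):
        spec = OligomerSpec(1, 0, ProtonationState(("neutral",)))
        topo = build_oligomer(spec)
        assert topo.formula == PHE2_FORMULA

    def test_zwitterion_unit_formula_matches_neutral(self):
        spec = OligomerSpec(1, 0, ProtonationState(("zwitterion",)))
        assert build_oligomer(spec).formula == PHE2_FORMULA

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_nmer_formula_arithmetic(self, n):
        # built formula equals n x monomer + z protons (z extra H on unit 0)
        labels = ("protonated",) + ("neutral",) * (n - 1)
        topo = build_oligomer(OligomerSpec(n, 1, ProtonationState(labels)))
        expected = {el: n * c for el, c in PHE2_FORMULA.items()}
        expected["H"] += 1
        assert topo.formula == expected

    def test_large_series_formula_arithmetic(self):
        # mass-formula layer covers the full peak series n=1..13
        for n in range(1, 14):
            f = IonFormula.oligomer(PHE2_FORMULA, n, 2)
            assert f.elements["C"] == 18 * n

    def test_unknown_residue(self):
        with pytest.raises(KeyError, match="Xyz"):
            peptide_smiles(["Xyz"], {"Phe": "Cc1ccccc1"})

    def test_initial_geometry_valid(self, dimer_pn_conf):
        assert dimer_pn_conf.is_valid()

    def test_charged_site_is_n_terminus(self, dimer_pn_topology):
        assert len(dimer_pn_topology.charged_sites) == 1
        site = dimer_pn_topology.charged_sites[0]
        assert dimer_pn_topology.elements[site] == "N"
        assert dimer_pn_topology.unit_of[site] == 0

    def test_rings_and_torsions_present(self, dimer_pn_topology):
        assert len(dimer_pn_topology.rings) == 4  # two Phe rings per unit
        assert len(dimer_pn_topology.torsions) >= 16


class TestResidueTemplate:
    def test_disconnected_graph_rejected(self):
        t = ResidueTemplate(
            "bad",
            atoms=[("C", np.zeros(3)), ("C", np.ones(3))],
            bonds=[],
        )
        with pytest.raises(ValueError, match="connected"):
            t.validate()

    def test_small_ring_rejected(self):
        t = ResidueTemplate(
            "bad",
            atoms=[("C", np.zeros(3)), ("C", np.ones(3))],
            bonds=[(0, 1, 1)],
            ring_atoms=[[0, 1]],
        )
        with pytest.raises(ValueError, match="ring"):
            t.validate()

    def test_from_mol(self):
        from rdkit import Chem

        tmpl = template_from_mol(
            Chem.MolFromSmiles("NC(Cc1ccccc1)C(=O)O"), "Phe"
        )
        assert tmpl.name == "Phe"
        assert len(tmpl.ring_atoms) == 1
        assert len(tmpl.ring_atoms[0]) == 6


class TestHbonds:
    def test_linear_hbond_detected(self):
        conf = hbond_toy(da_distance=2.9, dha_angle=175.0)
        assert find_hbonds(conf) == [(0, 1, 2)]

    def test_stretched_not_detected(self):
        conf = hbond_toy(da_distance=5.0, dha_angle=175.0)
        assert find_hbonds(conf) == []

    def test_angle_boundary_matches_criterion(self):
        # brute-force scan: detection flips exactly at the configured angle
        crit = GeometricCriteria(hbond_min_DHA_angle=120.0)
        for ang in np.arange(90.0, 180.0, 2.5):
            conf = hbond_toy(da_distance=2.9, dha_angle=float(ang))
            detected = bool(find_hbonds(conf, crit))
            assert detected == (ang >= 120.0), f"angle {ang}"

    def test_distance_boundary(self):
        crit = GeometricCriteria(hbond_max_DA_distance=3.5)
        for d in np.round(np.arange(2.5, 4.5, 0.1), 6):
            conf = hbond_toy(da_distance=float(d), dha_angle=175.0)
            assert bool(find_hbonds(conf, crit)) == (d <= 3.5)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        conf = hbond_toy(2.9, 160.0)
        base = find_hbonds(conf)
        for _ in range(5):
            moved = hbond_toy(2.9, 160.0)
            moved.coords = random_rigid_motion(conf.coords, rng)
            assert find_hbonds(moved) == base


class TestPiContacts:
    def test_contact_at_4p8(self):
        conf = pion_toy(distance=4.8, same_residue=False)
        contacts = find_pion_contacts(conf)
        assert len(contacts) == 1
        site, ring_id, dist, same = contacts[0]
        assert dist == pytest.approx(4.8, abs=1e-9)
        assert same is False

    def test_beyond_cutoff_empty(self):
        assert find_pion_contacts(pion_toy(distance=8.0)) == []

    def test_same_residue_flag(self):
        contacts = find_pion_contacts(pion_toy(distance=3.0, same_residue=True))
        assert contacts[0][3] is True

    def test_equidistant_tie_broken_by_ring_id(self):
        conf = pion_toy(distance=4.0, n_rings=2)
        # move N equidistant between the two ring centroids
        c0 = conf.coords[conf.topology.rings[0]].mean(axis=0)
        c1 = conf.coords[conf.topology.rings[1]].mean(axis=0)
        mid = (c0 + c1) / 2.0
        conf.coords[-1] = mid + np.array([0.0, 0.0, 1.0])
        contacts = find_pion_contacts(
            conf, GeometricCriteria(pion_max_centroid_distance=15.0)
        )
        assert len(contacts) == 2
        assert contacts[0][1] == 0 and contacts[1][1] == 1

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        conf = pion_toy(4.8)
        base = find_pion_contacts(conf)
        for _ in range(5):
            moved = pion_toy(4.8)
            moved.coords = random_rigid_motion(conf.coords, rng)
            got = find_pion_contacts(moved)
            assert [(s, r, same) for s, r, _d, same in got] == [
                (s, r, same) for s, r, _d, same in base
            ]
            assert got[0][2] == pytest.approx(base[0][2], abs=1e-9)


class TestFreeOH:
    def test_oh_pointing_away_is_free(self):
        conf = hbond_toy(da_distance=6.0, dha_angle=175.0)
        conf.topology.elements[0] = "O"  # make the donor a hydroxyl oxygen
        assert has_free_OH(conf) is True

    def test_donated_oh_not_free(self):
        conf = hbond_toy(da_distance=2.8, dha_angle=170.0)
        conf.topology.elements[0] = "O"
        assert has_free_OH(conf) is False

    def test_no_oh_errors(self):
        conf = pion_toy(4.0)
        with pytest.raises(ValueError, match="OH"):
            has_free_OH(conf)

    def test_zwitterion_unit_other_oh_free(self, dimer_pn_conf):
        # built pn dimer: both carboxyl OH groups exist; in the spread-out
        # seed geometry no OH donates, so a free OH is present
        assert has_free_OH(dimer_pn_conf) is True


class TestUvFilter:
    def test_monomer_pass(self):
        conf = pion_toy(distance=4.0, same_residue=False)
        passed, failed = uv_constraint_filter([conf], "monomer")
        assert passed == [conf] and failed == []

    def test_dimer_same_residue_fails(self):
        conf = pion_toy(distance=3.0, same_residue=True)
        passed, failed = uv_constraint_filter([conf], "dimer")
        assert passed == [] and failed == [conf]

    def test_dimer_other_residue_passes(self):
        conf = pion_toy(distance=4.8, same_residue=False)
        passed, _ = uv_constraint_filter([conf], "dimer")
        assert passed == [conf]

    def test_empty_input(self):
        assert uv_constraint_filter([], "monomer") == ([], [])

    def test_partition_exact(self):
        rng = np.random.default_rng(5)
        confs = [
            pion_toy(distance=float(d), same_residue=bool(s))
            for d, s in zip(rng.uniform(2, 9, 12), rng.integers(0, 2, 12))
        ]
        passed, failed = uv_constraint_filter(confs, "dimer")
        assert len(passed) + len(failed) == len(confs)
        assert {id(c) for c in passed} | {id(c) for c in failed} == {
            id(c) for c in confs
        }

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            uv_constraint_filter([], "trimer")


def test_criteria_validation():
    with pytest.raises(ValueError):
        GeometricCriteria(hbond_max_DA_distance=-1.0)
    with pytest.raises(ValueError):
        GeometricCriteria(hbond_min_DHA_angle=200.0)
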