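import math

import numpy as np
import pytest

from prostab.errors import ConfigurationError
from prostab.filters import (FilterConfig, HBond, apply_filter_battery,
                             assign_secondary_structure, compute_sasa,
                             detect_hbonds, evaluate_mutation_filters,
                             relative_sasa, summarize_verdicts)
from prostab.structures import (Atom, Mutation, ProteinStructure, Residue,
                                min_heavy_atom_distance)
from prostab.synthetic import make_cage_fixture, make_ideal_helix

CARBON_SPHERE = 4 * math.pi * 3.1 ** 2          # r 1.70 + probe 1.4


def _carbon(name, coord):
    return Atom(name, "C", coord)


def _single_atom_structure(coords):
    res = Residue("A", 1, "UNK", [_carbon(f"X{i}", c) for i, c in enumerate(coords)])
    return ProteinStructure(residues=[res])


class TestSasa:
    def test_isolated_carbon_is_analytic_sphere(self):
        s = _single_atom_structure([[0.0, 0.0, 0.0]])
        sasa = compute_sasa(s)
        area = sasa.per_atom[("A", 1, "", "X0")]
        assert area == pytest.approx(CARBON_SPHERE, rel=0.01)

    def test_two_distant_carbons_unoccluded(self):
        s = _single_atom_structure([[0, 0, 0], [6.5, 0, 0]])
        sasa = compute_sasa(s)
        for area in sasa.per_atom.values():
            assert area == pytest.approx(CARBON_SPHERE, rel=0.01)

    def test_cage_center_fully_buried(self):
        cage = make_cage_fixture()
        for n in (960, 10000):
            sasa = compute_sasa(cage, n_points=n)
            assert sasa.residue_area(("A", 1)) == 0.0

    def test_shell_atoms_keep_outward_area(self):
        sasa = compute_sasa(make_cage_fixture())
        shell = [v for k, v in sasa.per_atom.items() if k[1] == 2]
        assert all(a > 10.0 for a in shell)

    def test_removing_one_shell_atom_opens_hole(self):
        cage = make_cage_fixture()
        cage.residues[1].atoms.pop(0)
        sasa = compute_sasa(cage)
        assert sasa.residue_area(("A", 1)) > 0.0

    def test_sparse_matches_dense_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            coords = rng.uniform(0, 4.0, size=(5, 3))
            s = _single_atom_structure(list(coords))
            a = compute_sasa(s, n_points=960).per_atom
            b = compute_sasa(s, n_points=10000).per_atom
            for k in a:
                assert abs(a[k] - b[k]) <= 0.03 * CARBON_SPHERE

    def test_total_sasa_rigid_invariant(self, design_region):
        from scipy.spatial.transform import Rotation
        s1 = design_region
        s2 = design_region.copy()
        rot = Rotation.from_euler("xyz", [31, -57, 112], degrees=True).as_matrix()
        for res in s2.residues:
            for a in res.atoms:
                a.coord = rot @ a.coord + np.array([5.0, -3.0, 8.0])
        r1 = compute_sasa(s1).per_residue
        r2 = compute_sasa(s2).per_residue
        for key in r1:
            assert r2[key] == pytest.approx(r1[key], rel=0.03, abs=1.0)

    def test_cross_check_against_independent_implementation(self, tmp_path):
        # Bio.PDB ships its own Shrake–Rupley; agree on a small cluster
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley
        from prostab.structures import write_model
        s = make_ideal_helix(8, "ADKLNQST")
        p = tmp_path / "helix.pdb"
        write_model(s, p)
        ours = compute_sasa(s, n_points=960)
        bio = PDBParser(QUIET=True).get_structure("x", str(p))
        ShrakeRupley(probe_radius=1.4, n_points=960).compute(bio, level="R")
        for res in bio.get_residues():
            key = ("A", res.id[1], "")
            assert ours.per_residue[key] == pytest.approx(res.sasa, rel=0.15, abs=5.0)


class TestRelativeSasa:
    def test_exposed_central_ala_near_reference_maximum(self):
        # Gly-Ala-Gly-Gly in extended conformation ~ the reference context
        s = make_ideal_helix(4, "GAGG", phi=-139.0, psi=135.0)
        rel = relative_sasa(s, compute_sasa(s))
        assert rel[("A", 2, "")] == pytest.approx(1.0, abs=0.15)

    def test_caged_residue_is_zero(self):
        cage = make_cage_fixture()
        rel = relative_sasa(cage, compute_sasa(cage))
        assert rel[("A", 1, "")] == 0.0

    def test_unknown_residue_type_is_configuration_error(self):
        res = Residue("A", 1, "XYZ", [_carbon("CA", [0, 0, 0])])
        s = ProteinStructure(residues=[res])
        with pytest.raises(ConfigurationError):
            relative_sasa(s, compute_sasa(s))


class TestHBonds:
    def _pair(self, d, with_side=False):
        donor = Residue("A", 1, "GLY", [
            Atom("N", "N", [0.0, 0.0, 0.0]),
            Atom("CA", "C", [-1.2, -0.9, 0.0]),
            Atom("C", "C", [-2.5, 0.0, 0.0]),
        ])
        acceptor = Residue("A", 5, "GLY", [
            Atom("CA", "C", [d + 1.0, 1.0, 0.0]),
            Atom("O", "O", [d, 0.0, 0.0]),
            Atom("N", "N", [d + 2.0, 2.0, 0.0]),
        ])
        return ProteinStructure(residues=[donor, acceptor])

    def test_good_geometry_detected(self):
        s = self._pair(2.9)
        bonds = detect_hbonds(s)
        assert len(bonds) == 1
        hb = bonds[0]
        assert hb.donor[3] == "N" and hb.acceptor[3] == "O"
        assert hb.distance == pytest.approx(2.9)
        assert hb.angle >= 120.0

    def test_too_far_not_detected(self):
        assert detect_hbonds(self._pair(4.0)) == []

    def test_helix_backbone_bonds_present(self, demo_helix):
        bonds = detect_hbonds(demo_helix)
        pairs = {(hb.donor[1], hb.acceptor[1]) for hb in bonds
                 if hb.donor[3] == "N" and hb.acceptor[3] == "O"}
        interior = [(i, i - 4) for i in range(10, 60)]
        assert sum(p in pairs for p in interior) >= 40

    def test_oracle_distances_on_helix(self, demo_helix):
        # every reported bond satisfies both criteria when recomputed directly
        bonds = detect_hbonds(demo_helix, d_max=3.5, angle_min=120.0)
        assert bonds
        for hb in bonds:
            d_res = demo_helix.get_residue(hb.donor[:3])
            a_res = demo_helix.get_residue(hb.acceptor[:3])
            d = np.linalg.norm(d_res.atom(hb.donor[3]).coord
                               - a_res.atom(hb.acceptor[3]).coord)
            assert d == pytest.approx(hb.distance) and d <= 3.5


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_h(self):
        s = make_ideal_helix(10)
        labels = assign_secondary_structure(s)
        inner = [labels[("A", i, "")] for i in range(2, 10)]
        assert set(inner) == {"H"}
        assert labels[("A", 1, "")] == "L" and labels[("A", 10, "")] == "L"

    def test_short_fragment_is_all_loop(self):
        s = make_ideal_helix(4)
        # only 2 interior residues: the ≥4 helix run cannot be met
        labels = assign_secondary_structure(s)
        assert set(labels.values()) == {"L"}

    def test_non_helical_dihedrals_are_loop(self):
        s = make_ideal_helix(10, phi=-57.0, psi=100.0)
        labels = assign_secondary_structure(s)
        assert set(labels.values()) == {"L"}

    def test_extended_strand_labelled_e(self):
        s = make_ideal_helix(8, phi=-139.0, psi=135.0)
        labels = assign_secondary_structure(s)
        assert "E" in set(labels.values())


class TestRules:
    """Rule-level checks with hand-built precomputed artifacts."""

    @pytest.fixture()
    def helix_env(self, design_region):
        sasa = compute_sasa(design_region)
        return {
            "rel": relative_sasa(design_region, sasa),
            "ss": assign_secondary_structure(design_region),
            "hbonds": detect_hbonds(design_region),
        }

    def _config(self, **kw):
        base = dict(catalytic_residues=["A:30", "A:45"])
        base.update(kw)
        return FilterConfig(**base)

    def test_active_site_radius_excludes_close_positions(self, design_region, helix_env):
        config = self._config()
        near = Mutation("A", 28, "Q", "K")     # two residues from His30
        far = Mutation("A", 14, "G", "K")
        assert min_heavy_atom_distance(design_region, ("A", 28), ("A", 30)) <= 5.0
        v_near = evaluate_mutation_filters(design_region, near, config, **_env(helix_env))
        v_far = evaluate_mutation_filters(design_region, far, config, **_env(helix_env))
        assert not v_near.rule_results["R1_active_site"][0]
        assert v_far.rule_results["R1_active_site"][0]

    def test_empty_catalytic_list_is_configuration_error(self, design_region, helix_env):
        config = FilterConfig(catalytic_residues=[])
        with pytest.raises(ConfigurationError):
            evaluate_mutation_filters(design_region, Mutation("A", 14, "G", "K"),
                                      config, **_env(helix_env))

    def test_proline_into_helix_fails_r5(self, design_region, helix_env):
        v = evaluate_mutation_filters(design_region, Mutation("A", 20, "A", "P"),
                                      self._config(), **_env(helix_env))
        assert not v.rule_results["R5_proline_in_helix"][0]

    def test_glycine_into_loop_fails_r4(self, design_region, helix_env):
        # the chain terminus is a loop position
        last = design_region.polymer_residues("A")[-1]
        mut = Mutation("A", last.seq_number, last.one_letter, "G")
        v = evaluate_mutation_filters(design_region, mut, self._config(),
                                      **_env(helix_env))
        assert not v.rule_results["R4_loop_flexibility"][0]

    def test_exposed_hydrophobic_fails_r3(self, design_region, helix_env):
        v = evaluate_mutation_filters(design_region, Mutation("A", 14, "G", "L"),
                                      self._config(), **_env(helix_env))
        assert not v.rule_results["R3_exposed_hydrophobic"][0]

    def test_buried_large_to_small_fails_r6(self, design_region, helix_env):
        # force burial at the position and check the Zamyatnin volume rule
        env = _env(helix_env)
        env["rel_sasa"] = dict(env["rel_sasa"])
        env["rel_sasa"][("A", 21, "")] = 0.05
        v = evaluate_mutation_filters(design_region, Mutation("A", 21, "A", "G"),
                                      self._config(volume_loss_threshold=20.0), **env)
        assert not v.rule_results["R6_cavity_creation"][0]
        # L -> A loses 166.7 - 88.6 = 78.1 Å^3 > 40
        env["rel_sasa"][("A", 21, "")] = 0.05
        mut = Mutation("A", 21, "A", "S")       # small volume change passes
        v2 = evaluate_mutation_filters(design_region, mut, self._config(), **env)
        assert v2.rule_results["R6_cavity_creation"][0]

    def test_unsatisfied_hbond_fails_r2(self, design_region, helix_env):
        env = _env(helix_env)
        env["hbonds"] = list(env["hbonds"]) + [
            HBond(donor=("A", 22, "", "OG"), acceptor=("A", 18, "", "O"),
                  distance=2.8, angle=150.0)]
        # wild-type Ser donates via its side chain; Ala cannot
        v = evaluate_mutation_filters(design_region, Mutation("A", 22, "S", "A"),
                                      self._config(exposure_threshold=1.3), **env)
        assert not v.rule_results["R2_unsatisfied_hbond"][0]
        # Thr keeps a donor: passes
        v2 = evaluate_mutation_filters(design_region, Mutation("A", 22, "S", "T"),
                                       self._config(), **env)
        assert v2.rule_results["R2_unsatisfied_hbond"][0]


def _env(helix_env):
    return {"rel_sasa": helix_env["rel"], "ss": helix_env["ss"],
            "hbonds": helix_env["hbonds"]}


BATTERY_CANDIDATES = [
    Mutation("A", 14, "G", "K"),   # clean: survives
    Mutation("A", 29, "S", "K"),   # adjacent to His30: R1
    Mutation("A", 44, "D", "Q"),   # adjacent to Asp45: R1
    Mutation("A", 18, "G", "L"),   # exposed hydrophobic: R3
    Mutation("A", 20, "A", "P"),   # proline into helix: R5
    Mutation("A", 71, "A", "G"),   # glycine into terminal loop: R4
    Mutation("A", 52, "G", "E"),   # clean: survives
    Mutation("A", 23, "G", "W"),   # exposed hydrophobic: R3
    Mutation("A", 64, "G", "Q"),   # clean: survives
    Mutation("A", 58, "G", "R"),   # clean: survives
]


class TestBattery:
    def _oracle(self, structure, config):
        """Independent rule-by-rule reimplementation on the fixture."""
        from prostab.tables import HYDROPHOBIC, VOLUMES
        sasa = compute_sasa(structure)
        rel = relative_sasa(structure, sasa)
        ss = assign_secondary_structure(structure)
        hbonds = detect_hbonds(structure)
        survivors = []
        for m in BATTERY_CANDIDATES:
            key = (m.chain_id, m.position, "")
            r1 = all(min_heavy_atom_distance(structure, key, c) > config.active_site_radius
                     for c in config.catalytic_keys())
            from prostab.filters import sidechain_hbond_roles
            from prostab.tables import SIDECHAIN_ACCEPTORS, SIDECHAIN_DONORS
            don, acc = sidechain_hbond_roles(hbonds, key)
            r2 = not ((don and not SIDECHAIN_DONORS.get(m.mut_aa))
                      or (acc and not SIDECHAIN_ACCEPTORS.get(m.mut_aa)))
            r3 = not (m.mut_aa in HYDROPHOBIC and rel[key] > config.exposure_threshold)
            r4 = not (ss[key] == "L" and (m.mut_aa == "G" or m.wt_aa == "P"))
            r5 = not (m.mut_aa == "P" and ss[key] == "H")
            r6 = not (rel[key] < config.burial_threshold
                      and VOLUMES[m.wt_aa] - VOLUMES[m.mut_aa] > config.volume_loss_threshold)
            if all((r1, r2, r3, r4, r5, r6)):
                survivors.append(m)
        return survivors

    def test_survivors_match_rule_by_rule_oracle(self, demo_helix):
        config = FilterConfig(catalytic_residues=["A:30", "A:45"])
        survivors, verdicts = apply_filter_battery(BATTERY_CANDIDATES, demo_helix, config)
        assert survivors == self._oracle(demo_helix, config)
        assert {m.label for m in survivors} == {"G14K", "G52E", "G64Q", "G58R"}
        summary = summarize_verdicts(verdicts)
        assert summary["R1_active_site"] == 2
        assert summary["R3_exposed_hydrophobic"] == 2
        assert summary["R5_proline_in_helix"] == 1
        assert summary["R4_loop_flexibility"] == 1

    def test_battery_is_order_independent(self, demo_helix):
        config = FilterConfig(catalytic_residues=["A:30", "A:45"])
        fwd, _ = apply_filter_battery(BATTERY_CANDIDATES, demo_helix, config)
        rev, _ = apply_filter_battery(BATTERY_CANDIDATES[::-1], demo_helix, config)
        assert set(m.label for m in fwd) == set(m.label for m in rev)

    @pytest.mark.parametrize("update", [
        {"active_site_radius": 6.0},
        {"exposure_threshold": 0.15},
        {"burial_threshold": 0.30},
    ])
    def test_tightening_thresholds_never_adds_survivors(self, demo_helix, update):
        base = FilterConfig(catalytic_residues=["A:30", "A:45"])
        tight = FilterConfig(catalytic_residues=["A:30", "A:45"], **update)
        loose_set, _ = apply_filter_battery(BATTERY_CANDIDATES, demo_helix, base)
        tight_set, _ = apply_filter_battery(BATTERY_CANDIDATES, demo_helix, tight)
        assert {m.label for m in tight_set} <= {m.label for m in loose_set}

    def test_single_r5_violation_reported(self, demo_helix):
        config = FilterConfig(catalytic_residues=["A:30", "A:45"])
        survivors, verdicts = apply_filter_battery(
            [Mutation("A", 20, "A", "P")], demo_helix, config)
        assert survivors == []
        assert summarize_verdicts(verdicts)["R5_proline_in_helix"] == 1
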