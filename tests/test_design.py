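import numpy as np
import pytest

from prostab.design import (DesignConfig, anneal_states, generate_variants,
                            pack_rotamers, relax_model)
from prostab.energy import total_energy
from prostab.errors import ConfigurationError
from prostab.stability import DdgRecord
from prostab.structures import Mutation
from prostab.synthetic import make_ideal_helix, make_packing_instance


class TestAnneal:
    @pytest.mark.parametrize("seed", range(30))
    def test_reaches_enumeration_optimum(self, seed):
        rng = np.random.default_rng(1000 + seed)
        npos = int(rng.integers(1, 4))
        nstates = int(rng.integers(1, 6))
        inst = make_packing_instance(npos, nstates, seed=seed)
        state, energy = anneal_states(inst.self_energies, inst.pair_energies,
                                      steps=2000, kt_start=5.0, kt_end=0.3,
                                      rng=np.random.default_rng(seed))
        assert energy == pytest.approx(inst.best_energy, abs=1e-9)

    def test_best_visited_monotone_in_steps(self):
        inst = make_packing_instance(3, 5, seed=42)
        energies = []
        for steps in (0, 50, 200, 1000):
            _, e = anneal_states(inst.self_energies, inst.pair_energies,
                                 steps=steps, kt_start=5.0, kt_end=0.3,
                                 rng=np.random.default_rng(7))
            energies.append(e)
        assert energies == sorted(energies, reverse=True)

    def test_deterministic_for_fixed_seed(self):
        inst = make_packing_instance(3, 4, seed=5)
        runs = [anneal_states(inst.self_energies, inst.pair_energies, 500,
                              5.0, 0.3, np.random.default_rng(9))
                for _ in range(2)]
        assert runs[0] == runs[1]


class TestTotalEnergy:
    def test_two_distant_nonpolar_residues_score_zero(self, energy_model):
        from prostab.structures import Atom, ProteinStructure, Residue
        model = energy_model.__class__(reference_energies={},
                                       hbond_energy=energy_model.hbond_energy)
        s = ProteinStructure(residues=[
            Residue("A", 1, "GLY", [Atom("CA", "C", [0, 0, 0])]),
            Residue("A", 2, "GLY", [Atom("CA", "C", [20.0, 0, 0])]),
        ])
        assert total_energy(s, model) == 0.0

    def test_clash_term_value(self, energy_model):
        from prostab.structures import Atom, ProteinStructure, Residue
        model = energy_model.__class__(reference_energies={})
        s = ProteinStructure(residues=[
            Residue("A", 1, "GLY", [Atom("CA", "C", [0, 0, 0])]),
            Residue("A", 5, "GLY", [Atom("CA", "C", [2.0, 0, 0])]),
        ])
        # overlap = 1.70 + 1.70 - 2.0 = 1.4; no other term contributes
        assert total_energy(s, model) == pytest.approx(model.clash_weight * 1.4 ** 2)

    def test_hydrophobic_contact_lowers_energy_by_weight(self, energy_model):
        from prostab.structures import Atom, ProteinStructure, Residue
        model = energy_model.__class__(reference_energies={})
        def leu(num, x):
            return Residue("A", num, "LEU", [Atom("CA", "C", [x, 0, 0]),
                                             Atom("CB", "C", [x, 1.5, 0])])
        near = ProteinStructure(residues=[leu(1, 0.0), leu(5, 7.0)])
        far = ProteinStructure(residues=[leu(1, 0.0), leu(5, 19.0)])
        assert (total_energy(far, model) - total_energy(near, model)
                == pytest.approx(model.contact_weight))


class TestPackRotamers:
    def test_forced_two_state_optimum(self, design_region, energy_model, rotlib):
        # at a planted glycine, Lys (ref 0.26) beats Gly (ref 1.00)
        v = pack_rotamers(design_region, [("A", 14)], {("A", 14): {"K"}},
                          energy_model, rotlib, (5.0, 0.3, 300), seed=1)
        assert [m.label for m in v.mutations] == ["G14K"]

    def test_matches_exhaustive_enumeration(self, design_region, energy_model, rotlib):
        """Packing result equals brute force over the full joint state space."""
        import itertools
        from prostab.design import _build_state_tables
        keys = [("A", 14, ""), ("A", 18, "")]
        allowed = {("A", 14, ""): {"K", "E"}, ("A", 18, ""): {"Q"}}
        keys_n = [design_region.get_residue(k).key for k in keys]
        states, self_e, pair_e = _build_state_tables(
            design_region, keys_n, allowed, energy_model, rotlib)
        best = min(itertools.product(*[range(len(s)) for s in states]),
                   key=lambda combo: (
                       sum(self_e[i][c] for i, c in enumerate(combo))
                       + sum(pair_e.get((i, j), np.zeros((1, 1)))[combo[i], combo[j]]
                             if (i, j) in pair_e else 0.0
                             for i in range(len(combo)) for j in range(i + 1, len(combo)))))
        v = pack_rotamers(design_region, keys, allowed, energy_model, rotlib,
                          (5.0, 0.3, 1000), seed=2)
        expected = [states[i][best[i]][0] for i in range(2)]
        got = [v.structure.get_residue(k).one_letter for k in keys]
        assert got == expected

    def test_reported_energy_matches_full_recomputation(self, design_region,
                                                        energy_model, rotlib):
        v = pack_rotamers(design_region, [("A", 14), ("A", 52)],
                          {("A", 14): {"K"}, ("A", 52): {"E"}},
                          energy_model, rotlib, (5.0, 0.3, 300), seed=3)
        assert v.total_energy == pytest.approx(
            total_energy(v.structure, energy_model), abs=1e-9)

    def test_empty_designable_set_returns_identity(self, design_region,
                                                   energy_model, rotlib):
        with pytest.warns(UserWarning, match="empty designable"):
            v = pack_rotamers(design_region, [], {}, energy_model, rotlib)
        assert v.mutations == []
        assert v.sequence == "".join(
            r.one_letter for r in design_region.polymer_residues())


class TestRelax:
    def _variant(self, design_region, energy_model, rotlib, seed=4):
        return pack_rotamers(design_region, [("A", 14)], {("A", 14): {"K"}},
                             energy_model, rotlib, (5.0, 0.3, 200), seed=seed)

    def test_zero_steps_is_identity(self, design_region, energy_model, rotlib):
        v = self._variant(design_region, energy_model, rotlib)
        r = relax_model(v, energy_model, steps=0, seed=1)
        assert r.total_energy == v.total_energy
        for res, res2 in zip(v.structure.residues, r.structure.residues):
            for a, a2 in zip(res.atoms, res2.atoms):
                np.testing.assert_array_equal(a.coord, a2.coord)

    def test_energy_never_increases(self, design_region, energy_model, rotlib):
        v = self._variant(design_region, energy_model, rotlib)
        r = relax_model(v, energy_model, steps=60, seed=2)
        assert r.total_energy <= v.total_energy

    def test_relieves_engineered_clash(self, design_region, energy_model, rotlib):
        v = self._variant(design_region, energy_model, rotlib)
        # push the designed center into the backbone to create a clash
        cb = v.structure.get_residue(("A", 14)).atom("CB")
        cb.coord = v.structure.get_residue(("A", 15)).atom("N").coord + 0.5
        clashed = total_energy(v.structure, energy_model)
        v.total_energy = clashed
        r = relax_model(v, energy_model, steps=150, step_size=0.5, seed=3)
        assert r.total_energy < clashed


class TestGenerateVariants:
    def _pool(self, labels):
        return [DdgRecord(Mutation("A", int(l[1:-1]), l[0], l[-1]), -1.0, "external")
                for l in labels]

    @pytest.fixture()
    def small_config(self):
        return DesignConfig(n_variants_requested=3, mc_steps=300, relax_steps=20,
                            seed=11, mutation_fraction_min=0.05,
                            mutation_fraction_max=0.20)

    def test_variants_satisfy_all_contracts(self, design_region, energy_model,
                                            rotlib, small_config):
        pool = self._pool(["G14K", "G18E", "G23Q", "G38K", "G52E", "G58R"])
        variants = generate_variants(design_region, pool, small_config,
                                     energy_model, rotlib)
        L = len(design_region.polymer_residues("A"))
        m_lo = int(np.ceil(small_config.mutation_fraction_min * L))
        m_hi = int(np.floor(small_config.mutation_fraction_max * L))
        pool_set = {(m.mutation.position, m.mutation.mut_aa) for m in pool}
        assert variants
        for v in variants:
            assert m_lo <= len(v.mutations) <= m_hi
            assert {(m.position, m.mut_aa) for m in v.mutations} <= pool_set
            assert v.total_energy < v.wt_ref_energy

    def test_identical_seed_gives_identical_sequences(self, design_region,
                                                      energy_model, rotlib,
                                                      small_config):
        pool = self._pool(["G14K", "G18E", "G23Q", "G38K", "G52E", "G58R"])
        a = generate_variants(design_region, pool, small_config, energy_model, rotlib)
        b = generate_variants(design_region, pool, small_config, energy_model, rotlib)
        assert [v.sequence for v in a] == [v.sequence for v in b]

    def test_pool_too_small_for_fraction_min(self, design_region, energy_model,
                                             rotlib):
        config = DesignConfig(mutation_fraction_min=0.10, n_variants_requested=1)
        with pytest.raises(ConfigurationError, match="achievable"):
            generate_variants(design_region, self._pool(["G14K"]), config,
                              energy_model, rotlib)

    def test_fraction_window_arithmetic(self):
        # L = 100 with the default 2-20% window samples sizes in [2, 20]
        config = DesignConfig()
        assert int(np.ceil(config.mutation_fraction_min * 100)) == 2
        assert int(np.floor(config.mutation_fraction_max * 100)) == 20

    def test_invalid_fraction_window_rejected(self):
        with pytest.raises(ValueError):
            DesignConfig(mutation_fraction_min=0.3, mutation_fraction_max=0.2)
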