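"""Combinatorial variant design: Monte-Carlo rotamer packing plus a
perturb–minimize relaxation, at desk scale.

Packing works on a discrete state space — for every designable position the
states are (amino acid, rotamer) pairs from the allowed set — with energies
precomputed into self (state vs. fixed environment) and pairwise (state vs.
state) tables, so the interacting-body decomposition is exact for the
surrogate energy.  Simulated annealing with geometric cooling explores the
space; the best-visited state is kept and polished by a deterministic
single-move quench.  Relaxation then jitters the placed interaction centers
(and slightly the local backbone) under Metropolis acceptance, again keeping
the best-visited model.

A designed variant is kept only if its mutation count falls inside the
configured fraction window of the design-region length and its total energy
is strictly below that of a wild-type reference packed and relaxed under the
identical schedule — mirroring a design protocol that only admits variants
with lower thermodynamic energy than the wild-type structure.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, model_validator

from .energy import (EnergyModel, RotamerLibrary, default_rotamer_library,
                     place_center, residue_center, total_energy)
from .errors import ConfigurationError, InvalidModelError
from .structures import (Atom, Mutation, ProteinStructure, Residue,
                         ResidueKey, one_to_three)
from .tables import BACKBONE_NAMES, HYDROPHOBIC


class DesignConfig(BaseModel):
    """Tunable parameters of the design stage.

    The mutation-load window defaults to 2–20% of the design-region length,
    the ΔΔG cutoff to −0.5 kcal/mol and the active-site exclusion radius to
    5 Å — the values the stabilization protocol prescribes.
    """

    mutation_fraction_min: float = 0.02
    mutation_fraction_max: float = 0.20
    ddg_cutoff: float = -0.5
    active_site_radius: float = 5.0
    mc_steps: int = 2000
    mc_kt_start: float = 5.0
    mc_kt_end: float = 0.3
    relax_steps: int = 100
    relax_step_size: float = 0.3
    relax_kt_start: float = 1.0
    relax_kt_end: float = 0.1
    backbone_jitter: float = 0.05
    rmsd_cutoff: float = 1.0
    n_variants_requested: int = 10
    n_outer_cycles: int = 1
    seed: int = 0
    max_attempts_factor: int = 20

    @model_validator(mode="after")
    def _check(self):
        if not (0.0 < self.mutation_fraction_min <= self.mutation_fraction_max < 1.0):
            raise ValueError("need 0 < fraction_min <= fraction_max < 1")
        for name in ("mc_steps", "relax_steps", "n_outer_cycles",
                     "n_variants_requested"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        return self


@dataclass
class VariantModel:
    """A designed sequence with its model coordinates and bookkeeping."""

    sequence: str
    structure: ProteinStructure
    mutations: list[Mutation]
    total_energy: float
    designed_positions: list[ResidueKey] = field(default_factory=list)
    ca_rmsd_vs_wt: float | None = None
    wt_ref_energy: float | None = None
    variant_id: str = ""


# ----------------------------------------------------------- MC core

def anneal_states(self_energies: Sequence[np.ndarray],
                  pair_energies: Mapping[tuple[int, int], np.ndarray],
                  steps: int, kt_start: float, kt_end: float,
                  rng: np.random.Generator) -> tuple[tuple[int, ...], float]:
    """Simulated-annealing Metropolis over a discrete state space, followed
    by a deterministic single-move quench; returns the best state visited.

    Works for any problem expressed as self + pairwise tables (the packing
    oracle instances use exactly this interface).
    """
    npos = len(self_energies)
    n_states = [len(se) for se in self_energies]

    def pair(i, j, si, sj):
        if (i, j) in pair_energies:
            return float(pair_energies[(i, j)][si, sj])
        if (j, i) in pair_energies:
            return float(pair_energies[(j, i)][sj, si])
        return 0.0

    def site_energy(i, si, state):
        e = float(self_energies[i][si])
        for j in range(npos):
            if j != i:
                e += pair(i, j, si, state[j])
        return e

    def total(state):
        e = sum(float(self_energies[i][state[i]]) for i in range(npos))
        for i in range(npos):
            for j in range(i + 1, npos):
                e += pair(i, j, state[i], state[j])
        return e

    state = [int(np.argmin(se)) for se in self_energies]   # greedy start
    cur_e = total(state)
    best, best_e = tuple(state), cur_e

    for step in range(steps):
        frac = step / max(steps - 1, 1)
        kt = kt_start * (kt_end / kt_start) ** frac
        i = int(rng.integers(npos))
        if n_states[i] == 1:
            continue
        s_new = int(rng.integers(n_states[i]))
        if s_new == state[i]:
            continue
        d_e = site_energy(i, s_new, state) - site_energy(i, state[i], state)
        if d_e <= 0.0 or rng.random() < math.exp(-d_e / kt):
            state[i] = s_new
            cur_e += d_e
            if cur_e < best_e - 1e-12:
                best, best_e = tuple(state), cur_e

    # quench: first-improvement sweeps in lexicographic order
    state = list(best)
    improved = True
    while improved:
        improved = False
        for i in range(npos):
            cur_site = site_energy(i, state[i], state)
            for s in range(n_states[i]):
                if s == state[i]:
                    continue
                if site_energy(i, s, state) < cur_site - 1e-12:
                    state[i] = s
                    cur_site = site_energy(i, s, state)
                    improved = True
    return tuple(state), total(state)


# ------------------------------------------------------- state tables

def _normalize_keys(structure: ProteinStructure, keys) -> list[ResidueKey]:
    return [structure.get_residue(k).key for k in keys]


def _strip_to_backbone(structure: ProteinStructure,
                       keys: set[ResidueKey]) -> ProteinStructure:
    env = structure.copy()
    for res in env.residues:
        if res.key in keys:
            res.atoms = [a for a in res.atoms if a.name in BACKBONE_NAMES]
    return env


def _build_state_tables(structure: ProteinStructure,
                        designable: list[ResidueKey],
                        allowed: Mapping[ResidueKey, Sequence[str]],
                        model: EnergyModel, rotlib: RotamerLibrary,
                        pssm_scores=None, include_wt: bool = True):
    """Self and pair tables over (aa, rotamer) states.

    Exact decomposition: differences of the assembled model's total energy
    between assignments equal differences of the table sums, because hydrogen
    bonds and all environment–environment terms are assignment-independent.
    """
    dset = set(designable)
    env = _strip_to_backbone(structure, dset)

    # environment particles
    env_atoms, env_radii, env_res_order = [], [], []
    order_of: dict[ResidueKey, int] = {}
    chain_of: dict[ResidueKey, int] = {}
    chains: dict[str, int] = {}
    env_centers = []   # (coord, seq number, chain index) of hydrophobic env residues
    for order, res in enumerate(env.residues):
        order_of[res.key] = order
        is_poly = res.is_polymer and not res.hetero
        cid = chains.setdefault(res.chain_id, len(chains)) if is_poly else -1 - order
        chain_of[res.key] = cid
        for a in res.atoms:
            if a.is_heavy:
                env_atoms.append(a.coord)
                env_radii.append(model.radius(a.element))
                env_res_order.append(order)
        if is_poly and res.key not in dset and res.one_letter in HYDROPHOBIC:
            env_centers.append((residue_center(res), res.seq_number, cid))
    env_atoms = np.array(env_atoms).reshape(-1, 3)
    env_radii = np.array(env_radii)
    env_res_order = np.array(env_res_order)

    states: list[list[tuple[str, int, np.ndarray]]] = []
    self_e: list[np.ndarray] = []
    for key in designable:
        res = structure.get_residue(key)
        wt = res.one_letter
        aas = set(a.upper() for a in allowed.get(key, []))
        if include_wt or not aas:
            aas |= {wt}
        aas = sorted(aas)
        pos_states, energies = [], []
        for aa in aas:
            if aa not in rotlib.rotamers:
                continue
            for r_idx, (offset, _prior) in enumerate(rotlib.get(aa)):
                center = place_center(res, offset)
                e = model.reference_energies.get(aa, 0.0)
                if pssm_scores is not None:
                    site = pssm_scores.get((res.chain_id, res.seq_number))
                    if site is not None:
                        e -= model.pssm_bias_weight * site.get(aa, 0.0)
                # clash against the fixed environment (own residue excluded)
                mask = env_res_order != order_of[res.key]
                d = np.linalg.norm(env_atoms[mask] - center, axis=1)
                overlap = (env_radii[mask] + model.radius("C")) - d
                e += model.clash_weight * float((overlap[overlap > 0] ** 2).sum())
                if aa in HYDROPHOBIC:
                    for c, o, cid in env_centers:
                        if cid == chain_of[res.key] and \
                                abs(o - res.seq_number) < model.contact_min_separation:
                            continue
                        if np.linalg.norm(c - center) <= model.contact_radius:
                            e -= model.contact_weight
                pos_states.append((aa, r_idx, center))
                energies.append(e)
        if not pos_states:
            raise ConfigurationError(f"no packable amino acids at {key}")
        states.append(pos_states)
        self_e.append(np.array(energies))

    pair_e: dict[tuple[int, int], np.ndarray] = {}
    for i in range(len(designable)):
        oi, ci = designable[i][1], chain_of[designable[i]]
        for j in range(i + 1, len(designable)):
            oj, cj = designable[j][1], chain_of[designable[j]]
            mat = np.zeros((len(states[i]), len(states[j])))
            contact_ok = not (ci == cj and abs(oi - oj) < model.contact_min_separation)
            for si, (aai, _, pi) in enumerate(states[i]):
                for sj, (aaj, _, pj) in enumerate(states[j]):
                    d = float(np.linalg.norm(pi - pj))
                    overlap = 2.0 * model.radius("C") - d   # carbon-like centers
                    e = model.clash_weight * overlap ** 2 if overlap > 0 else 0.0
                    if (contact_ok and aai in HYDROPHOBIC and aaj in HYDROPHOBIC
                            and d <= model.contact_radius):
                        e -= model.contact_weight
                    mat[si, sj] = e
            if np.any(mat):
                pair_e[(i, j)] = mat
    return states, self_e, pair_e


def _assemble(structure: ProteinStructure, designable: list[ResidueKey],
              states, assignment) -> ProteinStructure:
    out = structure.copy()
    for key, pos_states, s in zip(designable, states, assignment):
        aa, _r_idx, center = pos_states[s]
        res = out.get_residue(key)
        res.res_name = one_to_three(aa)
        backbone = [a for a in res.atoms if a.name in BACKBONE_NAMES]
        res.atoms = backbone + [Atom("CB", "C", np.array(center, float))]
    return out


def _realized_mutations(wt: ProteinStructure, designed: ProteinStructure,
                        keys: list[ResidueKey]) -> list[Mutation]:
    muts = []
    for key in keys:
        a0 = wt.get_residue(key).one_letter
        a1 = designed.get_residue(key).one_letter
        if a0 != a1:
            muts.append(Mutation(key[0], key[1], a0, a1))
    return muts


def pack_rotamers(structure: ProteinStructure, designable_positions,
                  allowed_aas_per_position: Mapping,
                  energy_model: EnergyModel | None = None,
                  rotlib: RotamerLibrary | None = None,
                  schedule: tuple[float, float, int] | None = None,
                  seed: int = 0, pssm_scores=None,
                  include_wt: bool = True) -> VariantModel:
    """Anneal (amino acid, rotamer) states at the designable positions and
    return the best-energy model visited.  Deterministic for a fixed seed.

    The wild-type amino acid is always kept in each allowed set unless
    ``include_wt`` is False (used when a specific substitution must be
    modelled, e.g. in ΔΔG scoring)."""
    energy_model = energy_model or EnergyModel()
    rotlib = rotlib or default_rotamer_library()
    kt_start, kt_end, steps = schedule or (5.0, 0.3, 2000)

    keys = _normalize_keys(structure, designable_positions)
    if not keys:
        warnings.warn("empty designable set; returning the input as identity variant")
        from .structures import extract_sequence
        return VariantModel(
            sequence=extract_sequence(structure),
            structure=structure.copy(), mutations=[],
            total_energy=total_energy(structure, energy_model, pssm_scores))

    allowed = {structure.get_residue(k).key: v
               for k, v in allowed_aas_per_position.items()}
    states, self_e, pair_e = _build_state_tables(
        structure, keys, allowed, energy_model, rotlib, pssm_scores,
        include_wt=include_wt)
    rng = np.random.default_rng(seed)
    assignment, _table_e = anneal_states(self_e, pair_e, steps, kt_start, kt_end, rng)
    designed = _assemble(structure, keys, states, assignment)
    from .structures import extract_sequence
    return VariantModel(
        sequence=extract_sequence(designed),
        structure=designed,
        mutations=_realized_mutations(structure, designed, keys),
        total_energy=total_energy(designed, energy_model, pssm_scores),
        designed_positions=keys)


def relax_model(model: VariantModel, energy_model: EnergyModel | None = None,
                steps: int = 100, step_size: float = 0.3, seed: int = 0,
                kt_start: float = 1.0, kt_end: float = 0.1,
                backbone_jitter: float = 0.05,
                pssm_scores=None) -> VariantModel:
    """Metropolis perturbation of interaction centers plus small backbone
    jitter; the best-visited model is returned (energy never above input)."""
    energy_model = energy_model or EnergyModel()
    if steps < 0:
        raise ValueError("steps must be non-negative")
    current = model.structure.copy()
    cur_e = total_energy(current, energy_model, pssm_scores)
    best, best_e = current.copy(), cur_e
    keys = list(model.designed_positions)
    if steps == 0 or not keys:
        return VariantModel(sequence=model.sequence, structure=best,
                            mutations=list(model.mutations), total_energy=best_e,
                            designed_positions=keys,
                            wt_ref_energy=model.wt_ref_energy,
                            variant_id=model.variant_id)
    rng = np.random.default_rng(seed)
    for step in range(steps):
        frac = step / max(steps - 1, 1)
        kt = kt_start * (kt_end / kt_start) ** frac
        key = keys[int(rng.integers(len(keys)))]
        trial = current.copy()
        res = trial.get_residue(key)
        cb = res.atom("CB")
        if cb is None:
            raise InvalidModelError(f"designed residue {key} lacks its CB center")
        cb.coord = cb.coord + rng.uniform(-step_size, step_size, 3)
        if rng.random() < 0.3:
            for a in res.atoms:
                if a.name in BACKBONE_NAMES:
                    a.coord = a.coord + rng.uniform(-backbone_jitter,
                                                    backbone_jitter, 3)
        e = total_energy(trial, energy_model, pssm_scores)
        d_e = e - cur_e
        if d_e <= 0.0 or rng.random() < math.exp(-d_e / kt):
            current, cur_e = trial, e
            if cur_e < best_e:
                best, best_e = current.copy(), cur_e
    return VariantModel(sequence=model.sequence, structure=best,
                        mutations=list(model.mutations), total_energy=best_e,
                        designed_positions=keys,
                        wt_ref_energy=model.wt_ref_energy,
                        variant_id=model.variant_id)


def _design_once(structure, keys, allowed, config: DesignConfig,
                 energy_model, rotlib, pssm_scores, seeds) -> VariantModel:
    """One pack → (relax → pack)^cycles run; best-energy stage wins."""
    schedule = (config.mc_kt_start, config.mc_kt_end, config.mc_steps)
    model = pack_rotamers(structure, keys, allowed, energy_model, rotlib,
                          schedule, seed=int(seeds[0]), pssm_scores=pssm_scores)
    best = model
    for cycle in range(config.n_outer_cycles):
        relaxed = relax_model(model, energy_model, steps=config.relax_steps,
                              step_size=config.relax_step_size,
                              seed=int(seeds[1 + 2 * cycle]),
                              kt_start=config.relax_kt_start,
                              kt_end=config.relax_kt_end,
                              backbone_jitter=config.backbone_jitter,
                              pssm_scores=pssm_scores)
        if relaxed.total_energy < best.total_energy:
            best = relaxed
        model = pack_rotamers(relaxed.structure, keys, allowed, energy_model,
                              rotlib, schedule, seed=int(seeds[2 + 2 * cycle]),
                              pssm_scores=pssm_scores)
        if model.total_energy < best.total_energy:
            best = model
    return best


def generate_variants(structure: ProteinStructure, surviving_pool: Sequence,
                      config: DesignConfig,
                      energy_model: EnergyModel | None = None,
                      rotlib: RotamerLibrary | None = None,
                      pssm_scores=None,
                      chain_id: str | None = None) -> list[VariantModel]:
    """Sample designable subsets from the filtered pool, pack and relax each,
    and keep variants whose mutation count is in the configured window and
    whose energy is strictly below the matched wild-type reference."""
    energy_model = energy_model or EnergyModel()
    rotlib = rotlib or default_rotamer_library()
    if not surviving_pool:
        raise ConfigurationError("surviving pool is empty")
    chain_id = chain_id or structure.default_chain()
    region = structure.polymer_residues(chain_id)
    L = len(region)
    m_lo = math.ceil(config.mutation_fraction_min * L)
    m_hi = math.floor(config.mutation_fraction_max * L)

    by_pos: dict[ResidueKey, set[str]] = {}
    wt_of: dict[ResidueKey, str] = {}
    for cand in surviving_pool:
        mut = cand.mutation if hasattr(cand, "mutation") else cand
        key = structure.get_residue(mut.residue_key).key
        by_pos.setdefault(key, set()).add(mut.mut_aa)
        wt_of[key] = mut.wt_aa
    positions = sorted(by_pos, key=lambda k: (k[0], k[1], k[2]))
    if len(positions) < m_lo:
        raise ConfigurationError(
            f"pool covers {len(positions)} positions but the minimum mutation "
            f"load is {m_lo}; achievable maximum is {len(positions)}")
    m_hi_eff = min(m_hi, len(positions))
    if m_hi_eff < m_lo:
        raise ConfigurationError("mutation-load window is empty for this pool")

    master = np.random.default_rng(config.seed)
    variants: list[VariantModel] = []
    n_cycles_seeds = 1 + 2 * config.n_outer_cycles
    max_attempts = config.max_attempts_factor * max(config.n_variants_requested, 1)
    for attempt in range(max_attempts):
        if len(variants) >= config.n_variants_requested:
            break
        m = int(master.integers(m_lo, m_hi_eff + 1))
        chosen_idx = master.choice(len(positions), size=m, replace=False)
        chosen = [positions[i] for i in sorted(chosen_idx)]
        allowed = {k: by_pos[k] for k in chosen}
        seeds_v = master.integers(0, 2**31 - 1, size=n_cycles_seeds)
        seeds_wt = master.integers(0, 2**31 - 1, size=n_cycles_seeds)
        variant = _design_once(structure, chosen, allowed, config,
                               energy_model, rotlib, pssm_scores, seeds_v)
        wt_allowed = {k: {structure.get_residue(k).one_letter} for k in chosen}
        wt_ref = _design_once(structure, chosen, wt_allowed, config,
                              energy_model, rotlib, pssm_scores, seeds_wt)
        variant.wt_ref_energy = wt_ref.total_energy
        if not (m_lo <= len(variant.mutations) <= m_hi):
            continue
        if not variant.total_energy < wt_ref.total_energy:
            continue
        variant.variant_id = f"v{len(variants) + 1:03d}"
        variants.append(variant)
    if len(variants) < config.n_variants_requested:
        warnings.warn(f"produced {len(variants)} of "
                      f"{config.n_variants_requested} requested variants")
    return variants
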