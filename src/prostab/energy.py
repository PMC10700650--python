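"""The surrogate packing energy shared by the ΔΔG scan and the design loop.

The protocol only needs a ranking-competent total energy, not score-function
parity with a molecular-mechanics package, so the energy is a sum of simple,
independently testable terms over heavy atoms:

    E =   clash_weight · Σ_pairs max(0, r_i + r_j − d_ij)²       (repulsion)
        − contact_weight · #(hydrophobic center pairs ≤ contact_radius)
        − hbond_energy · #(detected hydrogen bonds)
        + Σ_residues reference_energy[aa]
        − pssm_bias_weight · Σ_residues PSSM score of the current amino acid

Bonded geometry is excluded from the clash sum by a residue-adjacency rule:
pairs within one residue never clash, and backbone–backbone pairs of
covalently adjacent residues never clash.  Ligand (HETATM) atoms participate
in the clash term only.

Designed side chains use a reduced representation: a single carbon-like
interaction center written as a ``CB`` pseudo-atom, placed by a rotamer
library as an offset in the local Cβ frame.  Wild-type input side chains
keep their full atoms; a residue's interaction center is then its side-chain
heavy-atom centroid (CA for glycine).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .filters import detect_hbonds
from .structures import ProteinStructure, Residue
from .tables import HYDROPHOBIC, REFERENCE_ENERGIES, VDW_RADII


@dataclass
class EnergyModel:
    """Weights and radii of the surrogate energy (kcal/mol-like units)."""

    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    clash_weight: float = 10.0
    contact_weight: float = 0.5
    contact_radius: float = 8.0
    hbond_energy: float = 2.0
    pssm_bias_weight: float = 1.0
    reference_energies: dict[str, float] = field(
        default_factory=lambda: dict(REFERENCE_ENERGIES))
    #: sequence separation below which hydrophobic contacts are not counted
    contact_min_separation: int = 2
    hbond_d_max: float = 3.5
    hbond_angle_min: float = 120.0

    def __post_init__(self):
        if any(r <= 0 for r in self.vdw_radii.values()):
            raise ValueError("van der Waals radii must be positive")
        for w in (self.clash_weight, self.contact_weight, self.hbond_energy,
                  self.pssm_bias_weight):
            if not math.isfinite(w):
                raise ValueError("energy weights must be finite")

    def radius(self, element: str) -> float:
        return self.vdw_radii.get(element.upper(), 1.70)


# PSSM scores addressed by (chain, seq_number) -> {aa: score}
PssmScores = dict


@dataclass
class RotamerLibrary:
    """Interaction-center rotamers: per amino acid, offsets in the local
    Cβ frame plus prior probabilities (priors sum to 1 per amino acid)."""

    rotamers: dict[str, list[tuple[np.ndarray, float]]]

    def __post_init__(self):
        for aa, lst in self.rotamers.items():
            if not lst:
                raise ValueError(f"amino acid {aa} has no rotamers")
            total = sum(p for _, p in lst)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"priors for {aa} sum to {total}, expected 1")

    def get(self, aa: str) -> list[tuple[np.ndarray, float]]:
        return self.rotamers[aa.upper()]


#: distance (Å) from Cβ to the side-chain interaction center, by amino acid;
#: encodes side-chain size in the reduced representation
_CENTER_DISTANCE = {
    "G": 0.0, "A": 0.0, "S": 1.0, "P": 1.0, "C": 1.2, "T": 1.2, "V": 1.2,
    "N": 1.6, "D": 1.6, "L": 1.8, "I": 1.8, "H": 2.0, "Q": 2.2, "E": 2.2,
    "M": 2.2, "F": 2.2, "W": 2.4, "K": 2.6, "Y": 2.6, "R": 3.0,
}
_TILT = math.radians(40.0)


def default_rotamer_library() -> RotamerLibrary:
    """1–3 rotamers per amino acid with uniform priors: one straight out of
    the Cβ frame, two tilted by 40° for side chains long enough to swing."""
    lib: dict[str, list[tuple[np.ndarray, float]]] = {}
    for aa, d in _CENTER_DISTANCE.items():
        if d < 1.5:
            offsets = [np.array([d, 0.0, 0.0])]
        else:
            c, s = math.cos(_TILT), math.sin(_TILT)
            offsets = [np.array([d, 0.0, 0.0]),
                       np.array([d * c, d * s, 0.0]),
                       np.array([d * c, 0.0, d * s])]
        p = 1.0 / len(offsets)
        lib[aa] = [(off, p) for off in offsets]
    return RotamerLibrary(rotamers=lib)


def load_rotamer_library(path: str | Path) -> RotamerLibrary:
    """Read a replacement library from TSV (aa, dx, dy, dz, prior)."""
    lib: dict[str, list[tuple[np.ndarray, float]]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            aa, dx, dy, dz, prior = line.split("\t")
            lib.setdefault(aa.upper(), []).append(
                (np.array([float(dx), float(dy), float(dz)]), float(prior)))
    return RotamerLibrary(rotamers=lib)


def cb_frame(res: Residue) -> tuple[np.ndarray, np.ndarray]:
    """(origin, 3x3 frame) at the residue's (virtual) Cβ.

    Axis 0 points from CA through Cβ, axis 1 lies toward N, axis 2 completes
    the right-handed frame.
    """
    from .synthetic import virtual_cb  # backbone-only construction
    n, ca, c = (res.atom(x) for x in ("N", "CA", "C"))
    if n is None or ca is None or c is None:
        raise ValueError(f"residue {res.key} lacks backbone atoms for a Cβ frame")
    cb = virtual_cb(n.coord, ca.coord, c.coord)
    u1 = cb - ca.coord
    u1 = u1 / np.linalg.norm(u1)
    t = n.coord - ca.coord
    u2 = t - np.dot(t, u1) * u1
    u2 = u2 / np.linalg.norm(u2)
    u3 = np.cross(u1, u2)
    return cb, np.column_stack([u1, u2, u3])


def place_center(res: Residue, offset: np.ndarray) -> np.ndarray:
    origin, frame = cb_frame(res)
    return origin + frame @ np.asarray(offset, float)


def residue_center(res: Residue) -> np.ndarray:
    """Interaction center: side-chain heavy centroid, else CA."""
    side = res.sidechain_atoms()
    if side:
        return np.mean([a.coord for a in side], axis=0)
    ca = res.atom("CA")
    if ca is None:
        raise ValueError(f"residue {res.key} has no CA")
    return ca.coord


def _clash_energy(coords: np.ndarray, radii: np.ndarray,
                  res_idx: np.ndarray, seq_num: np.ndarray,
                  backbone: np.ndarray, chain_idx: np.ndarray,
                  weight: float) -> float:
    d = squareform(pdist(coords))
    rsum = radii[:, None] + radii[None, :]
    overlap = rsum - d
    same_res = res_idx[:, None] == res_idx[None, :]
    adjacent = (chain_idx[:, None] == chain_idx[None, :]) & \
               (np.abs(seq_num[:, None] - seq_num[None, :]) == 1)
    bb_pair = backbone[:, None] & backbone[None, :]
    excluded = same_res | (adjacent & bb_pair)
    mask = (overlap > 0) & ~excluded
    iu = np.triu(mask, k=1)
    return weight * float((overlap[iu] ** 2).sum())


def _build_particles(structure: ProteinStructure, model: EnergyModel):
    """Flatten heavy atoms into arrays; returns also per-polymer-residue
    (center, hydrophobic flag, chain index, order index, one-letter)."""
    coords, radii, res_idx, seq_num, backbone, chain_idx = [], [], [], [], [], []
    centers = []
    chain_of: dict[str, int] = {}
    order = 0
    for res in structure.residues:
        is_poly = res.is_polymer and not res.hetero
        cid = chain_of.setdefault(res.chain_id, len(chain_of))
        # hetero residues get a unique pseudo chain so adjacency never applies
        this_chain = cid if is_poly else -1 - order
        for a in res.atoms:
            if not a.is_heavy:
                continue
            coords.append(a.coord)
            radii.append(model.radius(a.element))
            res_idx.append(order)
            seq_num.append(res.seq_number)
            backbone.append(a.is_backbone and is_poly)
            chain_idx.append(this_chain)
        if is_poly:
            centers.append((residue_center(res), res.one_letter in HYDROPHOBIC,
                            cid, res.seq_number, res.one_letter))
        order += 1
    return (np.array(coords), np.array(radii), np.array(res_idx),
            np.array(seq_num), np.array(backbone, bool),
            np.array(chain_idx), centers)


def hydrophobic_contact_count(centers, model: EnergyModel) -> int:
    """Count hydrophobic center pairs within the contact radius that are at
    least ``contact_min_separation`` apart in sequence (always counted
    across chains)."""
    hydro = [(c, ch, s) for c, h, ch, s, _aa in centers if h]
    count = 0
    for i in range(len(hydro)):
        for j in range(i + 1, len(hydro)):
            ci, chi, oi = hydro[i]
            cj, chj, oj = hydro[j]
            if chi == chj and abs(oi - oj) < model.contact_min_separation:
                continue
            if np.linalg.norm(ci - cj) <= model.contact_radius:
                count += 1
    return count


def total_energy(structure: ProteinStructure, model: EnergyModel | None = None,
                 pssm_scores: PssmScores | None = None) -> float:
    """Evaluate the surrogate energy of a model (deterministic)."""
    if model is None:
        model = EnergyModel()
    coords, radii, res_idx, seq_num, backbone, chain_idx, centers = \
        _build_particles(structure, model)
    if coords.size == 0:
        raise ValueError("structure has no heavy atoms to score")
    e = _clash_energy(coords, radii, res_idx, seq_num, backbone, chain_idx,
                      model.clash_weight)
    e -= model.contact_weight * hydrophobic_contact_count(centers, model)
    e -= model.hbond_energy * len(detect_hbonds(
        structure, d_max=model.hbond_d_max, angle_min=model.hbond_angle_min))
    for res in structure.polymer_residues():
        aa = res.one_letter
        e += model.reference_energies.get(aa, 0.0)
        if pssm_scores is not None:
            site = pssm_scores.get((res.chain_id, res.seq_number))
            if site is not None:
                e -= model.pssm_bias_weight * site.get(aa, 0.0)
    return float(e)
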