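"""Final screening of designed variants by Cα RMSD and energy decrease.

Superposition uses the Kabsch algorithm (closed-form least-squares rigid
alignment via SVD, with the reflection case sign-corrected so the rotation
is always proper).  Variants whose backbone drifts beyond the RMSD cutoff
or whose energy is not below the wild-type reference are dropped; survivors
are ranked by ascending energy and summarized in a mutation-overlap table
(mutations shared by more than five selected variants are flagged, following
the convention of reporting a design campaign's recurrent mutations).
"""
from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import DesignConfig, VariantModel
from .structures import ProteinStructure

OVERLAP_FLAG_COUNT = 5


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of A onto B.

    Returns (rotation R, translation t, rmsd) minimizing ‖R·a + t − b‖ in
    the least-squares sense, with det(R) = +1 enforced.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must both be N×3")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if np.linalg.matrix_rank(ac, tol=1e-9) < 2 or \
            np.linalg.matrix_rank(bc, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set")
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = b.mean(axis=0) - rot @ a.mean(axis=0)
    diff = (ac @ rot.T) - bc
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return rot, t, rmsd


def ca_rmsd(variant: VariantModel | ProteinStructure,
            wt: ProteinStructure) -> float:
    """Cα RMSD after optimal superposition, matched by (chain, number)."""
    structure = variant.structure if isinstance(variant, VariantModel) else variant
    wt_ca = {}
    for res in wt.polymer_residues():
        ca = res.atom("CA")
        if ca is not None:
            wt_ca[res.key] = ca.coord
    a, b = [], []
    for res in structure.polymer_residues():
        ca = res.atom("CA")
        if ca is not None and res.key in wt_ca:
            a.append(ca.coord)
            b.append(wt_ca[res.key])
    if len(a) < 3:
        raise ValueError(f"only {len(a)} matched Cα atoms; need at least 3")
    _, _, rmsd = kabsch_superpose(np.array(a), np.array(b))
    if isinstance(variant, VariantModel):
        variant.ca_rmsd_vs_wt = rmsd
    return rmsd


@dataclass
class SelectionEntry:
    variant_id: str
    energy: float
    energy_gap_vs_wt: float
    ca_rmsd: float
    n_mutations: int
    mutations: list[str]


@dataclass
class SelectionReport:
    entries: list[SelectionEntry] = field(default_factory=list)
    overlap: dict[str, int] = field(default_factory=dict)
    rmsd_cutoff: float = 1.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rmsd_cutoff": self.rmsd_cutoff,
            "variants": [vars(e) for e in self.entries],
            "mutation_overlap": [
                {"mutation": m, "count": c, "recurrent": c > OVERLAP_FLAG_COUNT}
                for m, c in self.overlap.items()],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("variant\tenergy\tenergy_gap_vs_wt\tca_rmsd\tn_mutations\tmutations\n")
            for e in self.entries:
                fh.write(f"{e.variant_id}\t{e.energy:.4f}\t{e.energy_gap_vs_wt:.4f}\t"
                         f"{e.ca_rmsd:.4f}\t{e.n_mutations}\t{','.join(e.mutations)}\n")

    def overlap_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("mutation\tcount\trecurrent\n")
            for m, c in self.overlap.items():
                fh.write(f"{m}\t{c}\t{c > OVERLAP_FLAG_COUNT}\n")


def rank_and_select(variants: Sequence[VariantModel], wt_energy: float,
                    config: DesignConfig) -> SelectionReport:
    """Gate by RMSD cutoff and energy decrease, rank ascending by energy,
    truncate to the requested count, and tabulate mutation overlap.

    The energy gate compares each variant against its matched wild-type
    reference when available, else against *wt_energy*.
    """
    survivors = []
    for v in variants:
        if v.ca_rmsd_vs_wt is None:
            raise ValueError(f"variant {v.variant_id or '?'} has no Cα RMSD")
        ref = v.wt_ref_energy if v.wt_ref_energy is not None else wt_energy
        if v.ca_rmsd_vs_wt > config.rmsd_cutoff:
            continue
        if v.total_energy >= ref:
            continue
        survivors.append(v)
    survivors.sort(key=lambda v: v.total_energy)        # stable sort
    selected = survivors[:config.n_variants_requested]
    if not selected:
        warnings.warn("no variants passed the RMSD/energy screen")
    overlap = Counter()
    for v in selected:
        overlap.update(m.label for m in v.mutations)
    entries = [SelectionEntry(
        variant_id=v.variant_id or f"v{idx + 1:03d}",
        energy=v.total_energy,
        energy_gap_vs_wt=(v.wt_ref_energy if v.wt_ref_energy is not None
                          else wt_energy) - v.total_energy,
        ca_rmsd=v.ca_rmsd_vs_wt,
        n_mutations=len(v.mutations),
        mutations=[m.label for m in v.mutations],
    ) for idx, v in enumerate(selected)]
    return SelectionReport(entries=entries, overlap=dict(overlap),
                           rmsd_cutoff=config.rmsd_cutoff)
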