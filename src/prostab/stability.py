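"""Predicted stability changes (ΔΔG) for candidate mutations.

Two routes attach a ΔΔG to a candidate:

* a built-in surrogate that scores the mutation as the energy difference
  between locally repacked mutant and wild-type models (both in the same
  reduced side-chain representation, so the comparison is internally
  consistent);
* an adapter for an external per-mutation TSV produced by any dedicated
  predictor.

Units are kcal/mol-like surrogate units; negative means stabilizing.  The
protocol keeps mutations with ΔΔG strictly below −0.5.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from scipy.spatial.distance import cdist

from .conservation import _iter_tsv_rows
from .design import pack_rotamers
from .energy import EnergyModel, RotamerLibrary, default_rotamer_library
from .errors import FormatError, NotFoundError
from .structures import Mutation, ProteinStructure

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DdgRecord:
    mutation: Mutation
    ddg: float
    method: str                       # 'surrogate' | 'external'

    def __post_init__(self):
        if not math.isfinite(self.ddg):
            raise ValueError(f"{self.mutation.label}: ΔΔG must be finite")
        if self.method not in ("surrogate", "external"):
            raise ValueError(f"unknown ΔΔG method {self.method!r}")


def repack_neighborhood(structure: ProteinStructure, mutation: Mutation,
                        radius: float) -> list:
    """The mutated residue plus every polymer residue with a heavy atom
    within *radius* Å of it (the local-repack region)."""
    target = structure.get_residue(mutation.residue_key)
    tcoords = target.heavy_coords()
    keys = [target.key]
    for res in structure.polymer_residues():
        if res.key == target.key:
            continue
        coords = res.heavy_coords()
        if coords.size and cdist(coords, tcoords).min() <= radius:
            keys.append(res.key)
    return keys


def surrogate_ddg(structure: ProteinStructure, mutation: Mutation,
                  model: EnergyModel | None = None,
                  rotlib: RotamerLibrary | None = None,
                  seed: int = 0, mc_steps: int = 400) -> DdgRecord:
    """ΔΔG = E(mutant after local repack) − E(wild type after identical
    local repack).

    The repack region is the mutated position plus all residues within the
    model's contact radius; both states are packed with the same seed, so a
    self-substitution scores exactly zero by construction.
    """
    model = model or EnergyModel()
    rotlib = rotlib or default_rotamer_library()
    res = structure.get_residue(mutation.residue_key)   # raises NotFoundError
    wt = res.one_letter
    if wt != mutation.wt_aa:
        raise ValueError(
            f"{mutation.label}: structure has {wt} at position {mutation.position}")
    keys = repack_neighborhood(structure, mutation, model.contact_radius)
    schedule = (2.0, 0.2, mc_steps)

    def packed_energy(target_aa: str) -> float:
        allowed = {k: {structure.get_residue(k).one_letter} for k in keys}
        allowed[res.key] = {target_aa}
        packed = pack_rotamers(structure, keys, allowed, model, rotlib,
                               schedule, seed=seed, include_wt=False)
        return packed.total_energy

    e_mut = packed_energy(mutation.mut_aa)
    e_wt = packed_energy(mutation.wt_aa)
    return DdgRecord(mutation=mutation, ddg=e_mut - e_wt, method="surrogate")


def read_ddg_table(path: str | Path) -> list[DdgRecord]:
    """External per-mutation ΔΔG TSV (chain, position, wt, mut, ddg).

    Duplicate (chain, position, mut) rows keep the lowest ΔΔG; collisions
    are logged.
    """
    records: dict[tuple, DdgRecord] = {}
    for lineno, row in _iter_tsv_rows(path, ("chain", "position", "wt", "mut", "ddg")):
        try:
            ddg = float(row["ddg"])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric ddg {row['ddg']!r}")
        try:
            pos = int(row["position"])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer position")
        mut = Mutation(row["chain"], pos, row["wt"].upper(), row["mut"].upper())
        rec = DdgRecord(mutation=mut, ddg=ddg, method="external")
        key = (mut.chain_id, mut.position, mut.mut_aa)
        if key in records:
            logger.warning("%s:%d: duplicate entry for %s; keeping lowest ΔΔG",
                           path, lineno, mut.label)
            if rec.ddg < records[key].ddg:
                records[key] = rec
        else:
            records[key] = rec
    return list(records.values())


def filter_by_ddg(records: Sequence[DdgRecord], cutoff: float = -0.5
                  ) -> list[DdgRecord]:
    """Keep records with ΔΔG strictly below *cutoff*; input order preserved."""
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if len({r.method for r in records}) > 1:
        warnings.warn("mixing surrogate and external ΔΔG records in one filter run")
    return [r for r in records if r.ddg < cutoff]


def write_ddg_tsv(records: Sequence[DdgRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tposition\twt\tmut\tddg\tmethod\n")
        for r in records:
            m = r.mutation
            fh.write(f"{m.chain_id}\t{m.position}\t{m.wt_aa}\t{m.mut_aa}\t"
                     f"{r.ddg:.4f}\t{r.method}\n")
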