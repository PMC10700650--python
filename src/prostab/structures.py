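"""Atomic protein models and coordinate primitives.

Parsing and serialization are delegated to gemmi; on top of it this module
enforces the conventions the design protocol relies on: only the first MODEL
is read, alternate locations are collapsed to the highest-occupancy conformer
(ties broken alphabetically), author residue numbering is preserved
everywhere (so positions like His25 or L101 stay addressable after
N-terminal truncation), and non-standard residues are kept structurally but
render as ``X`` in sequences.
"""
from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .errors import EmptyStructureError, NotFoundError
from .tables import BACKBONE_NAMES, ONE_TO_THREE, THREE_TO_ONE

ResidueKey = tuple  # (chain_id, seq_number) or (chain_id, seq_number, icode)


@dataclass
class Atom:
    """A single atom: PDB name, element symbol and Cartesian position (Å)."""

    name: str
    element: str
    coord: np.ndarray
    is_backbone: bool = False

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element symbol required")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    """One residue identified by (chain, author number, insertion code)."""

    chain_id: str
    seq_number: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    hetero: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    @property
    def is_polymer(self) -> bool:
        """Amino-acid residues, including non-standard ones carrying a CA."""
        if self.res_name in THREE_TO_ONE:
            return True
        return (not self.res_name == "HOH") and self.atom("CA") is not None

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coord for a in self.atoms if a.is_heavy]
        return np.array(coords, dtype=float).reshape(-1, 3)

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy and a.name not in BACKBONE_NAMES]


@dataclass
class ProteinStructure:
    """An ordered collection of residues from a single conformer."""

    residues: list[Residue] = field(default_factory=list)
    title: str = ""

    def __post_init__(self):
        self._index: dict[ResidueKey, Residue] = {}
        self._reindex()

    def _reindex(self):
        self._index = {}
        for res in self.residues:
            if res.key in self._index:
                raise ValueError(f"duplicate residue key {res.key}")
            self._index[res.key] = res

    def copy(self) -> "ProteinStructure":
        return _copy.deepcopy(self)

    def polymer_residues(self, chain_id: str | None = None) -> list[Residue]:
        out = [r for r in self.residues if r.is_polymer and not r.hetero]
        if chain_id:
            out = [r for r in out if r.chain_id == chain_id]
        return out

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.polymer_residues():
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def default_chain(self) -> str:
        chains = self.chains()
        if not chains:
            raise EmptyStructureError("structure has no polymer chains")
        return chains[0]

    def get_residue(self, key: ResidueKey | Sequence) -> Residue:
        key = tuple(key)
        if len(key) == 2:
            key = (*key, "")
        try:
            return self._index[key]
        except KeyError:
            raise NotFoundError(f"residue {key} not found") from None


@dataclass(frozen=True)
class Mutation:
    """A single point substitution in author numbering, e.g. L101F."""

    chain_id: str
    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self):
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"mutation {self.label}: wild type equals mutant")
        for aa in (self.wt_aa, self.mut_aa):
            if len(aa) != 1:
                raise ValueError(f"amino acids must be one-letter codes, got {aa!r}")

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.position, "")


def _pick_altloc(candidates: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved by altloc letter ('A' first)
    return min(candidates, key=lambda a: (-a.occ, a.altloc or "~"))


def read_pdb(path: str | Path) -> ProteinStructure:
    """Parse the first MODEL of a PDB file into a :class:`ProteinStructure`.

    HETATM residues (ligands, waters) are retained and flagged ``hetero``;
    they participate in distance and clash computations but never in
    sequence extraction or design.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise OSError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for name, group in by_name.items():
                g = _pick_altloc(group)
                atoms.append(Atom(
                    name=name,
                    element=g.element.name or "C",
                    coord=np.array([g.pos.x, g.pos.y, g.pos.z]),
                ))
            # amino-acid-like HETATMs (MSE etc. with a carbon CA) stay polymer
            has_ca = any(a.name == "CA" and a.element.upper() == "C" for a in atoms)
            hetero = res.het_flag == "H" and not (res.name in THREE_TO_ONE or
                                                  (has_ca and res.name != "HOH"))
            for a in atoms:
                a.is_backbone = a.name in BACKBONE_NAMES and not hetero
            residues.append(Residue(
                chain_id=chain.name,
                seq_number=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                res_name=res.name,
                atoms=atoms,
                hetero=hetero,
            ))
    structure = ProteinStructure(residues=residues, title=st.name or "")
    if not structure.polymer_residues():
        raise EmptyStructureError(f"{path}: no polymer residues (ATOM records)")
    return structure


def extract_sequence(structure: ProteinStructure, chain_id: str | None = None) -> str:
    """One-letter sequence of a chain in residue order; unknowns become 'X'."""
    if not chain_id:
        chain_id = structure.default_chain()
    residues = structure.polymer_residues(chain_id)
    if not residues:
        raise NotFoundError(f"chain {chain_id!r} not found")
    return "".join(r.one_letter for r in residues)


def truncate_n_terminus(structure: ProteinStructure, n: int,
                        chain_id: str | None = None) -> ProteinStructure:
    """Remove the first *n* polymer residues of a chain.

    Author numbering of the remaining residues is unchanged, so positions
    quoted against the full-length protein stay valid.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not chain_id:
        chain_id = structure.default_chain()
    chain_res = structure.polymer_residues(chain_id)
    if not chain_res:
        raise NotFoundError(f"chain {chain_id!r} not found")
    if n >= len(chain_res):
        raise ValueError(
            f"cannot remove {n} residues from chain {chain_id!r} of length {len(chain_res)}")
    drop = {r.key for r in chain_res[:n]}
    kept = [ _copy.deepcopy(r) for r in structure.residues if r.key not in drop ]
    return ProteinStructure(residues=kept, title=structure.title)


def min_heavy_atom_distance(structure: ProteinStructure,
                            res_a: ResidueKey, res_b: ResidueKey) -> float:
    """Minimum distance (Å) over all heavy-atom pairs of two residues."""
    a = structure.get_residue(res_a).heavy_coords()
    b = structure.get_residue(res_b).heavy_coords()
    if a.size == 0 or b.size == 0:
        raise NotFoundError("residue has no heavy atoms")
    return float(cdist(a, b).min())


def write_model(structure: ProteinStructure, path: str | Path) -> None:
    """Serialize a structure to PDB format (coordinates to 3 decimals)."""
    if not structure.residues:
        raise ValueError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = structure.title or "prostab model"
    model = gemmi.Model("1")
    chain: gemmi.Chain | None = None
    for res in structure.residues:
        if chain is None or chain.name != res.chain_id:
            chain = gemmi.Chain(res.chain_id)
            model.add_chain(chain)
            chain = model[-1]
        g = gemmi.Residue()
        g.name = res.res_name
        g.seqid = gemmi.SeqId(res.seq_number, res.icode or " ")
        g.het_flag = "H" if res.hetero else "A"
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coord)
            ga.occ = 1.0
            ga.b_iso = 0.0
            g.add_atom(ga)
        chain.add_residue(g)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def mutation_from_label(label: str, chain_id: str = "A") -> Mutation:
    """Parse a compact label like ``L101F`` into a :class:`Mutation`."""
    if len(label) < 3 or not label[1:-1].isdigit():
        raise ValueError(f"cannot parse mutation label {label!r}")
    return Mutation(chain_id=chain_id, position=int(label[1:-1]),
                    wt_aa=label[0].upper(), mut_aa=label[-1].upper())


def one_to_three(aa: str) -> str:
    try:
        return ONE_TO_THREE[aa.upper()]
    except KeyError:
        raise ValueError(f"unknown amino acid {aa!r}") from None
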