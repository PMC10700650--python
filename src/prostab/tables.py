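"""Amino-acid reference data shared across modules.

The numeric tables (theoretical Gly-X-Gly maximum solvent accessibilities,
residue volumes, per-residue reference energies) ship as editable TSV files
under ``prostab/data`` so a user can swap in alternative scales without
touching code.
"""
from __future__ import annotations

from importlib import resources

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

#: van der Waals radii per element (Å); anything unlisted falls back to carbon.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_VDW_RADIUS = 1.70

#: residues counted as hydrophobic by the surface-exposure filter and the
#: hydrophobic-contact energy term
HYDROPHOBIC = frozenset("AVLIMFWC")

#: side-chain hydrogen-bond donors per amino acid: (donor atom, antecedent)
SIDECHAIN_DONORS = {
    "R": [("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")],
    "N": [("ND2", "CG")],
    "Q": [("NE2", "CD")],
    "H": [("ND1", "CG"), ("NE2", "CD2")],
    "K": [("NZ", "CE")],
    "S": [("OG", "CB")],
    "T": [("OG1", "CB")],
    "W": [("NE1", "CD1")],
    "Y": [("OH", "CZ")],
    "C": [("SG", "CB")],
}

#: side-chain hydrogen-bond acceptors per amino acid
SIDECHAIN_ACCEPTORS = {
    "D": ["OD1", "OD2"],
    "E": ["OE1", "OE2"],
    "N": ["OD1"],
    "Q": ["OE1"],
    "H": ["ND1", "NE2"],
    "S": ["OG"],
    "T": ["OG1"],
    "Y": ["OH"],
    "M": ["SD"],
}


def _load_aa_table(filename: str, column: str) -> dict[str, float]:
    text = resources.files("prostab.data").joinpath(filename).read_text()
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    idx = header.index(column)
    out: dict[str, float] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        out[parts[0]] = float(parts[idx])
    return out


#: theoretical maximum accessible surface per residue type (Ų, Gly-X-Gly)
MAX_SASA = _load_aa_table("max_sasa.tsv", "max_sasa")

#: mean residue volumes (ų)
VOLUMES = _load_aa_table("volumes.tsv", "volume")

#: per-residue reference energies (kcal/mol-like); lower = intrinsically
#: more favourable in regular structure.  Used by the surrogate energy.
REFERENCE_ENERGIES = _load_aa_table("reference_energies.tsv", "energy")


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)
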