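"""Deterministic synthetic fixtures: toy structures, alignments and
packing instances that exercise every stage of the protocol without any
external data.

All generators are pure functions of their arguments (and seed), so
regeneration is bit-identical.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .conservation import Alignment
from .structures import Atom, ProteinStructure, Residue, one_to_three
from .tables import AA_ALPHABET

# ideal backbone geometry (Å / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
HELIX_PHI, HELIX_PSI = -57.0, -47.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement: position d with |cd|=bond, angle(b,c,d)
    and torsion(a,b,c,d) as given."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cβ position from backbone N/CA/C (tetrahedral construction)."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def make_ideal_helix(n_res: int, sequence: str | None = None,
                     chain_id: str = "A", phi: float = HELIX_PHI,
                     psi: float = HELIX_PSI) -> ProteinStructure:
    """Backbone (N, CA, C, O) plus Cβ on standard α-helix dihedrals.

    Consecutive Cα–Cα distances come out ≈3.8 Å and interior residues
    satisfy the helix dihedral windows of the secondary-structure rule.
    """
    if n_res < 4:
        raise ValueError("an ideal helix needs at least 4 residues")
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    sequence = sequence.upper()

    ncac: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    ncac.append((n0, ca0, c0))
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = ncac[-1]
        n_i = place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
        ca_i = place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, 180.0)
        c_i = place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        ncac.append((n_i, ca_i, c_i))

    residues = []
    for i, (n, ca, c) in enumerate(ncac):
        if i + 1 < n_res:
            # carbonyl O opposite the next amide N in the peptide plane
            o = place_atom(ncac[i + 1][1], ncac[i + 1][0], c, _B_C_O,
                           _A_CA_C_O, 0.0)
        else:
            o = place_atom(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)
        aa = sequence[i]
        atoms = [Atom("N", "N", n, True), Atom("CA", "C", ca, True),
                 Atom("C", "C", c, True), Atom("O", "O", o, True)]
        if aa != "G":
            atoms.append(Atom("CB", "C", virtual_cb(n, ca, c)))
        residues.append(Residue(chain_id=chain_id, seq_number=i + 1,
                                res_name=one_to_three(aa), atoms=atoms))
    return ProteinStructure(residues=residues, title=f"ideal helix {n_res}")


def make_toy_msa(length: int, n_seqs: int,
                 planted: dict[int, tuple[str, float]] | None = None,
                 seed: int = 0, reference: str | None = None) -> Alignment:
    """Alignment with uniform-background columns and planted conserved ones.

    ``planted`` maps 1-based columns to (amino acid, frequency); homolog rows
    draw the planted amino acid with that frequency and a uniform amino acid
    otherwise.  Row 0 is the reference: either the given ``reference``
    sequence or a random one, forced to differ from the planted amino acid at
    planted columns so the plant shows up as a substitution.
    """
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    planted = planted or {}
    for pos, (aa, freq) in planted.items():
        if not 1 <= pos <= length:
            raise ValueError(f"planted position {pos} outside 1..{length}")
        if not 0 < freq <= 1:
            raise ValueError(f"planted frequency must be in (0, 1], got {freq}")
        if aa not in AA_ALPHABET:
            raise ValueError(f"planted amino acid {aa!r} unknown")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AA_ALPHABET))

    if reference is None:
        ref = list(aas[rng.integers(0, 20, size=length)])
    else:
        if len(reference) != length:
            raise ValueError("reference length must equal alignment length")
        ref = list(reference.upper())
    for pos, (aa, _freq) in planted.items():
        if ref[pos - 1] == aa:
            ref[pos - 1] = "G" if aa != "G" else "A"

    rows = ["".join(ref)]
    for _ in range(n_seqs - 1):
        row = list(aas[rng.integers(0, 20, size=length)])
        for pos, (aa, freq) in planted.items():
            if rng.random() < freq:
                row[pos - 1] = aa
        rows.append("".join(row))
    ids = ["ref"] + [f"homolog{i}" for i in range(1, n_seqs)]
    return Alignment(ids=ids, sequences=rows)


def icosahedron_vertices() -> np.ndarray:
    """The 12 unit-sphere vertices of a regular icosahedron."""
    phi = (1 + math.sqrt(5)) / 2
    raw = []
    for a, b in itertools.product((-1.0, 1.0), repeat=2):
        raw += [(0, a, b * phi), (a, b * phi, 0), (b * phi, 0, a)]
    v = np.array(raw)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_cage_fixture(shell_radius: float = 3.1) -> ProteinStructure:
    """A carbon atom fully caged by a 12-atom icosahedral carbon shell.

    With carbon radius 1.70 Å and probe 1.4 Å, every probe-sphere sample
    point of the center lies inside a shell atom's expanded sphere, so the
    center's SASA is exactly zero; removing any one shell atom opens a hole.
    """
    center = Residue(chain_id="A", seq_number=1, res_name="GLY",
                     atoms=[Atom("CA", "C", np.zeros(3), True)])
    shell_atoms = [Atom(f"S{i:02d}", "C", shell_radius * v)
                   for i, v in enumerate(icosahedron_vertices())]
    shell = Residue(chain_id="A", seq_number=2, res_name="SHL",
                    atoms=shell_atoms, hetero=True)
    return ProteinStructure(residues=[center, shell], title="SASA cage")


@dataclass
class PackingInstance:
    """A tiny discrete packing problem with its enumerated optimum."""

    self_energies: list[np.ndarray]                 # per position, per state
    pair_energies: dict[tuple[int, int], np.ndarray]  # (i<j) -> (si, sj)
    best_assignment: tuple[int, ...]
    best_energy: float

    @property
    def n_positions(self) -> int:
        return len(self.self_energies)

    def total(self, assignment: tuple[int, ...] | list[int]) -> float:
        e = sum(float(self.self_energies[i][s]) for i, s in enumerate(assignment))
        for (i, j), mat in self.pair_energies.items():
            e += float(mat[assignment[i], assignment[j]])
        return e


def enumerate_optimum(self_energies, pair_energies):
    """Exhaustive search over all state combinations (the oracle)."""
    n_states = [len(se) for se in self_energies]
    best, best_e = None, math.inf
    for combo in itertools.product(*(range(s) for s in n_states)):
        e = sum(float(self_energies[i][s]) for i, s in enumerate(combo))
        for (i, j), mat in pair_energies.items():
            e += float(mat[combo[i], combo[j]])
        if e < best_e:
            best, best_e = combo, e
    return best, best_e


def make_packing_instance(n_positions: int, n_states: int, seed: int = 0,
                          scale: float = 2.0) -> PackingInstance:
    """Random self/pair energies with the optimum found by enumeration."""
    if not 1 <= n_positions <= 3:
        raise ValueError("n_positions must be 1..3")
    if not 1 <= n_states <= 5:
        raise ValueError("n_states must be 1..5")
    rng = np.random.default_rng(seed)
    self_e = [rng.normal(0.0, scale, size=n_states) for _ in range(n_positions)]
    pair_e = {(i, j): rng.normal(0.0, scale, size=(n_states, n_states))
              for i in range(n_positions) for j in range(i + 1, n_positions)}
    best, best_e = enumerate_optimum(self_e, pair_e)
    return PackingInstance(self_energies=self_e, pair_energies=pair_e,
                           best_assignment=best, best_energy=best_e)


# ------------------------------------------------------------ demo inputs

#: conserved polar substitutions planted at flexible glycine positions of the
#: demo helix (author numbering of the 71-residue fixture)
DEMO_PLANTED = {14: "K", 18: "E", 23: "Q", 38: "K", 52: "E", 58: "R",
                64: "Q", 68: "K"}
DEMO_CATALYTIC = {30: "H", 45: "D"}


def demo_wt_sequence(length: int = 71) -> str:
    """Deterministic wild-type sequence for the end-to-end demo fixture:
    a polar helix with glycines at the planted positions and a His/Asp
    catalytic pair mimicking a glycosyltransferase active site."""
    base = ("ASTDNEKQSA" * ((length // 10) + 1))[:length]
    seq = list(base)
    for pos, _aa in DEMO_PLANTED.items():
        if pos <= length:
            seq[pos - 1] = "G"
    for pos, aa in DEMO_CATALYTIC.items():
        if pos <= length:
            seq[pos - 1] = aa
    if length >= 60:
        seq[59] = "G"          # extra glycine targeted by the curated table
    return "".join(seq)


def make_demo_inputs(out_dir, length: int = 71, truncate_n: int = 11,
                     n_seqs: int = 60, planted_freq: float = 0.85,
                     seed: int = 0, n_variants: int = 10):
    """Write the full set of pipeline inputs (helix PDB, planted MSA,
    curated mutation table, run configuration) into *out_dir* and return
    the validated :class:`~prostab.pipeline.RunConfig`.

    The alignment covers the design region left after removing the first
    ``truncate_n`` flexible residues, with its reference row equal to the
    region's wild-type sequence.
    """
    from pathlib import Path

    from .pipeline import RunConfig
    from .structures import write_model

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = demo_wt_sequence(length)
    helix = make_ideal_helix(length, seq)
    pdb_path = out / "helix.pdb"
    write_model(helix, pdb_path)

    region_seq = seq[truncate_n:]
    planted_cols = {pos - truncate_n: (aa, planted_freq)
                    for pos, aa in DEMO_PLANTED.items()
                    if truncate_n < pos <= length}
    msa = make_toy_msa(len(region_seq), n_seqs, planted=planted_cols,
                       seed=seed, reference=region_seq)
    msa_path = out / "msa.fasta"
    with open(msa_path, "w") as fh:
        for sid, s in zip(msa.ids, msa.sequences):
            fh.write(f">{sid}\n{s}\n")

    curated_path = out / "curated.tsv"
    with open(curated_path, "w") as fh:
        fh.write("chain\tposition\twt\tmut\n")
        if length >= 60:
            fh.write("A\t60\tG\tK\n")
        fh.write("A\t23\tG\tE\n")

    config = RunConfig(
        structure_path=str(pdb_path),
        alignment_path=str(msa_path),
        curated_path=str(curated_path),
        chain_id="A",
        truncate_n=truncate_n,
        filters={"catalytic_residues": [f"A:{p}" for p in sorted(DEMO_CATALYTIC)
                                        if truncate_n < p <= length]},
        design={"n_variants_requested": n_variants, "seed": seed},
        output_dir=str(out / "run"),
        seed=seed,
    )
    config.to_yaml(out / "config.yaml")
    return config
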