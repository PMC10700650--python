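"""Conservation analysis: PSSM construction and candidate-mutation pools.

A position-specific scoring matrix (PSSM) is built from a homolog multiple
sequence alignment as per-column log-odds (in bits) of each amino acid
against a background distribution, with Laplace-style additive smoothing:

    score(c, a) = log2( ((n_ca + k) / (N_c + 20 k)) / q_a )

where ``n_ca`` counts amino acid ``a`` among the ungapped symbols of column
``c`` (gaps and 'X' are excluded), ``N_c`` is the ungapped count, ``k`` the
pseudocount, and ``q_a`` the background frequency.  Only columns where the
reference sequence is ungapped are kept, so rows map one-to-one onto
reference positions.

Positions with positive score for a non-wild-type amino acid are the
conservation-supported substitution pool; a curated table of additional
thermostabilizing mutations (e.g. from an external predictor) can be merged
in, with wild-type identity checked against the reference.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .errors import FormatError, NotFoundError
from .structures import Mutation, ResidueKey
from .tables import AA_ALPHABET, AA_INDEX

GAP_CHARS = {"-", "."}


@dataclass
class Alignment:
    """An aligned set of homolog sequences (upper case, '-' gaps)."""

    ids: list[str]
    sequences: list[str]

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def get(self, seq_id: str) -> str:
        try:
            return self.sequences[self.ids.index(seq_id)]
        except ValueError:
            raise NotFoundError(f"sequence {seq_id!r} not in alignment") from None


def _normalize(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch == ".":
            ch = "-"
        if ch != "-" and ch not in AA_INDEX:
            ch = "X"
        out.append(ch)
    return "".join(out)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned-FASTA file; case-normalized, '.' treated as a gap."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no sequences found")
    ids = [r.id for r in records]
    seqs = [_normalize(str(r.seq)) for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged alignment, lengths {sorted(lengths)}")
    return Alignment(ids=ids, sequences=seqs)


@dataclass
class PSSM:
    """Log-odds scores (bits), one row per ungapped reference position."""

    scores: np.ndarray                  # (L_ref, 20)
    positions: list[int]                # 1-based reference positions
    reference_id: str
    reference_sequence: str             # ungapped reference
    alphabet: str = AA_ALPHABET

    def score(self, position: int, aa: str) -> float:
        i = self.positions.index(position)
        return float(self.scores[i, AA_INDEX[aa]])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\twt\t" + "\t".join(self.alphabet) + "\n")
            for i, pos in enumerate(self.positions):
                row = "\t".join(f"{v:.4f}" for v in self.scores[i])
                fh.write(f"{pos}\t{self.reference_sequence[i]}\t{row}\n")


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def compute_pssm(alignment: Alignment, reference_id: str,
                 pseudocount: float = 1.0,
                 background: Sequence[float] | None = None,
                 weights: Sequence[float] | None = None) -> PSSM:
    """Build the log-odds matrix over reference-ungapped columns.

    ``weights`` is an optional per-sequence weight vector (hook for
    Henikoff-style weighting); by default every sequence counts once.
    """
    ref = alignment.get(reference_id)
    bg = uniform_background() if background is None else np.asarray(background, float)
    if bg.shape != (20,) or np.any(bg <= 0):
        raise ValueError("background must be 20 positive frequencies")
    if abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    w = np.ones(alignment.n_sequences) if weights is None else np.asarray(weights, float)
    if w.shape != (alignment.n_sequences,):
        raise ValueError("weights length must equal the number of sequences")

    rows, positions, ref_seq = [], [], []
    ref_pos = 0
    for c in range(alignment.length):
        if ref[c] in GAP_CHARS:
            continue
        ref_pos += 1
        counts = np.zeros(20)
        for s, seq in enumerate(alignment.sequences):
            ch = seq[c]
            if ch in AA_INDEX:
                counts[AA_INDEX[ch]] += w[s]
        n_c = counts.sum()
        freqs = (counts + pseudocount) / (n_c + 20.0 * pseudocount)
        rows.append(np.log2(freqs / bg))
        positions.append(ref_pos)
        ref_seq.append(ref[c])
    return PSSM(scores=np.array(rows).reshape(-1, 20), positions=positions,
                reference_id=reference_id, reference_sequence="".join(ref_seq))


@dataclass(frozen=True)
class MutationCandidate:
    """A substitution plus its provenance (PSSM scan or curated table)."""

    mutation: Mutation
    source: str                      # 'pssm' | 'curated'
    pssm_score: float | None = None

    def __post_init__(self):
        if self.source not in ("pssm", "curated"):
            raise ValueError(f"unknown candidate source {self.source!r}")
        if self.source == "pssm" and (self.pssm_score is None or self.pssm_score <= 0):
            raise ValueError("pssm-sourced candidates need a positive score")


def positive_mutations(pssm: PSSM, wt_sequence: str, chain_id: str = "A",
                       position_keys: Sequence[ResidueKey] | None = None,
                       threshold: float = 0.0) -> list[MutationCandidate]:
    """All substitutions with PSSM score above *threshold* (default 0).

    ``position_keys`` optionally maps the i-th reference position onto a
    structure residue key (chain, author number); by default positions are
    used as-is on ``chain_id``.
    """
    if len(wt_sequence) != len(pssm.positions):
        raise ValueError(
            f"wild-type length {len(wt_sequence)} != PSSM rows {len(pssm.positions)}")
    if position_keys is not None and len(position_keys) != len(pssm.positions):
        raise ValueError("position_keys length must match PSSM rows")
    out: list[MutationCandidate] = []
    for i, pos in enumerate(pssm.positions):
        wt = wt_sequence[i].upper()
        if position_keys is not None:
            ch, num = position_keys[i][0], position_keys[i][1]
        else:
            ch, num = chain_id, pos
        for a in AA_ALPHABET:
            if a == wt:
                continue
            score = float(pssm.scores[i, AA_INDEX[a]])
            if score > threshold:
                out.append(MutationCandidate(
                    mutation=Mutation(ch, num, wt, a),
                    source="pssm", pssm_score=score))
    return out


@dataclass
class MergeResult:
    candidates: list[MutationCandidate]
    rejected: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self):
        return len(self.candidates)


def merge_candidate_pool(pssm_pool: Sequence[MutationCandidate],
                         curated_table: str | Path,
                         wt_lookup: Callable[[str, int], str] | Mapping | None = None,
                         ) -> MergeResult:
    """Union of the PSSM pool with a curated TSV of extra mutations.

    Deduplication key is (chain, position, mutant aa); duplicates keep the
    PSSM provenance.  When ``wt_lookup`` is supplied, curated rows whose
    claimed wild type disagrees with the reference are rejected and reported.
    """
    seen = {(c.mutation.chain_id, c.mutation.position, c.mutation.mut_aa)
            for c in pssm_pool}
    merged = list(pssm_pool)
    rejected: list[str] = []
    for lineno, row in _iter_tsv_rows(curated_table, ("chain", "position", "wt", "mut")):
        chain, pos, wt, mut = row["chain"], row["position"], row["wt"], row["mut"]
        try:
            pos = int(pos)
        except ValueError:
            raise FormatError(f"{curated_table}:{lineno}: non-integer position {pos!r}")
        wt, mut = wt.upper(), mut.upper()
        if wt == mut or len(wt) != 1 or len(mut) != 1:
            raise FormatError(f"{curated_table}:{lineno}: bad substitution {wt}->{mut}")
        if wt_lookup is not None:
            expected = (wt_lookup(chain, pos) if callable(wt_lookup)
                        else wt_lookup.get((chain, pos)))
            if expected is not None and expected != wt:
                rejected.append(
                    f"line {lineno}: {wt}{pos}{mut} claims wt {wt} but reference has {expected}")
                continue
        key = (chain, pos, mut)
        if key in seen:
            continue
        seen.add(key)
        merged.append(MutationCandidate(
            mutation=Mutation(chain, pos, wt, mut), source="curated"))
    return MergeResult(candidates=merged, rejected=rejected)


def _iter_tsv_rows(path: str | Path, required: tuple[str, ...]):
    """Yield (line number, dict) for each data row of a header-led TSV."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        return
    header = [h.strip().lower() for h in lines[0].split("\t")]
    for col in required:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    for lineno, line in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < len(required):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} columns")
        yield lineno, dict(zip(header, parts))


def write_pool_tsv(pool: Sequence[MutationCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tposition\twt\tmut\tsource\tpssm_score\n")
        for c in pool:
            m = c.mutation
            score = "" if c.pssm_score is None else f"{c.pssm_score:.4f}"
            fh.write(f"{m.chain_id}\t{m.position}\t{m.wt_aa}\t{m.mut_aa}\t"
                     f"{c.source}\t{score}\n")


def read_pool_tsv(path: str | Path) -> list[MutationCandidate]:
    out = []
    for lineno, row in _iter_tsv_rows(path, ("chain", "position", "wt", "mut")):
        source = row.get("source", "curated") or "curated"
        score = row.get("pssm_score") or None
        out.append(MutationCandidate(
            mutation=Mutation(row["chain"], int(row["position"]),
                              row["wt"].upper(), row["mut"].upper()),
            source=source, pssm_score=float(score) if score else None))
    return out
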