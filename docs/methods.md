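# Methods

This note documents the models and procedures implemented in `prostab`,
the choices made where the design was genuinely open, and what the test
suite does and does not establish.

## Scope and design of the protocol

The package re-implements a conservation-guided enzyme-stabilization
protocol as deterministic, testable components: PSSM-based candidate
harvesting, ΔΔG filtering, structural exclusion rules, combinatorial
rotamer-packing design, and RMSD/energy selection. Services and score
functions that the original workflow consumed interactively (homology
search servers, external stability predictors, molecular-graphics
inspection, a molecular-mechanics energy function) are replaced by file
adapters and by documented surrogates, so the full protocol runs offline
and every stage's behaviour is checkable against independent oracles.

## Conservation model

The PSSM is a per-column log-odds matrix in bits,

    s(c, a) = log2( ((n_ca + k) / (N_c + 20k)) / q_a ),

computed only over columns where the reference sequence is ungapped, so
rows map one-to-one onto reference positions. `N_c` counts the 20 standard
amino acids in the column; gaps and `X` contribute nothing.

Choices: the background `q` defaults to uniform 1/20 rather than a
substitution-matrix-derived vector — this makes the
frequencies-equal-background case score exactly zero (an exact test) and
keeps planted-signal expectations computable in closed form; a custom
20-vector can be supplied. Smoothing is additive (Laplace) with `k = 1`,
the simplest defensible choice. No sequence weighting is applied by
default — a deliberate divergence from PSI-BLAST-style matrices — but a
per-sequence weight vector is accepted. The homolog search itself is out
of scope: the alignment is an input.

The candidate pool consists of (position, substitution) pairs with
positive score; reports additionally count distinct positions, since
"number of positions" and "number of mutations" differ and both are
useful.

## Surrogate energy

The protocol needs a ranking-competent total energy, not force-field
parity. The surrogate is a sum of independently testable terms over heavy
atoms (units are kcal/mol-like):

    E =  w_clash · Σ max(0, r_i + r_j − d_ij)²          over non-bonded pairs
       − w_contact · #(hydrophobic center pairs ≤ R_c)
       − E_hb · #(geometric hydrogen bonds)
       + Σ ref[aa]                                       per residue
       − w_pssm · Σ s(position, aa)                      when a PSSM is supplied

Defaults: van der Waals radii C 1.70, N 1.55, O 1.52, S/P 1.80 Å;
`w_clash = 10`, `w_contact = 0.5` with contact radius `R_c = 8` Å and a
minimum sequence separation of 2, `E_hb = 2`, `w_pssm = 1`. Bonded
geometry is excluded by a residue-adjacency rule: atom pairs within one
residue, and backbone–backbone pairs of residues adjacent in author
numbering on the same chain, never clash. Ligand (HETATM) atoms
participate in the clash term only — they act as excluded volume but have
no contacts, hydrogen bonds or reference energy.

The per-residue reference energies ship as an editable table
(`data/reference_energies.tsv`) based on experimental helix-propensity
scales (Ala 0.0 … Gly 1.0, Pro 3.16 kcal/mol): lower values mark residues
intrinsically favourable in regular structure, which gives the surrogate
ΔΔG a realistic sequence-dependent component on top of the packing terms.

### Reduced side-chain representation

Designed side chains are represented by a single carbon-like interaction
center written as a `CB`-named pseudo-atom, placed by a rotamer library as
an offset in a local frame anchored at the (virtual) Cβ. The shipped
library has 1–3 rotamers per amino acid with uniform priors: one offset
straight out of the Cα→Cβ axis at an amino-acid-specific distance
(Gly/Ala 0 Å … Arg 3.0 Å) and, for side chains longer than 1.5 Å, two
offsets tilted by 40°. Side-chain size is therefore encoded in the center
distance, not the center radius (all centers score as carbon). The library
is replaceable via a TSV.

Wild-type input side chains keep their full atoms; a full-atom residue's
interaction center is its side-chain heavy-atom centroid (Cα for
glycine). Because mutant and wild-type states are *both* reduced at every
repacked position, comparisons (ΔΔG, variant vs. wild-type reference) are
internally consistent; the absolute energies of reduced and full-atom
models are not comparable, which is why the pipeline reports the
energy gap against a matched reduced wild-type reference (below). A known
artifact of the reduction: a zero-offset center (Gly/Ala) sits close to
the adjacent backbone and can carry a small constant clash that longer
side chains avoid; it affects both states of a comparison identically
only when the compared amino acids have similar center offsets.

## ΔΔG scoring and filtering

`surrogate_ddg` scores a mutation as
`E(mutant, locally repacked) − E(wild type, identically repacked)`, where
the repack region is the mutated residue plus every polymer residue with a
heavy atom within the contact radius (8 Å) — the local-optimization spirit
of per-mutation stability protocols. Both states are annealed with the
same seed and an identical move sequence, so a self-substitution scores
exactly 0 by construction, and the score is invariant under rigid-body
motion of the input (all terms depend only on internal distances).
Alternatively, `read_ddg_table` adapts any external per-mutation TSV
(duplicates keep the lowest ΔΔG and are logged).

Filtering keeps records with ΔΔG strictly below the cutoff (default
−0.5), preserving input order. The cutoff applies to whichever method
produced the record; mixing surrogate and external records in one run is
allowed but warned about. Scoring uses a single conformer; multi-conformer
averaging is left as a hook.

## Structural exclusion rules

The battery commits criteria that were originally applied by visual
inspection to deterministic geometry. All thresholds except the
literature-stated ~5 Å active-site radius are package choices and are
config-exposed:

- **R1 active site**: fail if the minimum heavy-atom distance from the
  mutated residue to any configured catalytic residue is ≤ 5.0 Å. The
  catalytic list is required — the rule cannot be silently skipped. Any
  heavy atom counts (the more conservative reading). For UGT76G1 the
  documented pair is His25/Asp124; published figure captions also print
  D104, an inconsistency the configuration simply records by listing
  whichever residues the user designates.
- **R2 unsatisfied hydrogen bond**: fail if the wild-type side chain
  participates in ≥1 detected hydrogen bond in a role (donor/acceptor)
  that the mutant amino acid's chemistry table cannot fill. Evaluated on
  the input structure only; mutant side chains are not rebuilt.
- **R3 exposed hydrophobic**: fail if the mutant is in {A,V,L,I,M,F,W,C}
  and relative SASA > 0.25.
- **R4 loop flexibility**: fail for glycine introduced at, or proline
  removed from, a loop position.
- **R5 proline in helix**: fail for proline at a helix position.
- **R6 cavity creation** (proxy): fail if the position is buried
  (relative SASA < 0.10) and the substitution loses more than 40 ų of
  residue volume (standard residue-volume table; e.g. L→A loses
  166.7 − 88.6 = 78.1 ų). Explicit void detection is a non-goal.

Supporting geometry:

- **SASA** is Shrake–Rupley on a deterministic Fibonacci sphere lattice
  (default 960 points, probe 1.4 Å): per atom, the unoccluded fraction of
  sample points at radius r+probe times 4π(r+probe)². Relative SASA
  divides per-residue totals by theoretical Gly-X-Gly maxima
  (`data/max_sasa.tsv`), clipped to [0, 1.2]. At 960 points the areas
  agree with a 10,000-point dense evaluation to well under 3% of an
  atom's full sphere area (the normalization used for that check, since
  relative error is meaningless for nearly buried atoms).
- **Hydrogen bonds** are inferred from heavy-atom chemistry (backbone
  N donor/O acceptor plus per-amino-acid side-chain tables): donor–
  acceptor distance ≤ 3.5 Å and antecedent–donor–acceptor angle ≥ 120°,
  excluding intra-residue pairs and backbone–backbone pairs of covalently
  adjacent residues. Crystal structures of the relevant resolution carry
  no hydrogens, so no hydrogen placement is attempted.
- **Secondary structure** uses backbone dihedral windows: helix-compatible
  φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°] labelled `H` in runs of ≥ 4;
  strand-compatible φ ∈ [−170°, −70°], ψ ∈ [90°, 180°] labelled `E` in
  runs of ≥ 3; everything else (including termini and positions with
  missing backbone, which warn) is loop `L`. This is deliberately not a
  DSSP re-implementation.

## Design loop

Packing is exact-decomposition simulated annealing: for the designable
positions, states are (amino acid, rotamer) pairs; self energies (state
vs. fixed environment, including reference and PSSM terms) and pairwise
energies (center–center clash and contacts) are precomputed, which is an
exact decomposition of the surrogate because hydrogen bonds and all
environment–environment terms are assignment-independent (designed
centers carry no donors/acceptors). Annealing uses geometric cooling
(default kT 5 → 0.3 over 2000 steps) from a greedy start, tracks the
best-visited state, and finishes with a deterministic first-improvement
quench; ties resolve to the lexicographically first state by construction
of the sweep order. On enumerable instances (≤3 positions × ≤5 states)
this reaches the exhaustively enumerated optimum in all seeded tests.

Relaxation perturbs one designed center per move by up to the step size
(default 0.3 Å per coordinate), occasionally jittering that residue's
backbone by up to 0.05 Å, under Metropolis acceptance with its own cooling
schedule; the best-visited model is returned, so the reported energy never
exceeds the input. The outer loop is pack → (relax → pack) per cycle
(default one cycle), keeping the best-energy stage output — the cycle
count is configurable since protocols of this family iterate the two
steps without a canonical count.

`generate_variants` samples, per attempt, a designable subset of size m
uniform in [⌈f_min·L⌉, ⌊f_max·L⌋] (defaults 2%/20% of the design-region
length L, measured on the truncated chain), restricts each position to
{wild type} ∪ pool substitutions, runs the design loop, and computes a
**matched wild-type reference**: the same positions packed and relaxed
under the same schedule restricted to wild-type identities. A variant is
emitted only if its realized mutation count lies inside the window and its
energy is strictly below the reference. Because the packer may keep the
wild type at sampled positions, attempts can fall below the window and are
discarded; sampling continues up to 20× the requested variant count.
Per-attempt seeds derive deterministically from the master seed, so a
fixed seed and configuration reproduce bit-identical variant sequences.

## Selection

Cα RMSD uses Kabsch superposition (SVD with the reflection case
sign-corrected to a proper rotation; collinear inputs rejected), matching
residues by chain and author number. Variants above the RMSD cutoff
(default 1.0 Å — the screen is literature-motivated but no threshold is
printed anywhere, so it is exposed and reported) or at or above their
reference energy are dropped; survivors are ranked by ascending energy
with stable ties and truncated to the requested count. The overlap table
counts how many selected variants share each mutation, flagging those in
more than 5 variants. Energy gaps are in surrogate units.

## Synthetic fixtures and what the tests show

The fixture generators define the study conditions:

- `make_ideal_helix` builds N/CA/C/O (+Cβ) backbones by
  natural-extension placement with ideal bond geometry at φ = −57°,
  ψ = −47° (3.6 residues/turn, Cα–Cα 3.8 Å), parameterizable to extended
  or non-regular conformations.
- `make_toy_msa` plants conserved columns (amino acid + frequency) over a
  uniform background, with the reference row forced to differ at planted
  columns; uniform background matches the PSSM default so expected scores
  are exact.
- `make_cage_fixture` surrounds a carbon with a 12-atom icosahedral shell
  at 3.1 Å: every probe-sphere sample point of the center is within one
  shell atom's expanded sphere (worst-case chord 1.99 Å < 3.1 Å), so the
  center's SASA is exactly zero, while removing any vertex opens a hole
  (gap chord 3.26 Å > 3.1 Å).
- `make_packing_instance` draws random self/pair energies and stores the
  enumerated optimum as the oracle.
- `make_demo_inputs` assembles the end-to-end conditions: a 71-residue
  polar helix (design region 60 after removing the 11 flexible N-terminal
  residues), a His30/Asp45 catalytic pair, eight glycines whose
  replacement by conserved polar residues (K/E/Q/R at frequency 0.85 in a
  60-sequence alignment) is the planted stabilization signal, and a small
  curated table. Sizes were chosen so the full protocol runs in about a
  minute on one CPU.

All fixtures are deterministic in their seeds. What passing tests show:
the geometric primitives match analytic and dense-sampling oracles, the
combinatorial optimizer matches enumeration, the statistical scan recovers
planted signals, and the protocol's contracts (monotone pool shrinkage,
mutation-load window, active-site exclusion, strict energy decrease, RMSD
gate, byte-identical reruns) hold end to end. What they do not show:
fidelity to any real protein family — the fixtures are single ideal
helices without tertiary packing, real rotamer distributions, ligand
chemistry beyond excluded volume, or realistic alignment phylogeny — and
the surrogate energy makes no claim of thermodynamic accuracy; its role is
to rank states consistently.

## Numerical and degenerate-input conventions

Alternate locations keep the highest-occupancy conformer (ties:
alphabetical); only the first MODEL of multi-model files is read;
non-standard residues (e.g. MSE) stay in the structure, render as `X` and
are never designable. PDB output rounds coordinates to 3 decimals
(round-trip error ≤ 5×10⁻⁴ Å). Empty designable sets return the input as
an identity variant with a warning; an empty post-screen selection is a
warned-about empty report, not an error; a pool too small for the
mutation-load window is a configuration error stating the achievable
maximum. Annealing improvement comparisons use a 10⁻¹² slack so exact
ties never cycle.

## Known limitations

- The reduced interaction-center representation cannot capture side-chain
  hydrogen bonding or aromatic-specific interactions of designed residues;
  gains such as engineered π-stacking networks are invisible to the
  surrogate.
- R2 judges the mutant's hydrogen-bond capacity from a chemistry table,
  not from rebuilt geometry.
- Relative SASA against Gly-X-Gly maxima exceeds 1 for terminal or
  isolated residues (hence the 1.2 clip).
- The secondary-structure rule under-calls strands at chain edges and
  ignores hydrogen-bond topology.
- ΔΔG values are surrogate-scale; the −0.5 cutoff transfers literally to
  external tables only when those are in comparable units.
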