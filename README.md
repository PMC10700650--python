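# prostab

Conservation-guided computational stabilization of enzymes, at desk scale.

Industrial enzymes — the motivating case is UGT76G1, the stevia
UDP-glycosyltransferase that converts stevioside to rebaudioside A — often
unfold or lose activity at process temperatures. A well-established remedy
is computational stabilization: harvest candidate point mutations from the
conservation pattern of a homolog family, keep only those predicted to
lower the folding free energy, discard the structurally suspect ones, and
combine the survivors into multi-mutant designs whose models score better
than the wild type. `prostab` implements that whole protocol as a reusable
library and CLI:

1. **Conservation scan** — a position-specific scoring matrix (PSSM) is
   built from an aligned homolog set as per-column log-odds (bits)

   *s(c, a) = log₂( ((n₍c,a₎ + k) / (N_c + 20k)) / q_a )*

   with Laplace pseudocount *k* and background *q*; every substitution with
   *s > 0* (an amino acid over-represented among homologs relative to the
   wild type) enters the candidate pool. A curated table of extra
   thermostabilizing mutations (e.g. from an external predictor) can be
   merged in, with wild-type identities checked against the reference.
2. **ΔΔG filter** — each candidate receives a predicted stability change,
   either from an external per-mutation table or from the built-in
   surrogate scorer (energy difference between locally repacked mutant and
   wild-type models); only mutations with ΔΔG < −0.5 are kept.
3. **Structural exclusion battery** — deterministic geometric rules remove
   mutations near catalytic residues (minimum heavy-atom distance ≤ 5 Å),
   mutations that orphan a satisfied side-chain hydrogen bond, exposed
   hydrophobics (Shrake–Rupley relative SASA), flexibility-increasing
   loop mutations, prolines inserted into α-helices, and buried
   large-to-small substitutions (cavity proxy), each with an auditable
   per-rule verdict.
4. **Design** — after truncating the flexible N-terminus, variants carrying
   2–20% mutations are built by simulated-annealing rotamer packing over
   the surviving pool followed by a Metropolis perturb–minimize relaxation,
   and kept only if their total surrogate energy is strictly below a
   wild-type reference treated identically.
5. **Selection** — designs are screened by Cα RMSD against the wild-type
   model (Kabsch superposition) and ranked by energy; the report includes a
   mutation-overlap profile across the selected set.

A synthetic-fixture module generates ideal helices, planted-signal
alignments, SASA cages and enumerable packing instances, so the entire
protocol runs and tests without any downloads.

## Worked example

Generate the synthetic inputs (a 71-residue polar helix whose homolog
alignment carries planted conserved substitutions at eight glycine
positions, plus a His/Asp catalytic pair) and run the full protocol:

```bash
prostab fixtures --out demo --seed 1
prostab run-all --config demo/config.yaml
```

which prints

```
pool: 363 -> 83 (ΔΔG) -> 15 (filters); variants 10 generated, 10 selected
manifest: demo/run/manifest.json
```

Reading: the PSSM scan over the 60-residue design region produced 363
candidate substitutions; 83 scored below the −0.5 ΔΔG cutoff; 15 (at 9
distinct positions) survived the structural battery — dominated by the
planted glycine-to-polar substitutions; all 10 requested variants packed
and relaxed to energies below their wild-type references and passed the
1 Å Cα RMSD screen. `demo/run/selection.tsv` ranks them:

```
variant  energy     energy_gap_vs_wt  ca_rmsd  n_mutations  mutations
v004     -222.9369  44.1727           0.0193   9            G14K,G18E,G23Q,G38K,G52E,G58R,G60T,G64Q,G68K
v003     -220.6933  39.8588           0.0000   9            G14K,G18E,G23Q,G38K,G52E,G58R,G60T,G64Q,G68K
...
```

and `demo/run/overlap.tsv` shows which mutations recur across the selected
set (entries in more than 5 variants are flagged). Each stage can also be
run standalone (`prostab scan`, `ddg`, `filter`, `design`, `select`) on the
previous stage's TSV outputs; see `prostab --help`.

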