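# packmotif

Crystal packing similarity for molecular crystals: from CIF files to
per-structure solid-state geometry reports and cross-structure detection of
shared *supramolecular constructs* (SCs) — the recurring packing motifs of a
compound family — with dimensionality classification and a
structure-relationship graph.

The package is aimed at small-molecule crystallographers and crystal engineers
studying substituent-variation series (the worked example below mimics a family
of 4-substituted methylidene oxindoles: an amide N–H donor, a carbonyl
acceptor, and a pendant aryl ring whose para substituent varies).

## What it computes

**Per structure** (`packmotif audit`, or the library API):

* cell metrics — volume from the metric tensor,
  `V = abc·√(1 − cos²α − cos²β − cos²γ + 2·cosα·cosβ·cosγ)`,
  calculated density `D = Z·M/(N_A·V)` with `Z` inferred from a
  density-plausibility scan constrained by the space-group order;
* symmetry expansion (xyz operator strings, exact rational translations),
  covalent bond perception from Cordero radii, connected-component molecule
  assembly with unwrapping across cell boundaries, major-conformer selection
  for occupancy disorder, E/Z assignment of exocyclic double bonds;
* hydrogen bonds (D…A ≤ 3.5 Å, D–H…A ≥ 120°, N/O by default) and
  sub-van-der-Waals close contacts (Bondi radii) over all symmetry and
  translation images, symmetry-deduplicated;
* least-squares mean planes and interplanar angles.

**Across structures** (`packmotif family`): around a kernel molecule of each
structure a coordination-sphere cluster is built (every molecule with an
atom–atom contact inside the vdW sum + 1.5 Å). Each kernel→neighbour relation
is condensed into a rigid-motion-invariant descriptor — centroid distance *d*,
relative orientation as a quaternion in the kernel's molecular frame, centroid
offset direction **u** in that frame, and an inversion-parity bit. Descriptors
of two clusters are matched one-to-one within tolerances (0.5 Å, 12°); the
translation sublattice spanned by matched members (including tape repeats
carried by the inversion partners of adjacent dimers) gives the motif's
dimensionality: 0D discrete assembly < 1D stack/tape < 2D layer < 3D
isostructural. Congruent pairwise motifs are merged into named SCs
(`A01`, `A11`, `B11`, … = family letter + dimensionality + ordinal; base
vectors labelled `t1`, `t2`, … in order of first appearance) and arranged in a
strict-hierarchy relationship graph.

A first-class synthetic generator (`packmotif.synthetic`) builds ground-truth
toy crystals — inversion dimers, dimer stacks and tapes, layers, isostructural
pairs, hydrate water channels, a P2₁/c catamer — in P1, P−1, P2₁/c and C2/c,
so every pipeline stage is testable without any external data.

## Worked example

```sh
python examples/family_census.py
```

builds five toy structures engineered like a substituent series and prints:

```
sc_id  D               description  n_structures        members base_vectors                         base_magnitudes dependencies
  A01  0 0D inversion-related pair             5 S1 S2 S3 S4 S5                                                        Primary SC
  A11  1             1D stack/tape             3       S1 S2 S3           t1                             4.070-4.130     A11->A01
  A12  1             1D stack/tape             2          S3 S4           t2                           13.400-13.400     A12->A01
  A13  1             1D stack/tape             2          S4 S5           t3                           18.600-18.600     A13->A01
  A31  3      3D isostructural set             2          S1 S2     t1 t4 t5 4.070-4.100 13.718-13.752 16.400-16.440     A31->A11
```

Read this as: all five structures share the H-bonded dimer (`A01`, the primary
SC); three of them stack that dimer with a 4.07 Å repeat (`A11`, base vector
`t1`); two pairs extend it into 13.4 Å and 18.6 Å tapes (`A12`, `A13`); and
S1/S2 are fully isostructural (`A31`), whose packing contains the stack —
hence the dependency chain `A31→A11→A01`. The same command on real CIFs:

```sh
packmotif family 3a.cif 3b.cif 3c.cif --out results/
```

writes `sc_table.csv`, `sc_report.json` and `relationships.dot`.

Other examples: `cell_metrics.py` (Table-style V, Z, D_calcd),
`audit_structure.py` (H-bond and contact report of a hydrate),
`compare_two.py` (pairwise dimensionality), `generate_toys.py` (the synthetic
generator and its ground-truth records), and `validate_deposits.py` (how to
re-run the analysis on the deposited experimental CIFs of the oxindole series,
which are not redistributed here).

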