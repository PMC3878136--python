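# Methods

This note documents the models, conventions and numerical choices behind
packmotif, and what the synthetic test fixtures do and do not establish.

## Cell metrics and CIF handling

Volume comes from the standard triclinic closed form (equivalently
`√det G` with `G` the metric tensor); density from `D = Z·M/(N_A·V)` with
1 Å³ = 10⁻²⁴ cm³. When a deposit states no `Z`, it is inferred by scanning
candidate values and keeping those with a density in the organic window
0.5–3.5 g/cm³, preferring the value closest to 1.4 g/cm³ (a typical organic
crystal density). The scan is restricted to crystallographically possible
values — integer multiples of the space-group order, plus half of it for a
formula unit on a special position — because an unconstrained scan can prefer
an impossible Z (e.g. Z = 7 in C2/c for a cell of ~2580 Å³ and M ≈ 318).
An ambiguity (two candidates within 0.15 g/cm³) raises rather than guesses.

Parsing is backed by gemmi (document/loop reading, xyz operator strings);
operators are stored with exact rational translations so group closure can be
checked exactly. Supported tags are the small-molecule dialect: cell
lengths/angles, either symmetry-operator loop tag, and the atom-site loop
(label, optional type symbol, fractional x/y/z, optional occupancy). Fractional
coordinates are wrapped to [0,1) on ingest; all downstream geometry uses
unwrapped Cartesian copies. When the type-symbol column is absent the element
is inferred from the label stem. Atomic weights are current IUPAC conventional
values; reported formula weights from older tables may disagree by up to
±0.05 g/mol, which the tests allow for.

## Molecules

Orthogonalization uses the standard setting (*a* along x, *b* in the
xy-plane). Bonds are perceived with the Cordero covalent radii plus a 0.40 Å
tolerance (configurable); H–H bonds are never formed and each hydrogen keeps
only its nearest heavy atom. Molecules are connected components of the
periodic bond graph, unwrapped by integer lattice shifts so each is
contiguous; a component whose unwrapping is inconsistent (a covalent chain
through the lattice) is flagged polymeric and excluded from cluster analysis.
Special-position duplicates are removed at 0.30 Å after symmetry expansion.
Occupancy disorder is resolved by keeping the highest-occupancy alternative
within each group of overlapping (< 0.8 Å, same element) or stem-sharing
partially occupied sites, with a label-sort tie-break. A molecule generated
from a *half*-molecule asymmetric unit (molecular symmetry on a special
position) is outside the supported scope.

E/Z assignment of an exocyclic C=C uses the fixed convention
torsion(ref1–C=C–ref2) ∈ [−90°, 90°] → Z, with the carbonyl-side atom as ref1
and the aryl ipso carbon as ref2.

## Per-structure geometry

Hydrogen bonds and close contacts are searched over all symmetry/translation
images within a window derived from the cell's interplanar spacings, enlarged
by the molecular radius and re-centred per operator (a wrapped image's base
copy can sit cells away). Defaults — D…A ≤ 3.5 Å, D–H…A ≥ 120°, N/O donors
and acceptors — are deliberately wide: amide and water donors in molecular
crystals fall at 2.68–2.90 Å and 151–177°, so the window captures them with
headroom; everything is configurable. Donors without a modelled H (common for
water in older refinements) are reported in a separate D…A-only candidate
list. Riding hydrogens are used as deposited; no normalization to neutron
distances. Symmetry deduplication is geometric: two interactions with the same
label pair, distance (1e-4 Å) and angle (0.01°) are one interaction.

Mean planes minimize the perpendicular rms (smallest singular vector);
interplanar angles are the acute angle between normals. The oxindole-like
"core" plane is defined as the 9-atom bicyclic set (N1, C2, C3, C3A, C4–C7,
C7A) and the "aryl" plane as the 6-membered pendant ring (C10–C15); these
label sets are a documented choice, adjustable per structure.

## Clusters and the similarity engine

The cluster shell contains every image with an atom–atom contact inside the
vdW sum + margin (default 1.5 Å) of the kernel — a contact criterion rather
than a centroid radius, since centroid cutoffs miss elongated molecules.
Waters are included by default and excludable (`host_only`); they carry no
correspondence labels and therefore never enter descriptor matching, so a
hydrate's host packing is comparable with an anhydrate's.

The atom correspondence between structures is the lexicographically ordered
intersection of non-hydrogen host labels (hydrogens carry no independent
information under riding models). Descriptors are expressed in a kernel-fixed
frame built from the principal axes of the correspondence points. Two
numerical choices matter here:

* *Frame robustness.* A frame built from the first three points wobbles by
  several degrees per structure at refinement-scale noise, enough to break a
  12° tolerance between two noisy copies; principal axes average the noise
  over all points.
* *Sign gauge.* Principal axes are defined up to sign, and no per-structure
  sign statistic is reliably stable. Frames are therefore gauge-fixed against
  a reference structure (the first, by input order): the frame mismatch after
  the best proper superposition of the correspondence points is snapped to
  the nearest proper sign flip. All descriptors, signatures and base vectors
  in one comparison share that gauge. Enantiomeric kernels (an improper
  mismatch) are not supported by the gauge and would degrade matching.

Matching is a deterministic minimum-cost assignment of maximal cardinality
(`scipy.optimize.linear_sum_assignment`) over admissible pairs (parity equal,
|Δd| ≤ 0.5 Å, rotation and offset-direction deviations ≤ 12°). Optimal
assignment (rather than greedy) is what makes "larger tolerances never match
fewer members" an actual invariant. Default tolerances are calibrated to
unify the within-SC spreads such series show (a stack repeat varying by
~0.09 Å across members; interplanar angles spreading ~13°) while separating
distinct motifs. The dissimilarity index is the rms of tolerance-normalized
deviations over matched pairs: 0 for self-comparison, ≤ 1 for any accepted
match.

**Dimensionality.** The motif's translation sublattice is generated (i) by
matched members that are pure lattice translations of the kernel in both
structures and (ii) by lattice-offset differences between matched members of
one operator class — the mechanism by which an 18.6 Å dimer tape is detected
even though no molecule touches its own image 18.6 Å away (the inversion
partner of the adjacent dimer does). A candidate generator enters the basis
only if every small integer combination with the existing basis has the same
length in both structures (closure consistency; this rejects artifacts where
a long combination matches although its constituents do not), and candidates
whose lengths agree best across the two structures are ranked first, so an
exactly shared repeat beats a coincidentally matching shorter combination.
The rank of the basis is the dimensionality; rank 0 with a matched
symmetry-related member is a 0D discrete assembly.

**SC assembly.** Pairwise motifs are merged when their signatures — matched
descriptors plus kernel-frame lattice offsets — embed bijectively within
tolerance, including relational checks on offset differences within an
operator class (offsets carry an arbitrary wrap constant, so only same-class
differences are compared). Sub-construct containment is injective embedding
plus member-set inclusion. Implied lower-dimensional sub-motifs (the 0D core
of a stack, the 1D stack along the shortest base vector of a layer or
isostructural pair) are generated only as a fallback when the family provides
no direct pairwise evidence for them; this lets a two-member isostructural
family still report its 0D and 1D content without duplicating constructs in
richer families. Family letters are connected components of the containment
relation, ordered by (lowest dimensionality, largest membership); ordinals
within a letter+dimensionality sort by base-vector magnitude; base-vector
labels t1, t2, … are assigned on first appearance and re-used when magnitude
(≤ 0.5 Å) and kernel-frame direction (≤ 12°) agree. Within-family text
sources sometimes label such vectors inconsistently; here the labels are
generated, so they are consistent by construction.

The relationship graph keeps covering relations only (transitive reduction),
has a strict level order 0D < 1D < 2D < 3D < structures, and every SC reaches
at least two structures; the meet of two structure nodes is their set of
maximal common constructs.

## The synthetic generator

The host template mimics a 3-benzylidene-oxindole: an idealized planar
bicyclic amide core (1.40 Å aromatic geometry) with one N–H donor and one
C=O acceptor, an exocyclic C=C, and a pendant aryl ring rotated exactly 42°
about the C9–C10 axis — the mid-range of the 36–50° interplanar spread such
compounds show. The centrosymmetric dimer is placed so N…O = 2.87 Å
(mid-range of the 2.84–2.90 Å reported for such amide dimers) with a linear
N–H…O; stack and tape repeats default to 4.07, 13.4 and 18.6 Å. The P2₁/c
catamer donates along the 2₁ screw with the repeat solved exactly from the
molecular geometry; its N–H…O is bent to ~157° — the price of keeping
neighbouring chain images clash-free with this idealized molecule.

Cell vectors of the multi-structure families were designed numerically, once,
against three constraints: no non-bonded intermolecular approach below 1.5 Å
anywhere in the lattice; each designed translation supported by a genuine vdW
contact (directly or through the adjacent dimer's inversion partner, which
requires tilting long cell vectors along the dimer axis — exactly how the
real oblique cells of such series work); and all *unshared* magnitudes
differing by ≥ 0.6 Å so only designed base vectors match at the default
tolerance. Coordinate noise is seeded isotropic Gaussian displacement applied
to the asymmetric unit; the seed fully determines the output bytes, and is
recorded in the CIF comment.

What the toys do *not* emulate: realistic thermal motion and displacement
parameters, genuine refinement correlations, disorder beyond a two-conformer
toggle, solvent beyond a single water, special-position molecules (except the
C2/c water channel), or the full close-packing density of real crystals —
only the designed contact directions are guaranteed to be in contact, so
"self-comparison is 3D" holds for the packed family fixtures, not for every
toy (the hydrate and catamer cells are contact-complete only along their
designed axes). Passing tests therefore demonstrate correctness of the
machinery on controlled geometry, not recovery performance on experimental
data; the examples include a script for running the pipeline on the deposited
experimental structures where available.

## Problem sizes

The default test suite and the acceptance script use 20-replicate recovery
runs at σ = 0.03 Å, 50 randomized brute-force-oracle fixtures, and families
of ≤ 5 structures of ~28-atom molecules — sizes chosen to exercise every code
path with exhaustive oracles while keeping a full run in the tens of seconds.

## Known limitations

* Molecules completed by symmetry (Z' < 1 hosts) and polymeric/catenated
  components are detected and excluded, not analysed.
* The frame gauge assumes same-handed kernels across the family.
* Greedy shortest-basis reduction of the translation sublattice does not
  guarantee a minimal generating set for adversarial lattices (index-> 1
  sublattices); it is exact for the designed fixtures and typical cells.
* The catamer chain H-bond angle (157°) is flatter than experimental
  catamers (~167°); see above.
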