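# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `hydroforge`, and what the packaged tests do and do not
demonstrate.

## Model and assumptions

The method assumes all heavy atoms of the target are present and accurately
placed, with elements, formal charges and bond orders known (or derivable
from residue templates / the distance rule below).  Hydrogen positions are
then a local property of each heavy atom's bonding environment: bond
lengths and angles are nearly constant across molecules, so a hydrogen
arrangement observed once on a given environment transfers to every other
occurrence of that environment.  The environment is identified by the
library key (element, formal charge, chirality sign, sorted heavy-bond-order
tuple); geometric differences *within* one key — e.g. the ring-angle
difference between five- and six-membered sugar rings — are deliberately
ignored, and the acceptance suite measures that the resulting hydrogen error
(~0.02 Å for the packaged ring pair) stays below the ~0.08 Å mean C–H
vibration amplitude.

Only hydrogens on terminal heavy atoms have a genuine degree of freedom
(rotation about the single bond); these are optimized, everything else is
fixed by the fragment geometry.

## Key construction details

* **Canonical neighbor order**: heavy neighbors sort by (bond-order rank,
  element symbol), with rank single < partial double < aromatic < double <
  triple.  Aromatic is a distinct order symbol, never 1.5 or kekulized.
* **Chirality**: sign of the scalar triple product of the first three
  canonically ordered neighbor vectors, normalized; |volume| < 0.05 counts
  as planar (sign 0).  When the first three neighbors contain two with the
  same (order, element) descriptor, the sign would depend on input order
  (swapping the tied pair flips it), so such centers get sign 0; the
  superimposition's permutation search recovers the correct hydrogen side
  for near-tetrahedral tied centers, so placement accuracy is unaffected.
* **Partial double bonds**: a single N–X bond is relabeled when X carries a
  double or aromatic bond.  This runs identically on reference and target
  molecules, before fragmentation.

## Placement conventions

* Superimposition is rotation-only about the central atom (no centroid
  subtraction); Kabsch via SVD with the reflection-corrected determinant.
* Interchangeable neighbors (same order and element) are matched by
  exhaustive permutation within their group (≤ 4 neighbors ⇒ ≤ 24
  assignments); the minimum-RMSD assignment wins, first found on ties
  (tie threshold 1e-12 Å).
* Terminal atoms (one heavy neighbor) take the minimal rotation aligning
  the neighbor direction; the residual dihedral is anchored by rotating the
  first hydrogen anti to the lowest-index second-shell heavy atom, or to a
  hydrogen of the partner when no second-shell heavy atom exists.  This
  makes placement deterministic and exactly equivariant under rigid motions
  for every molecule whose heavy skeleton is not a point or a straight
  line; for point/line skeletons (water, methane, ethane, methylamine) the
  skeleton itself is axially symmetric and *no* deterministic placement can
  be equivariant — the arbitrary residual spin is later overridden by
  relaxation anyway.
* Isolated atoms (e.g. a lone water oxygen) use the identity rotation.
* Atoms whose key is absent from the library are reported as unassigned and
  receive no hydrogens; this is an expected outcome, not an error.

## Energy function and parameters

| parameter | value | unit | note |
|---|---|---|---|
| electrostatic constant | 332.067 | kcal·Å/(mol·e²) | Coulomb term prefactor |
| ε, δ per element | UFF table | kcal/mol, Å | H 0.044/2.886, C 0.105/3.851, N 0.069/3.660, O 0.060/3.500, S 0.274/4.035, … |
| donor–acceptor scale | 0.79 | – | multiplies δ_ij when both partners are polar |
| cutoff | 10 | Å | cell list with cell edge = cutoff |
| PEOE iterations | 6 | – | damping (1/2)^t is geometric; 6 suffice |

Combination rules: ε_ij geometric mean, δ_ij arithmetic mean.  A pair counts
as donor–acceptor when both ends are *polar*: N/O/S heavy atoms and
hydrogens bonded to them.  Elements without UFF parameters raise an error
naming the element; elements without PEOE parameters fall back to zero
charge with a warning.

Partial charges are computed by the PEOE scheme as implemented in biotite
(the iterative partial equalization of orbital electronegativities, seeded
from formal charges).  Biotite parametrizes kekulized aromatic bond types,
so generic aromatic orders are remapped to its aromatic-single type for the
charge computation only.  User-supplied per-atom charges bypass PEOE
entirely.

## Relaxation algorithm

Hill climbing in sweep order (ascending group index), one proposal per
group per sweep: rotate by +Δφ on even sweeps and −Δφ on odd sweeps
(Δφ = 10° default) for freely rotatable groups, by 180° for flip-restricted
groups.  A proposal is accepted iff the energy change over exactly the
interaction pairs involving that group's hydrogens — partners held fixed —
is strictly negative; accepted moves apply immediately (coordinate
descent).  Termination: two consecutive sweeps without any acceptance, or
100 sweeps with a warning.  The interaction set is built once from the
initial geometry and kept fixed: hydrogens move at most ~2 Å about their
axis, which the 10 Å cutoff absorbs.

The optional multistart mode reruns the climb from N seeded random initial
dihedral assignments (uniform angles for free groups, a random flip state
for flip groups) plus the unperturbed start, and returns the lowest-energy
outcome.  All randomness flows through one seed; given (model, parameters,
increment, seed) the result is deterministic.

Under an orthorhombic periodic box all distances use the minimum-image
convention and the cell list runs in periodic mode; energies are invariant
under shifting all coordinates by a lattice vector.

## Formal charges from pH

For amino-acid residues only: an acidic site is assigned −1 iff pH > pKa, a
basic site +1 iff pH < pKa, and pH = pKa keeps the neutral form.  The
packaged pKa values are the CRC Handbook free-amino-acid compilation
(Asp 3.65, Glu 4.25, His 6.00, Cys 8.18, Tyr 10.07, Lys 10.53, Arg 12.48;
generic termini 9.00/2.00); histidine is therefore neutral at pH 7.  The
charge sits on the conventional atom (OD2/OE2, ND1, SG, OH, NZ, NH1, N,
OXT).  The table is an argument of `assign_formal_charges` and fully
user-replaceable.  Fractional protonation, microenvironment pKa shifts and
non-amino-acid sites are out of scope.

## File formats

SDF and mmCIF round-trip all bond orders and formal charges exactly.  PDB
has no bond-order field; on write the repeated-CONECT convention encodes
orders 1–3 (a partner serial listed twice means a double bond), and reading
recovers them from CONECT multiplicity.  Aromatic and partial-double orders
cannot be expressed in PDB and degrade to a single entry.  Partial-double
is an internal relabel of a nominally single bond and is always written as
single; it is rederived after reading.  Bond perception for bond-less
inputs: Chemical Component Dictionary templates (via biotite's bundled CCD)
for known residues, including peptide/phosphodiester links, then the
distance rule D ≤ r_cov(a)+r_cov(b)+0.45 Å (Cordero radii, order single)
for everything the templates do not cover.

## Fixture molecules and what the tests show

The packaged fixtures are built at idealized geometry (sp3 109.471°, sp2
120°, planar regular aromatic rings, C–H 1.09 Å, O–H 0.96 Å, N–H 1.01 Å,
C–C 1.54/1.39 Å; water at the experimental 104.5°), so round-trip placement
errors measure the algorithm, not the data.  The set covers isolated
centers, free rotors, flip-restricted imine/guanidinium nitrogens, aromatic
rings with and without substituents, a chiral α-carbon, and a five-/
six-membered hydroxy-ring pair sharing a library key across different ring
geometries.  The C–OH hydrogen of the ring pair is placed opposite the
normalized sum of the heavy-neighbor directions: under the fully symmetric
tetrahedral completion the cross-ring comparison collapses to an exact
(zero-deviation) fit, whereas the sum rule carries the ring-strain
difference into the hydrogen direction and makes the comparison informative.

Idealized fixtures do not emulate experimental coordinate noise,
crystal-contact hydrogen-bond networks, alternate conformations or
metal-coordination environments; passing tests therefore demonstrate
correctness of the machinery, not prediction accuracy on experimental
structures.  Synthetic many-molecule systems for the energy tests place
randomly oriented ethanol copies on a jittered 6 Å grid — dense enough for
thousands of interaction pairs, without the unphysical sub-Å clashes that
uniform random placement produces (whose near-singular Lennard-Jones terms
would dominate any energy comparison numerically).

Problem sizes used by the test suite and the acceptance script — ~300-atom
systems for the incremental-energy check, ~500-atom systems for the
cell-list check, 200 point sets × 1000 rotations for superimposition, a
36-point grid for the rotor — are desk-scale choices that keep the whole
suite in the tens-of-seconds range while exercising every code path.

## Known limitations

* One fragment geometry per key (last-wins); no selection among reference
  geometries.
* Hill climbing is local; the multistart option mitigates but does not
  guarantee global optima for coupled rotor networks.
* pH handling covers amino acids only, as an all-or-nothing assignment.
* PDB cannot express aromatic bond orders (format limitation).
* Prochiral hydrogen naming (HB2 vs HB3 style) follows placement order, not
  geometry.
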