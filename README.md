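# hydroforge

Most experimentally determined biomolecular structures — and the output of
many docking and coarse simulation tools — lack hydrogen atoms, because
hydrogens scatter X-rays too weakly to be resolved.  Analyses that depend on
them (hydrogen-bond detection, molecular dynamics setup, pKa-aware modeling)
therefore need the missing hydrogens predicted from the heavy-atom skeleton.
`hydroforge` does this for arbitrary organic molecules, from single ligands
to macromolecules, without per-molecule force-field parametrization.

## Method

**Fragment library.** Every reference molecule with known hydrogen positions
is split into one *fragment* per heavy atom: the central atom (translated to
the origin), its bonded heavy neighbors, and its hydrogens.  Each fragment is
indexed by a hashable *library key*

> (central element, central formal charge, chirality sign,
> canonically sorted heavy-bond-order tuple)

Hydrogens are not part of the key, so a hydrogen-free target atom forms the
same key as its protonated reference.  Nitrogen atoms get special handling:
a nominally single N–X bond whose partner carries a double or aromatic bond
(amides, guanidinium, anilines) is relabeled *partial double*, because the
nitrogen lone pair enforces a planar rather than pyramidal geometry.
Duplicate keys are resolved last-wins.

**Placement.** Each target heavy atom is matched against the library by key.
The library fragment is rotated about the origin to minimize the RMSD
between the two heavy-neighbor sets (Kabsch/SVD, trying all permutations of
interchangeable neighbors), and the rotated library hydrogens are translated
to the target atom's position.

**Relaxation.** Hydrogens on *terminal* heavy atoms (one heavy neighbor —
hydroxyls, methyls, amines) remain ambiguous up to rotation about the bond.
Their dihedrals are optimized by alternating-direction hill climbing over a
non-bonded energy

    V(i,j) = 332.067 q_i q_j / D_ij
             + ε_ij [ (δ_ij/D_ij)^12 − 2 (δ_ij/D_ij)^6 ]

with ε_ij = √(ε_i ε_j) and δ_ij = (δ_i+δ_j)/2 from the per-element Universal
Force Field table, δ_ij scaled by 0.79 for hydrogen-bond donor–acceptor
pairs, a 10 Å cutoff with a linear-time cell list, and PEOE (Gasteiger)
partial charges q.  Groups attached by a (partial) double bond — imines,
guanidinium NH₂ — are restricted to 180° flips.  Each proposed step is
accepted iff the isolated energy change of that group's hydrogens is
negative; the run stops after two sweeps without acceptance.

Formal charges of amino-acid residues can optionally be recalculated from a
user-supplied pH against tabulated free-amino-acid pKa values before
fragmentation, so that e.g. a deprotonated carboxylate receives no hydrogen.

## Worked example

```python
import hydroforge as hf

toluene = hf.make_molecule("toluene").without_hydrogens()
hf.write_structure(toluene, "toluene_heavy.sdf", format="sdf")

model = hf.read_structure("toluene_heavy.sdf")
model, unassigned = hf.add_hydrogens(model, seed=0)
print("atoms:", model.n_atoms)
print("hydrogens added:", int(model.is_hydrogen.sum()))
print("unassigned heavy atoms:", sorted(unassigned))
print("names:", model.atom_name.tolist())
```

prints

```
atoms: 15
hydrogens added: 8
unassigned heavy atoms: []
names: ['C1', 'C2', 'C3', 'C4', 'C5', 'C6', 'C7', 'H2', 'H3', 'H4', 'H5', 'H6', 'H71', 'H72', 'H73']
```

All seven heavy atoms of toluene found a matching fragment in the packaged
library; five ring CH hydrogens and a three-hydrogen methyl rotor were
added, hydrogens were renamed after their bonded heavy atom and reordered
behind the heavy atoms of the residue.  The same pipeline from the shell:

```
$ hydroforge -i toluene_heavy.sdf -o toluene_h.sdf -v
INFO read 7 atoms from toluene_heavy.sdf
INFO fragments matched: 7/7, hydrogens now present: 8
INFO relaxed 1 rotatable group(s) in 7 sweep(s); final interaction energy 1.0150 kcal/mol
INFO wrote 15 atoms to toluene_h.sdf
```

Useful flags: `--ph 7.0` (recalculate amino-acid formal charges),
`--no-relax`, `--fragments extra.sdf` (extend the library; later molecules
override on key collision), `--charges FILE` (bypass PEOE),
`--keep-hydrogens`, `--multistart N --seed S`.

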