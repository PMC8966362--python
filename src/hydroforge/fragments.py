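"""Fragment decomposition and the fragment library.

A molecule is split into one *fragment* per heavy atom: the central atom
(translated to the origin), its bonded heavy neighbors, the orders of the
bonds to them, and — for reference molecules — the bonded hydrogens.  The
hashable *library key* of a fragment is

    (central element, central formal charge, chirality sign,
     canonically sorted heavy-bond-order tuple)

Hydrogens never enter the key, so a hydrogen-free target atom maps to the
same key as the fully protonated reference atom.

Canonical neighbor order sorts heavy neighbors by (bond-order rank, element
symbol) with rank single < partial double < aromatic < double < triple.
The chirality sign is the sign of the scalar triple product of the first
three canonically ordered neighbor vectors.  When two of those neighbors
have identical (order, element) descriptors the sign would flip under their
swap, so no input-order-independent nonzero sign exists; such centers get
sign 0 and the residual correspondence ambiguity is resolved during
superimposition by permutation search.

The library maps keys to fragments with *last-wins* semantics: inserting a
duplicate key replaces the stored coordinates.  Different heavy-atom
geometries sharing a key (e.g. the ring CH carbons of five- and
six-membered sugar rings) are deliberately not distinguished.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .model import BOND_ORDER_RANK, BondOrder, MolecularModel

__all__ = [
    "FragmentKey",
    "Fragment",
    "FragmentLibrary",
    "relabel_partial_double_bonds",
    "compute_chirality",
    "fragment_molecule",
    "build_library",
    "PLANARITY_TOLERANCE",
]

#: |normalized triple product| below which a center counts as planar.
PLANARITY_TOLERANCE = 0.05

LIBRARY_FORMAT_VERSION = 1


@dataclass(frozen=True)
class FragmentKey:
    """Hashable identity of a heavy-atom environment."""

    element: str
    charge: int
    chirality: int
    bond_orders: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "bond_orders", tuple(int(o) for o in self.bond_orders))


@dataclass
class Fragment:
    """One heavy atom's environment, central atom at the origin.

    ``neighbor_coord`` rows follow the canonical neighbor order;
    ``neighbor_descriptors`` holds the matching (order-rank, element) pairs
    used to group interchangeable neighbors during superimposition.
    ``hydrogen_coord`` is empty for target fragments.
    """

    key: FragmentKey
    neighbor_coord: np.ndarray          # (k, 3)
    hydrogen_coord: np.ndarray          # (h, 3)
    neighbor_descriptors: tuple[tuple[int, str], ...]
    center_index: int = -1              # atom index in the source molecule

    def __post_init__(self):
        self.neighbor_coord = np.asarray(
            self.neighbor_coord, dtype=np.float64
        ).reshape(-1, 3)
        self.hydrogen_coord = np.asarray(
            self.hydrogen_coord, dtype=np.float64
        ).reshape(-1, 3)
        if len(self.neighbor_coord) != len(self.key.bond_orders):
            raise ValueError("neighbor count does not match key order tuple")


# ----------------------------------------------------------------------
def relabel_partial_double_bonds(model: MolecularModel) -> MolecularModel:
    """Mark nitrogen single bonds with double-bond character.

    Every single bond from a nitrogen to a neighbor that itself carries a
    double or aromatic bond (amide C(=O)-N, guanidinium N-C(=N), aromatic
    amines) is relabeled :attr:`BondOrder.PARTIAL_DOUBLE`.  The nitrogen
    lone pair conjugates into the neighboring pi system, so these nominally
    single bonds enforce a planar geometry; the distinct order symbol keeps
    planar and pyramidal nitrogen environments apart in library keys.

    Applied identically to reference and target molecules, before
    fragmentation.
    """
    model = model.copy()
    bonds = model.bonds
    if not len(bonds):
        return model
    has_pi = np.zeros(model.n_atoms, dtype=bool)
    for a, b, o in bonds:
        if BondOrder(o) in (BondOrder.DOUBLE, BondOrder.AROMATIC):
            has_pi[a] = True
            has_pi[b] = True
    new_orders = bonds[:, 2].copy()
    for row, (a, b, o) in enumerate(bonds):
        if BondOrder(o) is not BondOrder.SINGLE:
            continue
        for n, x in ((a, b), (b, a)):
            if model.element[n] == "N" and has_pi[x]:
                new_orders[row] = int(BondOrder.PARTIAL_DOUBLE)
                break
    model.bonds = np.column_stack([bonds[:, 0], bonds[:, 1], new_orders])
    return model


def compute_chirality(
    neighbor_vectors, tolerance: float = PLANARITY_TOLERANCE
) -> int:
    """Ternary chirality sign of an ordered set of neighbor vectors.

    Returns the sign of the scalar triple product ``v1 . (v2 x v3)`` of the
    first three vectors, normalized by their lengths; 0 for fewer than three
    neighbors or when the normalized volume is below ``tolerance``
    (near-planar sp2 centers).
    """
    vectors = np.asarray(neighbor_vectors, dtype=np.float64).reshape(-1, 3)
    if len(vectors) < 3:
        return 0
    v1, v2, v3 = vectors[:3]
    norms = np.linalg.norm(v1) * np.linalg.norm(v2) * np.linalg.norm(v3)
    if norms == 0:
        return 0
    volume = float(np.dot(v1, np.cross(v2, v3))) / norms
    if abs(volume) < tolerance:
        return 0
    return 1 if volume > 0 else -1


def _canonical_heavy_neighbors(model, center, heavy_adj):
    """Heavy neighbors of ``center`` in canonical order.

    Returns (indices, descriptors) where descriptors are
    (order-rank, element) tuples, sorted ascending; ties keep input order
    (resolved later by permutation search).
    """
    entries = [
        ((BOND_ORDER_RANK[BondOrder(o)], str(model.element[j])), j, int(o))
        for j, o in heavy_adj[center]
    ]
    entries.sort(key=lambda e: e[0])
    descriptors = tuple(e[0] for e in entries)
    indices = [e[1] for e in entries]
    orders = tuple(e[2] for e in entries)
    return indices, descriptors, orders


def _key_chirality(model, center, nbr_indices, descriptors) -> int:
    """Chirality entering the library key.

    Zero when the first three canonical descriptors contain a tie: the
    triple-product sign would depend on the order in which the tied
    neighbors were listed, and keys must not depend on atom input order.
    """
    if len(nbr_indices) < 3:
        return 0
    d = descriptors
    if d[0] == d[1] or d[1] == d[2] or (len(d) > 3 and d[2] == d[3]):
        return 0
    vectors = model.coord[nbr_indices[:3]] - model.coord[center]
    return compute_chirality(vectors)


def fragment_molecule(
    model: MolecularModel, with_hydrogens: bool = False
) -> list[Fragment]:
    """Split a molecule into one fragment per heavy atom.

    Bonds must be assigned and :func:`relabel_partial_double_bonds` already
    applied.  Coordinates are translated so the central atom sits at the
    origin.  Hydrogens are included only when ``with_hydrogens`` and
    present in the model.
    """
    adj = model.neighbors()
    heavy_adj = model.heavy_neighbors(adj)
    is_h = model.is_hydrogen
    fragments = []
    for center in range(model.n_atoms):
        if is_h[center]:
            continue
        nbr_idx, descriptors, orders = _canonical_heavy_neighbors(
            model, center, heavy_adj
        )
        key = FragmentKey(
            element=str(model.element[center]),
            charge=int(model.formal_charge[center]),
            chirality=_key_chirality(model, center, nbr_idx, descriptors),
            bond_orders=orders,
        )
        origin = model.coord[center]
        nbr_coord = model.coord[nbr_idx] - origin if nbr_idx else np.empty((0, 3))
        if with_hydrogens:
            h_idx = [j for j, _ in adj[center] if is_h[j]]
            h_coord = model.coord[h_idx] - origin if h_idx else np.empty((0, 3))
        else:
            h_coord = np.empty((0, 3))
        fragments.append(
            Fragment(key, nbr_coord, h_coord, descriptors, center_index=center)
        )
    return fragments


# ----------------------------------------------------------------------
class FragmentLibrary:
    """Mapping from :class:`FragmentKey` to reference :class:`Fragment`.

    Insertion follows last-wins semantics: adding a fragment under an
    existing key replaces the stored one.
    """

    def __init__(self):
        self._entries: dict[FragmentKey, Fragment] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: FragmentKey) -> bool:
        return key in self._entries

    def keys(self):
        return self._entries.keys()

    def add(self, fragment: Fragment) -> None:
        self._entries[fragment.key] = fragment

    def add_molecule(self, model: MolecularModel) -> None:
        """Fragment a reference molecule (hydrogens and bonds required for
        useful entries) and insert all fragments."""
        model = relabel_partial_double_bonds(model)
        for fragment in fragment_molecule(model, with_hydrogens=True):
            self.add(fragment)

    def lookup(self, key: FragmentKey) -> Fragment | None:
        """Exact-key lookup; ``None`` signals a miss (not an error)."""
        return self._entries.get(key)

    # -- serialization -------------------------------------------------
    def save(self, path) -> None:
        """Write the library to a versioned JSON file (float32 precision)."""
        entries = []
        for key, frag in self._entries.items():
            entries.append({
                "element": key.element,
                "charge": key.charge,
                "chirality": key.chirality,
                "bond_orders": list(key.bond_orders),
                "descriptors": [[r, e] for r, e in frag.neighbor_descriptors],
                "neighbor_coord": np.asarray(
                    frag.neighbor_coord, dtype=np.float32
                ).tolist(),
                "hydrogen_coord": np.asarray(
                    frag.hydrogen_coord, dtype=np.float32
                ).tolist(),
            })
        with open(str(path), "w") as f:
            json.dump({"format_version": LIBRARY_FORMAT_VERSION,
                       "entries": entries}, f)

    @classmethod
    def load(cls, path) -> "FragmentLibrary":
        with open(str(path)) as f:
            data = json.load(f)
        version = data.get("format_version")
        if version != LIBRARY_FORMAT_VERSION:
            raise ValueError(f"unsupported library format version {version!r}")
        library = cls()
        for e in data["entries"]:
            key = FragmentKey(
                e["element"], int(e["charge"]), int(e["chirality"]),
                tuple(e["bond_orders"]),
            )
            library.add(Fragment(
                key,
                np.asarray(e["neighbor_coord"], dtype=np.float64).reshape(-1, 3),
                np.asarray(e["hydrogen_coord"], dtype=np.float64).reshape(-1, 3),
                tuple((int(r), str(el)) for r, el in e["descriptors"]),
            ))
        return library


def build_library(models) -> FragmentLibrary:
    """Compile reference molecules into a fragment library (iteration
    order; duplicate keys keep the later molecule's coordinates)."""
    library = FragmentLibrary()
    for model in models:
        library.add_molecule(model)
    return library
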