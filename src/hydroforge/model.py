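"""Molecular data model.

A :class:`MolecularModel` is the single structure currency of the package:
a flat table of atoms (element, name, residue, Cartesian coordinates in Å,
integer formal charge) plus a bond table with explicit bond orders and an
optional orthorhombic box for periodic systems.

Bond orders are represented by :class:`BondOrder`.  Besides the chemical
orders (single/double/triple/aromatic) there is a *partial double* order:
a nominally single bond from a nitrogen whose partner carries a double or
aromatic bond (amides, guanidinium, anilines).  The nitrogen lone pair gives
such bonds double-bond character and a planar geometry, so they are kept
distinct when fragment identities are built.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BondOrder", "MolecularModel", "ModelError", "COVALENT_RADII"]


class ModelError(ValueError):
    """Raised when a model violates its structural invariants."""


class BondOrder(enum.IntEnum):
    SINGLE = 1
    DOUBLE = 2
    TRIPLE = 3
    AROMATIC = 4
    PARTIAL_DOUBLE = 5


#: Rank used for canonical sorting of bonds in fragment keys:
#: single < partial double < aromatic < double < triple.
BOND_ORDER_RANK = {
    BondOrder.SINGLE: 0,
    BondOrder.PARTIAL_DOUBLE: 1,
    BondOrder.AROMATIC: 2,
    BondOrder.DOUBLE: 3,
    BondOrder.TRIPLE: 4,
}

# Covalent radii (Å), Cordero et al. consensus values; used only by the
# distance fallback of bond perception.
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "NA": 1.66, "MG": 1.41, "SI": 1.11, "P": 1.07, "S": 1.05, "CL": 1.02,
    "K": 2.03, "CA": 1.76, "MN": 1.39, "FE": 1.32, "CU": 1.32, "ZN": 1.22,
    "SE": 1.20, "BR": 1.20, "I": 1.39,
}

_KNOWN_ELEMENTS = frozenset(COVALENT_RADII) | {
    "HE", "LI", "BE", "NE", "AL", "AR", "SC", "TI", "V", "CR", "CO", "NI",
    "GA", "GE", "AS", "KR", "RB", "SR", "MO", "RU", "RH", "PD", "AG", "CD",
    "SN", "SB", "TE", "XE", "CS", "BA", "W", "PT", "AU", "HG", "PB", "BI",
}


@dataclass
class MolecularModel:
    """Heavy-atom (or fully protonated) molecular model.

    Attributes
    ----------
    element : (n,) array of str
        Upper-case element symbols.
    atom_name : (n,) array of str
    res_name, res_id, chain_id : per-atom residue annotation.
    coord : (n, 3) float64 array, Å.
    formal_charge : (n,) int array, elementary charges.
    is_hetero : (n,) bool array.
    bonds : (m, 3) int array
        Rows ``(a, b, order)`` with 0-based atom indices and
        :class:`BondOrder` values; each unordered pair stored once.
    box : optional (3,) float64 array
        Edge lengths of an orthorhombic periodic box, Å.
    """

    element: np.ndarray
    atom_name: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    coord: np.ndarray
    formal_charge: np.ndarray
    is_hetero: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))
    box: np.ndarray | None = None

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        element,
        coord,
        *,
        atom_name=None,
        res_name=None,
        res_id=None,
        chain_id=None,
        formal_charge=None,
        is_hetero=None,
        bonds=None,
        box=None,
    ) -> "MolecularModel":
        element = np.asarray([str(e).upper() for e in element], dtype="U4")
        n = len(element)
        coord = np.asarray(coord, dtype=np.float64).reshape(n, 3)
        if atom_name is None:
            counts: dict[str, int] = {}
            names = []
            for e in element:
                counts[e] = counts.get(e, 0) + 1
                names.append(f"{e}{counts[e]}")
            atom_name = names
        atom_name = np.asarray(atom_name, dtype="U6")
        res_name = np.asarray(
            ["UNL"] * n if res_name is None else res_name, dtype="U5"
        )
        res_id = np.asarray(
            np.ones(n, dtype=np.int64) if res_id is None else res_id, dtype=np.int64
        )
        chain_id = np.asarray(["A"] * n if chain_id is None else chain_id, dtype="U4")
        formal_charge = np.asarray(
            np.zeros(n, dtype=np.int64) if formal_charge is None else formal_charge,
            dtype=np.int64,
        )
        is_hetero = np.asarray(
            np.zeros(n, dtype=bool) if is_hetero is None else is_hetero, dtype=bool
        )
        if bonds is None or len(bonds) == 0:
            bonds = np.empty((0, 3), dtype=np.int64)
        bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 3)
        if box is not None:
            box = np.asarray(box, dtype=np.float64).reshape(3)
        model = cls(
            element, atom_name, res_name, res_id, chain_id, coord,
            formal_charge, is_hetero, bonds, box,
        )
        model.validate()
        return model

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.element)

    @property
    def is_hydrogen(self) -> np.ndarray:
        return self.element == "H"

    def copy(self) -> "MolecularModel":
        return MolecularModel(
            self.element.copy(), self.atom_name.copy(), self.res_name.copy(),
            self.res_id.copy(), self.chain_id.copy(), self.coord.copy(),
            self.formal_charge.copy(), self.is_hetero.copy(), self.bonds.copy(),
            None if self.box is None else self.box.copy(),
        )

    def validate(self) -> None:
        n = self.n_atoms
        if not np.all(np.isfinite(self.coord)):
            raise ModelError("non-finite coordinates")
        bad = [e for e in np.unique(self.element) if e not in _KNOWN_ELEMENTS]
        if bad:
            raise ModelError(f"unknown element symbol(s): {bad}")
        if len(self.bonds):
            a, b = self.bonds[:, 0], self.bonds[:, 1]
            if a.min(initial=0) < 0 or max(a.max(initial=-1), b.max(initial=-1)) >= n:
                raise ModelError("bond index out of range")
            if np.any(a == b):
                raise ModelError("self-bond in bond table")
            lo, hi = np.minimum(a, b), np.maximum(a, b)
            pairs = set(zip(lo.tolist(), hi.tolist()))
            if len(pairs) != len(self.bonds):
                raise ModelError("duplicate bond pair in bond table")
            try:
                [BondOrder(o) for o in self.bonds[:, 2]]
            except ValueError as exc:
                raise ModelError(f"invalid bond order: {exc}") from None
        # each hydrogen bonds exactly once, to a heavy atom
        h_idx = np.where(self.is_hydrogen)[0]
        if len(h_idx) and len(self.bonds):
            adj = self.neighbors()
            for h in h_idx:
                nb = adj[h]
                if len(nb) != 1 or self.element[nb[0][0]] == "H":
                    raise ModelError(
                        f"hydrogen atom {h} must have exactly one bond to a heavy atom"
                    )
        elif len(h_idx) and not len(self.bonds) and n > len(h_idx):
            # hydrogens without any bond table: tolerated only for
            # freshly read files, validate() of bonded pipelines re-checks
            pass

    # ------------------------------------------------------------------
    # connectivity helpers
    # ------------------------------------------------------------------
    def neighbors(self) -> list[list[tuple[int, int]]]:
        """Adjacency list: ``adj[i]`` is a list of ``(j, order)`` tuples."""
        adj: list[list[tuple[int, int]]] = [[] for _ in range(self.n_atoms)]
        for a, b, order in self.bonds:
            adj[a].append((int(b), int(order)))
            adj[b].append((int(a), int(order)))
        return adj

    def heavy_neighbors(self, adj=None) -> list[list[tuple[int, int]]]:
        """Adjacency restricted to heavy (non-hydrogen) partners."""
        if adj is None:
            adj = self.neighbors()
        is_h = self.is_hydrogen
        return [
            [(j, o) for j, o in nb if not is_h[j]] for nb in adj
        ]

    def total_formal_charge(self) -> int:
        return int(self.formal_charge.sum())

    def select(self, indices) -> "MolecularModel":
        """Sub-model of the given atoms; bonds re-indexed, cross bonds dropped."""
        indices = np.asarray(indices, dtype=np.int64)
        remap = -np.ones(self.n_atoms, dtype=np.int64)
        remap[indices] = np.arange(len(indices))
        new_bonds = []
        for a, b, o in self.bonds:
            if remap[a] >= 0 and remap[b] >= 0:
                new_bonds.append((remap[a], remap[b], o))
        return MolecularModel(
            self.element[indices], self.atom_name[indices],
            self.res_name[indices], self.res_id[indices], self.chain_id[indices],
            self.coord[indices], self.formal_charge[indices],
            self.is_hetero[indices],
            np.asarray(new_bonds, dtype=np.int64).reshape(-1, 3),
            None if self.box is None else self.box.copy(),
        )

    def without_hydrogens(self) -> "MolecularModel":
        return self.select(np.where(~self.is_hydrogen)[0])

    def reorder(self, permutation) -> "MolecularModel":
        """Apply an atom permutation; ``permutation[k]`` is the old index
        of the atom placed at new position ``k``."""
        permutation = np.asarray(permutation, dtype=np.int64)
        if sorted(permutation.tolist()) != list(range(self.n_atoms)):
            raise ModelError("reorder requires a permutation of all atom indices")
        inverse = np.empty_like(permutation)
        inverse[permutation] = np.arange(self.n_atoms)
        bonds = self.bonds.copy()
        if len(bonds):
            bonds[:, 0] = inverse[bonds[:, 0]]
            bonds[:, 1] = inverse[bonds[:, 1]]
        return MolecularModel(
            self.element[permutation], self.atom_name[permutation],
            self.res_name[permutation], self.res_id[permutation],
            self.chain_id[permutation], self.coord[permutation],
            self.formal_charge[permutation], self.is_hetero[permutation],
            bonds, None if self.box is None else self.box.copy(),
        )

    def add_atoms(
        self, element, coord, *, bond_to=None, orders=None,
        atom_name=None, formal_charge=None,
    ) -> "MolecularModel":
        """Return a new model with atoms appended at the end.

        ``bond_to[k]`` is the existing-atom index the k-th new atom is bonded
        to (``None`` entries add no bond).  Residue annotation is inherited
        from the bonding partner, or from the last atom if unbonded.
        """
        element = np.asarray([str(e).upper() for e in element], dtype="U4")
        k = len(element)
        coord = np.asarray(coord, dtype=np.float64).reshape(k, 3)
        n = self.n_atoms
        if bond_to is None:
            bond_to = [None] * k
        if orders is None:
            orders = [BondOrder.SINGLE] * k
        anchor = [bt if bt is not None else n - 1 for bt in bond_to]
        res_name = self.res_name[anchor]
        res_id = self.res_id[anchor]
        chain_id = self.chain_id[anchor]
        hetero = self.is_hetero[anchor]
        if atom_name is None:
            atom_name = [f"{e}{n + i + 1}" for i, e in enumerate(element)]
        if formal_charge is None:
            formal_charge = np.zeros(k, dtype=np.int64)
        new_bonds = [
            (bt, n + i, int(o))
            for i, (bt, o) in enumerate(zip(bond_to, orders))
            if bt is not None
        ]
        bonds = np.vstack([
            self.bonds.reshape(-1, 3),
            np.asarray(new_bonds, dtype=np.int64).reshape(-1, 3),
        ])
        return MolecularModel(
            np.concatenate([self.element, element]),
            np.concatenate([self.atom_name, np.asarray(atom_name, dtype="U6")]),
            np.concatenate([self.res_name, res_name]),
            np.concatenate([self.res_id, res_id]),
            np.concatenate([self.chain_id, chain_id]),
            np.vstack([self.coord, coord]),
            np.concatenate([self.formal_charge, np.asarray(formal_charge, dtype=np.int64)]),
            np.concatenate([self.is_hetero, hetero]),
            bonds,
            None if self.box is None else self.box.copy(),
        )
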