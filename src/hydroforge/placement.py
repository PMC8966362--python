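"""Rotational superimposition of library fragments and hydrogen placement.

For every heavy atom of the target, the matching library fragment is rotated
about the coordinate origin so that its heavy-neighbor coordinates fit the
target's (Kabsch/SVD, reflection-corrected), the winning rotation is applied
to the library hydrogens, and the hydrogens are translated back to the
target atom's position.  No centering step is performed — the central atom
defines the origin on both sides.

Neighbors with identical (bond order, element) descriptors are
interchangeable; all permutations within such groups are tried and the
minimum-RMSD assignment kept (first found wins on ties).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .fragments import FragmentLibrary, fragment_molecule
from .model import MolecularModel

__all__ = ["RigidTransform", "superimpose", "place_hydrogens"]


@dataclass
class RigidTransform:
    """Rotation (about the origin) followed by a translation."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation matrix is a reflection (det -1)")

    def apply(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation


def _minimal_rotation(u, v) -> np.ndarray:
    """Rotation with smallest angle mapping direction u onto direction v."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, v))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate by pi about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    axis = axis / s
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def superimpose(fixed, mobile) -> tuple[RigidTransform, float]:
    """Rotation about the origin minimizing the RMSD of ``mobile`` onto
    ``fixed``.

    Both point sets are origin-centered fragment coordinates of equal
    cardinality; no centroid subtraction is performed.  Uses the Kabsch
    algorithm (SVD of the covariance, smallest singular axis flipped when
    the raw solution would be a reflection).  For a single point the
    minimal rotation aligning the directions is returned; for empty sets
    the identity.

    Returns
    -------
    (RigidTransform, float)
        Transform with zero translation, and the achieved RMSD in Å.
    """
    fixed = np.asarray(fixed, dtype=np.float64).reshape(-1, 3)
    mobile = np.asarray(mobile, dtype=np.float64).reshape(-1, 3)
    if fixed.shape != mobile.shape:
        raise ValueError("point sets must have equal cardinality")
    n = len(fixed)
    if n == 0:
        return RigidTransform(), 0.0
    if n == 1:
        rotation = _minimal_rotation(mobile[0], fixed[0])
    else:
        covariance = mobile.T @ fixed
        u, _, vt = np.linalg.svd(covariance)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = mobile @ rotation.T - fixed
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return RigidTransform(rotation=rotation), rmsd


def _descriptor_permutations(descriptors):
    """All index permutations exchanging only same-descriptor neighbors."""
    groups: dict[tuple, list[int]] = {}
    for i, d in enumerate(descriptors):
        groups.setdefault(d, []).append(i)
    per_group = [list(itertools.permutations(g)) for g in groups.values()]
    for combo in itertools.product(*per_group):
        perm = [0] * len(descriptors)
        for positions, permuted in zip(groups.values(), combo):
            for slot, src in zip(positions, permuted):
                perm[slot] = src
        yield perm


def _best_superimposition(target_coord, library_fragment):
    """Minimum-RMSD rotation over all admissible neighbor correspondences."""
    best = None
    for perm in _descriptor_permutations(library_fragment.neighbor_descriptors):
        transform, rmsd = superimpose(
            target_coord, library_fragment.neighbor_coord[perm]
        )
        if best is None or rmsd < best[1] - 1e-12:
            best = (transform, rmsd)
    return best


def _anchor_dihedral(
    model, center, neighbor, heavy_adj, rotation, library_fragment,
    partner_hydrogens=None,
):
    """Fix the residual dihedral freedom of a single-neighbor fragment.

    The minimal rotation aligning the one neighbor direction leaves the
    hydrogens free to spin about the bond.  To make placement deterministic
    — and equivariant under rigid motions wherever the molecule provides a
    reference — the first hydrogen is rotated about the bond axis to sit
    anti (dihedral 180°) to a second-shell reference: the lowest-index
    heavy neighbor of the bonded partner, or failing that a hydrogen of the
    partner (giving staggered conformers on H3C-XH_n skeletons).  A
    molecule whose heavy skeleton is a straight line has no such reference
    for its first group; the minimal rotation is kept there (the skeleton
    itself is axially symmetric, so no equivariant choice exists), and
    relaxation later optimizes the angle anyway.
    """
    if len(library_fragment.hydrogen_coord) == 0:
        return rotation
    second_shell = [b for b, _ in heavy_adj[neighbor] if b != center]
    if second_shell:
        reference_coord = model.coord[min(second_shell)]
    elif partner_hydrogens is not None and len(partner_hydrogens):
        reference_coord = partner_hydrogens[0]
    else:
        return rotation
    axis = model.coord[neighbor] - model.coord[center]
    axis = axis / np.linalg.norm(axis)

    def perp(v):
        return v - np.dot(v, axis) * axis

    r_perp = perp(reference_coord - model.coord[neighbor])
    h_perp = perp(library_fragment.hydrogen_coord[0] @ rotation.T)
    if np.linalg.norm(r_perp) < 1e-8 or np.linalg.norm(h_perp) < 1e-8:
        return rotation
    target_dir = -r_perp / np.linalg.norm(r_perp)      # anti position
    current_dir = h_perp / np.linalg.norm(h_perp)
    cos_a = np.clip(np.dot(current_dir, target_dir), -1.0, 1.0)
    sin_a = float(np.dot(np.cross(current_dir, target_dir), axis))
    angle = np.arctan2(sin_a, cos_a)
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    spin = np.eye(3) + s * K + (1.0 - c) * (K @ K)
    return spin @ rotation


def place_hydrogens(
    model: MolecularModel,
    library: FragmentLibrary,
    keep_existing: bool = True,
) -> tuple[MolecularModel, set[int]]:
    """Add hydrogen atoms to every heavy atom with a library match.

    Heavy atoms that already carry hydrogens are skipped when
    ``keep_existing`` (their hydrogens are preserved); with
    ``keep_existing=False`` the model must have been stripped beforehand.
    Atoms whose key misses the library receive no hydrogens and are
    reported in the returned index set.

    Bonds must be assigned and partial-double relabeling applied.
    """
    is_h = model.is_hydrogen
    heavy_adj = model.heavy_neighbors()
    has_h = np.zeros(model.n_atoms, dtype=bool)
    for a, b, _ in model.bonds:
        if is_h[b]:
            has_h[a] = True
        if is_h[a]:
            has_h[b] = True

    unassigned: set[int] = set()
    new_coords: list[np.ndarray] = []
    new_bond_to: list[int] = []
    h_by_heavy: dict[int, list[np.ndarray]] = {}
    for a, b, _ in model.bonds:
        if is_h[b]:
            h_by_heavy.setdefault(int(a), []).append(model.coord[b])
        elif is_h[a]:
            h_by_heavy.setdefault(int(b), []).append(model.coord[a])
    for fragment in fragment_molecule(model, with_hydrogens=False):
        center = fragment.center_index
        if keep_existing and has_h[center]:
            continue
        library_fragment = library.lookup(fragment.key)
        if library_fragment is None:
            unassigned.add(center)
            continue
        if len(fragment.neighbor_coord) == 0:
            # isolated atom (e.g. water oxygen): any rotation is equally
            # valid before relaxation; use the identity
            rotation = np.eye(3)
        else:
            transform, _ = _best_superimposition(
                fragment.neighbor_coord, library_fragment
            )
            rotation = transform.rotation
            if len(fragment.neighbor_coord) == 1:
                neighbor = heavy_adj[center][0][0]
                rotation = _anchor_dihedral(
                    model, center, neighbor, heavy_adj, rotation,
                    library_fragment,
                    partner_hydrogens=h_by_heavy.get(neighbor),
                )
        h_coord = (
            library_fragment.hydrogen_coord @ rotation.T + model.coord[center]
        )
        for row in h_coord:
            new_coords.append(row)
            new_bond_to.append(center)
            h_by_heavy.setdefault(center, []).append(row)

    if not new_coords:
        return model.copy(), unassigned
    result = model.add_atoms(
        ["H"] * len(new_coords),
        np.asarray(new_coords),
        bond_to=new_bond_to,
        atom_name=[f"H{k+1}" for k in range(len(new_coords))],
    )
    return result, unassigned
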