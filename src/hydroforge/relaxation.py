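"""Dihedral relaxation of rotatable terminal groups.

After initial placement, hydrogens on *terminal* heavy atoms (exactly one
heavy neighbor) are ambiguous up to rotation about that bond.  Their
dihedral angles are optimized by alternating-direction hill climbing over a
non-bonded energy:

    V(i, j) = 332.067 q_i q_j / D_ij
              + eps_ij * ((delta_ij / D_ij)^12 - 2 (delta_ij / D_ij)^6)

with eps_ij = sqrt(eps_i eps_j) and delta_ij = (delta_i + delta_j)/2 from
the per-element Universal Force Field table, delta_ij scaled by 0.79 for
potential hydrogen-bond donor-acceptor pairs, energies in kcal/mol,
distances in Å, charges in elementary charges.  Interactions are evaluated
between every rotatable hydrogen and all atoms within a 10 Å cutoff (cell
list; minimum image under an orthorhombic periodic box), excluding partners
whose distance the rotation cannot change.

Each hill-climbing sweep proposes, for every group in ascending index
order, a step of +increment on even sweeps and -increment on odd sweeps
(180° for flip-restricted groups, i.e. terminal atoms attached by a double
or partial-double bond, as in imines and guanidinium); a proposal is
accepted — and applied immediately — iff the isolated energy change of that
group's hydrogens is negative.  Relaxation terminates once two consecutive
sweeps accept nothing.  An optional multistart mode restarts from seeded
random dihedral assignments and keeps the lowest-energy outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from biotite.structure import CellList

from .model import BondOrder, MolecularModel

__all__ = [
    "UFF_NONBONDED",
    "NonbondedParams",
    "RotatableGroup",
    "InteractionSet",
    "RelaxationResult",
    "find_rotatable_groups",
    "pair_energy",
    "interaction_pairs",
    "rotate_group",
    "delta_energy",
    "relax",
]

#: Universal Force Field non-bonded parameters per element:
#: (well depth eps, kcal/mol; optimal distance delta, Å).
UFF_NONBONDED: dict[str, tuple[float, float]] = {
    "H": (0.044, 2.886),
    "B": (0.180, 4.083),
    "C": (0.105, 3.851),
    "N": (0.069, 3.660),
    "O": (0.060, 3.500),
    "F": (0.050, 3.364),
    "NA": (0.030, 2.983),
    "MG": (0.111, 3.021),
    "SI": (0.402, 4.295),
    "P": (0.305, 4.147),
    "S": (0.274, 4.035),
    "CL": (0.227, 3.947),
    "K": (0.035, 3.812),
    "CA": (0.238, 3.399),
    "MN": (0.013, 2.961),
    "FE": (0.013, 2.912),
    "CU": (0.005, 3.495),
    "ZN": (0.124, 2.763),
    "SE": (0.291, 4.205),
    "BR": (0.251, 4.189),
    "I": (0.339, 4.500),
}

COULOMB_CONSTANT = 332.067       # kcal Å / (mol e²)
HBOND_SCALE = 0.79               # delta_ij scale for donor-acceptor pairs
DEFAULT_CUTOFF = 10.0            # Å

_POLAR_ELEMENTS = frozenset({"N", "O", "S"})


class ParameterError(KeyError):
    """Raised when an element has no UFF non-bonded parameters."""


@dataclass
class NonbondedParams:
    """Per-atom energy parameters for one model."""

    epsilon: np.ndarray              # (n,) kcal/mol
    delta: np.ndarray                # (n,) Å
    charges: np.ndarray              # (n,) elementary charges
    polar: np.ndarray                # (n,) bool: can be part of an H-bond
    coulomb_constant: float = COULOMB_CONSTANT
    hbond_scale: float = HBOND_SCALE
    cutoff: float = DEFAULT_CUTOFF

    @classmethod
    def from_model(
        cls, model: MolecularModel, charges, cutoff: float = DEFAULT_CUTOFF
    ) -> "NonbondedParams":
        """Build per-atom tables; ``charges`` are PEOE or user partial
        charges.  Errors loudly for elements outside the UFF table."""
        eps = np.empty(model.n_atoms)
        delta = np.empty(model.n_atoms)
        for i, e in enumerate(model.element):
            try:
                eps[i], delta[i] = UFF_NONBONDED[str(e)]
            except KeyError:
                raise ParameterError(
                    f"no UFF non-bonded parameters for element {e!r}"
                ) from None
        # polar: N/O/S heavy atoms, and hydrogens bonded to them
        polar = np.isin(model.element, list(_POLAR_ELEMENTS))
        is_h = model.is_hydrogen
        for a, b, _ in model.bonds:
            if is_h[a] and polar[b]:
                polar[a] = True
            if is_h[b] and polar[a]:
                polar[b] = True
        return cls(
            epsilon=eps,
            delta=delta,
            charges=np.asarray(charges, dtype=np.float64),
            polar=polar,
            cutoff=cutoff,
        )


@dataclass
class RotatableGroup:
    """One rotatable terminal group.

    ``mode`` is "free" (10° steps about a single bond) or "flip" (180°
    jumps, for terminal atoms attached by a double or partial-double bond).
    """

    terminal: int                    # terminal heavy atom index
    axis_partner: int                # its single heavy neighbor
    hydrogens: np.ndarray            # indices of the rotating hydrogens
    mode: str                        # "free" | "flip"
    dihedral_offset: float = 0.0     # radians, cumulative applied rotation


def find_rotatable_groups(model: MolecularModel) -> list[RotatableGroup]:
    """Identify rotatable terminal groups.

    A group is a heavy atom with exactly one heavy neighbor and at least
    one bonded hydrogen.  A single bond to the neighbor gives free
    rotation; a double or partial-double bond allows only 180° flips;
    triple bonds (hydrogen on the rotation axis) are excluded, as are
    hydrogens of atoms embedded in rings or chains (≥2 heavy neighbors).
    """
    adj = model.neighbors()
    is_h = model.is_hydrogen
    groups = []
    for atom in range(model.n_atoms):
        if is_h[atom]:
            continue
        heavy = [(j, o) for j, o in adj[atom] if not is_h[j]]
        hydrogens = [j for j, _ in adj[atom] if is_h[j]]
        if len(heavy) != 1 or not hydrogens:
            continue
        partner, order = heavy[0]
        order = BondOrder(order)
        if order is BondOrder.SINGLE:
            mode = "free"
        elif order in (BondOrder.DOUBLE, BondOrder.PARTIAL_DOUBLE):
            mode = "flip"
        else:
            continue
        groups.append(RotatableGroup(
            terminal=atom,
            axis_partner=partner,
            hydrogens=np.asarray(sorted(hydrogens), dtype=np.int64),
            mode=mode,
        ))
    return groups


# ----------------------------------------------------------------------
# energy
# ----------------------------------------------------------------------
def _displacement(coord_a, coord_b, box):
    """coord_b - coord_a, under minimum image if a box is given."""
    d = np.asarray(coord_b, dtype=np.float64) - np.asarray(coord_a, dtype=np.float64)
    if box is not None:
        d = d - box * np.round(d / box)
    return d


def pair_energy(
    q_i: float,
    q_j: float,
    element_i: str,
    element_j: str,
    D: float,
    is_donor_acceptor: bool = False,
    coulomb_constant: float = COULOMB_CONSTANT,
    hbond_scale: float = HBOND_SCALE,
    eps: float | None = None,
    delta: float | None = None,
) -> float:
    """Non-bonded energy of one atom pair at distance ``D`` Å, kcal/mol.

    Electrostatics plus Lennard-Jones with geometric-mean well depth and
    arithmetic-mean optimal distance from the UFF table; the optimal
    distance is scaled by 0.79 for hydrogen-bond donor-acceptor pairs.
    ``eps``/``delta`` override the combined UFF parameters (an ``eps`` of 0
    isolates the electrostatic term).
    """
    if D <= 0:
        raise ValueError("pair distance must be positive")
    try:
        eps_i, delta_i = UFF_NONBONDED[str(element_i).upper()]
        eps_j, delta_j = UFF_NONBONDED[str(element_j).upper()]
    except KeyError as exc:
        raise ParameterError(f"no UFF non-bonded parameters for element {exc}") from None
    if eps is None:
        eps = np.sqrt(eps_i * eps_j)
    if delta is None:
        delta = 0.5 * (delta_i + delta_j)
    if is_donor_acceptor:
        delta *= hbond_scale
    ratio6 = (delta / D) ** 6
    return coulomb_constant * q_i * q_j / D + eps * (ratio6 * ratio6 - 2 * ratio6)


@dataclass
class InteractionSet:
    """Precomputed interaction pairs of rotatable hydrogens.

    ``pairs`` holds unordered-unique (hydrogen, partner) rows; when both
    ends are rotatable hydrogens of different groups the pair is stored
    once.  ``eps``, ``delta`` and ``qq`` are the combined per-pair
    parameters (``delta`` already donor-acceptor scaled, ``qq`` already
    multiplied by the electrostatic constant).  ``group_pairs[k]`` indexes
    the rows involving hydrogens of group k.
    """

    pairs: np.ndarray                # (m, 2) int
    eps: np.ndarray                  # (m,)
    delta: np.ndarray                # (m,)
    qq: np.ndarray                   # (m,)
    group_pairs: list[np.ndarray] = field(default_factory=list)
    box: np.ndarray | None = None

    def energy(self, coord) -> float:
        """Total non-bonded energy over the stored pairs."""
        if len(self.pairs) == 0:
            return 0.0
        d = coord[self.pairs[:, 1]] - coord[self.pairs[:, 0]]
        if self.box is not None:
            d = d - self.box * np.round(d / self.box)
        dist = np.linalg.norm(d, axis=1)
        ratio6 = (self.delta / dist) ** 6
        return float(np.sum(self.qq / dist + self.eps * (ratio6**2 - 2 * ratio6)))


def interaction_pairs(
    model: MolecularModel,
    groups: list[RotatableGroup],
    params: NonbondedParams,
) -> InteractionSet:
    """All (rotatable hydrogen, partner) pairs within the cutoff.

    Uses a cell list with cell edge equal to the cutoff (periodic when the
    model carries a box), so the search is linear in system size; the
    result is identical to brute-force enumeration.  Partners whose
    distance is invariant under the group's rotation are excluded: the
    hydrogen's own terminal heavy atom, the axis partner, and sibling
    hydrogens of the same group.
    """
    if model.box is not None and np.any(model.box <= 0):
        raise ValueError("periodic box must have positive edge lengths")
    h_group = {}
    for k, g in enumerate(groups):
        for h in g.hydrogens:
            h_group[int(h)] = k
    rows = []
    if h_group:
        coord = np.asarray(model.coord, dtype=np.float64)
        box33 = None if model.box is None else np.diag(model.box)
        cell_list = CellList(
            coord.astype(np.float32),
            cell_size=params.cutoff,
            periodic=model.box is not None,
            box=None if box33 is None else box33.astype(np.float32),
        )
        for h, k in sorted(h_group.items()):
            g = groups[k]
            excluded = {h, int(g.terminal), int(g.axis_partner)}
            excluded.update(int(x) for x in g.hydrogens)
            near = cell_list.get_atoms(
                coord[h].astype(np.float32), radius=params.cutoff
            )
            near = near[near >= 0]
            for b in np.sort(near):
                b = int(b)
                if b in excluded:
                    continue
                # unordered-unique: skip the mirror entry of a pair of
                # rotatable hydrogens
                if b in h_group and b < h:
                    continue
                d = _displacement(coord[h], coord[b], model.box)
                if np.dot(d, d) <= params.cutoff**2:
                    rows.append((h, b))
    pairs = np.asarray(sorted(set(rows)), dtype=np.int64).reshape(-1, 2)
    i, j = pairs[:, 0], pairs[:, 1]
    eps = np.sqrt(params.epsilon[i] * params.epsilon[j])
    delta = 0.5 * (params.delta[i] + params.delta[j])
    donor_acceptor = params.polar[i] & params.polar[j]
    delta = np.where(donor_acceptor, delta * params.hbond_scale, delta)
    qq = params.coulomb_constant * params.charges[i] * params.charges[j]
    group_pairs = []
    for g in groups:
        members = set(int(x) for x in g.hydrogens)
        group_pairs.append(np.asarray([
            r for r in range(len(pairs))
            if int(pairs[r, 0]) in members or int(pairs[r, 1]) in members
        ], dtype=np.int64))
    return InteractionSet(
        pairs=pairs, eps=eps, delta=delta, qq=qq,
        group_pairs=group_pairs,
        box=None if model.box is None else model.box.copy(),
    )


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------
def _rotation_about_axis(axis, angle):
    axis = np.asarray(axis, dtype=np.float64)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("zero-length rotation axis")
    x, y, z = axis / norm
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def rotate_group(
    model: MolecularModel, group: RotatableGroup, angle: float
) -> np.ndarray:
    """Coordinates of the group's hydrogens rotated by ``angle`` (radians)
    about the axis-partner → terminal-atom bond.  The model is not
    modified; only the hydrogen coordinates are returned."""
    return rotated_hydrogen_coord(
        model.coord, group, angle, model.coord[group.hydrogens]
    )


def rotated_hydrogen_coord(coord, group, angle, h_coord):
    """Rotate ``h_coord`` about the group's bond axis by ``angle``."""
    pivot = coord[group.terminal]
    axis = coord[group.terminal] - coord[group.axis_partner]
    rot = _rotation_about_axis(axis, angle)
    return (np.asarray(h_coord, dtype=np.float64) - pivot) @ rot.T + pivot


def delta_energy(
    coord,
    group_index: int,
    proposed_h_coord,
    groups: list[RotatableGroup],
    interactions: InteractionSet,
) -> float:
    """Isolated energy change of moving one group's hydrogens.

    Sums, over exactly the interaction pairs that involve hydrogens of
    ``group_index``, the pair energy at the proposed hydrogen positions
    minus the pair energy at the current positions; all partner positions
    are held fixed.
    """
    rows = interactions.group_pairs[group_index]
    if len(rows) == 0:
        return 0.0
    group = groups[group_index]
    h_position = {int(h): r for r, h in enumerate(group.hydrogens)}
    pairs = interactions.pairs[rows]
    eps = interactions.eps[rows]
    delta = interactions.delta[rows]
    qq = interactions.qq[rows]
    coord = np.asarray(coord, dtype=np.float64)
    proposed = np.asarray(proposed_h_coord, dtype=np.float64)

    def pair_distances(h_coord_lookup):
        a = np.array([
            h_coord_lookup(int(i)) if int(i) in h_position else coord[int(i)]
            for i in pairs[:, 0]
        ])
        b = np.array([
            h_coord_lookup(int(j)) if int(j) in h_position else coord[int(j)]
            for j in pairs[:, 1]
        ])
        d = b - a
        if interactions.box is not None:
            d = d - interactions.box * np.round(d / interactions.box)
        return np.linalg.norm(d, axis=1)

    d_old = pair_distances(lambda h: coord[h])
    d_new = pair_distances(lambda h: proposed[h_position[h]])

    def energies(dist):
        ratio6 = (delta / dist) ** 6
        return qq / dist + eps * (ratio6**2 - 2 * ratio6)

    return float(np.sum(energies(d_new) - energies(d_old)))


# ----------------------------------------------------------------------
# hill climbing
# ----------------------------------------------------------------------
@dataclass
class RelaxationResult:
    """Diagnostics of one relaxation run."""

    model: MolecularModel
    n_sweeps: int = 0
    n_accepted: int = 0
    energy_trace: list[float] = field(default_factory=list)
    final_energy: float = 0.0
    converged: bool = True


def _hill_climb(coord, groups, interactions, increment, max_iterations):
    """Alternating-direction coordinate-descent; mutates ``coord`` hydrogen
    rows in place.  Returns (n_sweeps, energy_trace, converged)."""
    trace = [interactions.energy(coord)]
    rejection_sweeps = 0
    sweep = 0
    converged = False
    while sweep < max_iterations:
        sign = 1.0 if sweep % 2 == 0 else -1.0
        accepted_any = False
        for k, group in enumerate(groups):
            step = np.pi if group.mode == "flip" else sign * increment
            proposal = rotated_hydrogen_coord(
                coord, group, step, coord[group.hydrogens]
            )
            change = delta_energy(coord, k, proposal, groups, interactions)
            if change < 0.0:
                coord[group.hydrogens] = proposal
                group.dihedral_offset = (group.dihedral_offset + step) % (2 * np.pi)
                trace.append(trace[-1] + change)
                accepted_any = True
        sweep += 1
        if accepted_any:
            rejection_sweeps = 0
        else:
            rejection_sweeps += 1
            if rejection_sweeps >= 2:
                converged = True
                break
    if not converged:
        warnings.warn(
            f"relaxation did not converge within {max_iterations} sweeps"
        )
    return sweep, trace, converged


def relax(
    model: MolecularModel,
    params: NonbondedParams,
    increment: float = 10.0,
    max_iterations: int = 100,
    multistart: int = 0,
    seed: int | None = None,
    groups: list[RotatableGroup] | None = None,
    full_output: bool = False,
):
    """Relax all rotatable terminal groups by hill climbing.

    Parameters
    ----------
    increment : float
        Dihedral step for freely rotatable groups, degrees (flip groups
        always move by 180°).
    multistart : int
        Number of additional seeded random initial dihedral assignments;
        the lowest-energy outcome (including the unperturbed start) wins.
    groups : optional
        Restrict relaxation to the given groups (default: all groups found
        by :func:`find_rotatable_groups`).
    full_output : bool
        Return a :class:`RelaxationResult` instead of just the model.

    Heavy atoms and non-rotatable hydrogens are returned bit-identical to
    the input; only the rotatable hydrogens move.
    """
    base_groups = find_rotatable_groups(model) if groups is None else groups
    increment_rad = np.deg2rad(increment)
    result_model = model.copy()
    if not base_groups:
        if full_output:
            return RelaxationResult(model=result_model, converged=True)
        return result_model

    interactions = interaction_pairs(model, base_groups, params)
    rng = np.random.default_rng(seed)

    def run(start_angles):
        coord = model.coord.copy()
        run_groups = [
            RotatableGroup(g.terminal, g.axis_partner, g.hydrogens.copy(), g.mode)
            for g in base_groups
        ]
        for g, angle in zip(run_groups, start_angles):
            if angle != 0.0:
                coord[g.hydrogens] = rotated_hydrogen_coord(
                    coord, g, angle, coord[g.hydrogens]
                )
                g.dihedral_offset = angle % (2 * np.pi)
        sweeps, trace, converged = _hill_climb(
            coord, run_groups, interactions, increment_rad, max_iterations
        )
        return coord, run_groups, sweeps, trace, converged

    starts = [np.zeros(len(base_groups))]
    for _ in range(multistart):
        angles = np.where(
            [g.mode == "flip" for g in base_groups],
            rng.integers(0, 2, len(base_groups)) * np.pi,
            rng.uniform(0.0, 2 * np.pi, len(base_groups)),
        )
        starts.append(angles)

    best = None
    for start in starts:
        coord, run_groups, sweeps, trace, converged = run(start)
        final = interactions.energy(coord)
        if best is None or final < best[0]:
            best = (final, coord, run_groups, sweeps, trace, converged)

    final, coord, run_groups, sweeps, trace, converged = best
    result_model.coord = coord
    for g, rg in zip(base_groups, run_groups):
        g.dihedral_offset = rg.dihedral_offset
    if full_output:
        return RelaxationResult(
            model=result_model,
            n_sweeps=sweeps,
            n_accepted=len(trace) - 1,
            energy_trace=trace,
            final_energy=final,
            converged=converged,
        )
    return result_model
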