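"""Shared test helpers: fixture molecules and synthetic many-molecule systems."""

import numpy as np
import pytest

import hydroforge as hf


@pytest.fixture(scope="session")
def fixture_models():
    """All packaged fixture molecules, by name."""
    return {name: hf.make_molecule(name) for name in hf.available_fixtures()}


@pytest.fixture(scope="session")
def default_library():
    return hf.default_library()


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def make_liquid(n_molecules, seed, box_edge=None, molecule="ethanol"):
    """Liquid-like system: randomly oriented copies of one fixture molecule
    on a jittered cubic grid (spacing 6 Å, so molecules touch but do not
    interpenetrate — hard clashes would swamp energy comparisons with
    astronomically large Lennard-Jones terms).

    Provides a many-atom system with genuine rotatable groups for
    interaction-pair and energy tests.  With ``box_edge`` the grid is
    scaled into an orthorhombic box of that edge length and coordinates
    are wrapped.
    """
    rng = np.random.default_rng(seed)
    template = hf.make_molecule(molecule)
    dims = int(np.ceil(n_molecules ** (1 / 3)))
    spacing = (box_edge / dims) if box_edge is not None else 6.0
    sites = [
        np.array([i, j, k], dtype=float) * spacing
        for i in range(dims) for j in range(dims) for k in range(dims)
    ]
    rng.shuffle(sites)
    parts = []
    for k in range(n_molecules):
        copy = template.copy()
        jitter = rng.uniform(-0.5, 0.5, 3)
        copy.coord = copy.coord @ random_rotation(rng).T + sites[k] + jitter
        if box_edge is not None:
            copy.coord %= box_edge
        copy.res_id[:] = k + 1
        parts.append(copy)
    merged = parts[0]
    for extra in parts[1:]:
        offset = merged.n_atoms
        bonds = extra.bonds.copy()
        bonds[:, :2] += offset
        merged = hf.MolecularModel(
            np.concatenate([merged.element, extra.element]),
            np.concatenate([merged.atom_name, extra.atom_name]),
            np.concatenate([merged.res_name, extra.res_name]),
            np.concatenate([merged.res_id, extra.res_id]),
            np.concatenate([merged.chain_id, extra.chain_id]),
            np.vstack([merged.coord, extra.coord]),
            np.concatenate([merged.formal_charge, extra.formal_charge]),
            np.concatenate([merged.is_hetero, extra.is_hetero]),
            np.vstack([merged.bonds, bonds]),
        )
    if box_edge is not None:
        merged.box = np.full(3, float(box_edge))
    merged.validate()
    return merged


def brute_force_pairs(model, groups, cutoff):
    """O(n²) reference enumeration of rotatable-hydrogen interaction pairs,
    with the same exclusions and unordered-unique convention as
    ``interaction_pairs``."""
    h_group = {}
    for k, g in enumerate(groups):
        for h in g.hydrogens:
            h_group[int(h)] = k
    pairs = set()
    coord = model.coord
    for h, k in h_group.items():
        g = groups[k]
        excluded = {h, int(g.terminal), int(g.axis_partner)}
        excluded.update(int(x) for x in g.hydrogens)
        for b in range(model.n_atoms):
            if b in excluded:
                continue
            if b in h_group and b < h:
                continue
            d = coord[b] - coord[h]
            if model.box is not None:
                d = d - model.box * np.round(d / model.box)
            if np.dot(d, d) <= cutoff**2:
                pairs.add((h, b))
    return pairs
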