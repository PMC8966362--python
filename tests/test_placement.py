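import itertools

import numpy as np
import pytest

import hydroforge as hf
from hydroforge.fragments import fragment_molecule
from hydroforge.placement import _best_superimposition, _descriptor_permutations

from conftest import random_rotation


# ----------------------------------------------------------------------
# superimposition
# ----------------------------------------------------------------------
def test_identical_sets_give_identity_and_zero_rmsd():
    points = np.array([[1.0, 0, 0], [0, 1.3, 0], [0, 0, -0.8]])
    transform, rmsd = hf.superimpose(points, points)
    assert np.allclose(transform.rotation, np.eye(3), atol=1e-12)
    assert rmsd < 1e-12


def test_known_rotation_is_recovered_exactly():
    rng = np.random.default_rng(11)
    points = rng.normal(size=(4, 3))
    rotation = random_rotation(rng)
    transform, rmsd = hf.superimpose(points, points @ rotation.T)
    assert rmsd < 1e-10
    assert np.allclose(transform.rotation @ rotation, np.eye(3), atol=1e-10)


def test_kabsch_beats_random_rotations():
    """The analytic optimum never loses to random rotation sampling."""
    rng = np.random.default_rng(4)
    random_rots = np.array([random_rotation(rng) for _ in range(1000)])
    for _ in range(50):
        n = rng.integers(3, 5)
        fixed = rng.normal(size=(n, 3))
        mobile = rng.normal(size=(n, 3))
        transform, rmsd = hf.superimpose(fixed, mobile)
        # vectorized RMSD under all random rotations
        rotated = np.einsum("rij,nj->rni", random_rots, mobile)
        rmsds = np.sqrt(((rotated - fixed) ** 2).sum(-1).mean(-1))
        assert rmsd <= rmsds.min() + 1e-12
        R = transform.rotation
        assert np.abs(R @ R.T - np.eye(3)).max() < 1e-10
        assert abs(np.linalg.det(R) - 1) < 1e-10


def test_single_point_aligns_direction():
    fixed = np.array([[0.0, 0.0, 2.0]])
    mobile = np.array([[1.5, 0.0, 0.0]])
    transform, _ = hf.superimpose(fixed, mobile)
    out = transform.apply(mobile)[0]
    assert np.allclose(out / np.linalg.norm(out), [0, 0, 1], atol=1e-12)
    assert np.isclose(np.linalg.norm(out), 1.5)


def test_empty_sets_give_identity():
    transform, rmsd = hf.superimpose(np.empty((0, 3)), np.empty((0, 3)))
    assert np.allclose(transform.rotation, np.eye(3))
    assert rmsd == 0.0


def test_permutation_search_never_worse_than_canonical_order(fixture_models):
    model = fixture_models["pyranose"]
    library = hf.build_library([fixture_models["furanose"]])
    for frag in fragment_molecule(hf.relabel_partial_double_bonds(model)):
        hit = library.lookup(frag.key)
        if hit is None or len(frag.neighbor_coord) < 2:
            continue
        _, best_rmsd = _best_superimposition(frag.neighbor_coord, hit)
        _, canonical_rmsd = hf.superimpose(frag.neighbor_coord, hit.neighbor_coord)
        assert best_rmsd <= canonical_rmsd + 1e-12


def test_descriptor_permutations_respect_groups():
    descriptors = ((0, "C"), (0, "C"), (0, "O"))
    perms = sorted(tuple(p) for p in _descriptor_permutations(descriptors))
    assert perms == [(0, 1, 2), (1, 0, 2)]


# ----------------------------------------------------------------------
# hydrogen placement
# ----------------------------------------------------------------------
def hydrogens_of(model, heavy):
    adj = model.neighbors()
    return [j for j, _ in adj[heavy] if model.is_hydrogen[j]]


@pytest.mark.parametrize("name", [
    "methane", "ethane", "ethanol", "water", "benzene", "toluene",
    "isobutylene", "formamide", "methylamine", "alanine", "pyranose",
    "furanose", "arginine-sidechain",
])
def test_self_round_trip_restores_hydrogens(name, fixture_models):
    """Library from the molecule itself: fixed hydrogens return exactly,
    terminal ones up to a rotation about the bond."""
    m = fixture_models[name]
    library = hf.build_library([m])
    target = hf.relabel_partial_double_bonds(m.without_hydrogens())
    placed, unassigned = hf.place_hydrogens(target, library, keep_existing=False)
    assert not unassigned
    assert int(placed.is_hydrogen.sum()) == int(m.is_hydrogen.sum())

    heavy_adj = m.heavy_neighbors()
    heavy_indices = np.where(~m.is_hydrogen)[0]   # target index -> index in m
    for target_idx in range(target.n_atoms):
        orig_idx = int(heavy_indices[target_idx])
        originals = hydrogens_of(m, orig_idx)
        news = hydrogens_of(placed, target_idx)
        assert len(originals) == len(news)
        if not originals:
            continue
        if len(heavy_adj[orig_idx]) >= 2:
            best = min(
                max(
                    np.linalg.norm(m.coord[a] - placed.coord[b])
                    for a, b in zip(originals, perm)
                )
                for perm in itertools.permutations(news)
            )
            assert best < 1e-3, (name, orig_idx)
        else:
            # terminal or isolated: internal geometry must be preserved
            for h in news:
                d_new = np.linalg.norm(placed.coord[h] - placed.coord[target_idx])
                d_ref = sorted(
                    np.linalg.norm(m.coord[a] - m.coord[orig_idx]) for a in originals
                )
                assert min(abs(d_new - d) for d in d_ref) < 1e-3
            if len(heavy_adj[orig_idx]) == 1:
                axis_old = heavy_adj[orig_idx][0][0]
                axis_new = [
                    j for j, _ in placed.heavy_neighbors()[target_idx]
                ][0]

                def angles(model, center, axis_atom, hs):
                    axis = model.coord[axis_atom] - model.coord[center]
                    return sorted(
                        np.degrees(np.arccos(np.clip(
                            np.dot(model.coord[h] - model.coord[center], axis)
                            / np.linalg.norm(model.coord[h] - model.coord[center])
                            / np.linalg.norm(axis), -1, 1)))
                        for h in hs
                    )
                new_angles = angles(placed, target_idx, axis_new, news)
                old_angles = angles(m, orig_idx, axis_old, originals)
                for a_new, a_old in zip(new_angles, old_angles):
                    assert abs(a_new - a_old) < 0.1


def test_miss_path_reports_unassigned(fixture_models):
    library = hf.build_library([fixture_models["methane"]])
    target = hf.relabel_partial_double_bonds(
        fixture_models["ethanol"].without_hydrogens()
    )
    placed, unassigned = hf.place_hydrogens(target, library, keep_existing=False)
    assert unassigned == {0, 1, 2}
    assert int(placed.is_hydrogen.sum()) == 0


def test_toluene_from_benzene_and_isobutylene(fixture_models):
    """Ring CH hydrogens come from benzene, the methyl from isobutylene;
    the hydrogen-free ring junction has no matching key and is reported."""
    library = hf.build_library(
        [fixture_models["benzene"], fixture_models["isobutylene"]]
    )
    target = hf.relabel_partial_double_bonds(
        fixture_models["toluene"].without_hydrogens()
    )
    placed, unassigned = hf.place_hydrogens(target, library, keep_existing=False)
    assert int(placed.is_hydrogen.sum()) == 8   # 5 ring CH + 3 methyl
    junction = 0                                 # ring carbon bearing the methyl
    assert unassigned == {junction}
    assert not hydrogens_of(fixture_models["toluene"], junction)


def test_placement_equivariance_under_rigid_motion(fixture_models):
    """For molecules with a non-degenerate heavy skeleton, placement
    commutes with rigid motions (a line- or point-shaped skeleton is
    axially symmetric, so no deterministic placement can be equivariant
    there; those cases preserve internal geometry instead)."""
    rng = np.random.default_rng(42)
    rotation = random_rotation(rng)
    shift = rng.normal(size=3) * 5
    for name in ["ethanol", "toluene", "pyranose", "alanine", "formamide",
                 "arginine-sidechain", "isobutylene"]:
        m = fixture_models[name]
        library = hf.build_library([m])
        target = hf.relabel_partial_double_bonds(m.without_hydrogens())
        placed, _ = hf.place_hydrogens(target, library, keep_existing=False)
        moved = target.copy()
        moved.coord = target.coord @ rotation.T + shift
        placed_moved, _ = hf.place_hydrogens(moved, library, keep_existing=False)
        assert np.abs(
            placed.coord @ rotation.T + shift - placed_moved.coord
        ).max() < 1e-6, name


def test_placed_bond_lengths_match_library_geometry(fixture_models):
    """Rigid placement preserves the library fragment's H bond lengths."""
    m = fixture_models["pyranose"]
    library = hf.build_library([fixture_models["furanose"]])
    target = hf.relabel_partial_double_bonds(m.without_hydrogens())
    placed, _ = hf.place_hydrogens(target, library, keep_existing=False)
    for frag in fragment_molecule(hf.relabel_partial_double_bonds(m)):
        hit = library.lookup(frag.key)
        if hit is None:
            continue
        lib_lengths = sorted(np.linalg.norm(hit.hydrogen_coord, axis=1))
        new_lengths = sorted(
            np.linalg.norm(placed.coord[h] - placed.coord[frag.center_index])
            for h in hydrogens_of(placed, frag.center_index)
        )
        for a, b in zip(new_lengths, lib_lengths):
            assert abs(a - b) < 1e-6


def test_existing_hydrogens_are_kept_when_requested(fixture_models):
    m = fixture_models["ethanol"]
    library = hf.build_library([m])
    partial = m.select([i for i in range(m.n_atoms) if i != 5])  # drop one H
    relabeled = hf.relabel_partial_double_bonds(partial)
    placed, _ = hf.place_hydrogens(relabeled, library, keep_existing=True)
    # every heavy atom still carries at least one hydrogen, so fill-missing
    # mode leaves the model untouched
    assert int(placed.is_hydrogen.sum()) == int(partial.is_hydrogen.sum())
    assert np.array_equal(placed.coord, partial.coord)
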