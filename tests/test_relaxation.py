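import numpy as np
import pytest

import hydroforge as hf
from hydroforge.relaxation import (
    DEFAULT_CUTOFF,
    ParameterError,
    rotated_hydrogen_coord,
)

from conftest import brute_force_pairs, make_liquid


# ----------------------------------------------------------------------
# rotatable-group detection
# ----------------------------------------------------------------------
def test_ethanol_has_two_free_groups(fixture_models):
    groups = hf.find_rotatable_groups(fixture_models["ethanol"])
    kinds = sorted(
        (str(fixture_models["ethanol"].element[g.terminal]), g.mode)
        for g in groups
    )
    assert kinds == [("C", "free"), ("O", "free")]


def test_benzene_has_no_rotatable_groups(fixture_models):
    assert hf.find_rotatable_groups(fixture_models["benzene"]) == []


def test_guanidinium_nitrogens_are_flip_groups(fixture_models):
    m = hf.relabel_partial_double_bonds(fixture_models["arginine-sidechain"])
    modes = [
        (str(m.element[g.terminal]), g.mode) for g in hf.find_rotatable_groups(m)
    ]
    assert modes.count(("N", "flip")) == 2   # =NH2+ and the amine-like NH2
    assert ("C", "free") in modes            # the methyl cap


# ----------------------------------------------------------------------
# energy function
# ----------------------------------------------------------------------
def test_lj_minimum_is_minus_well_depth():
    eps = np.sqrt(hf.UFF_NONBONDED["C"][0] * hf.UFF_NONBONDED["O"][0])
    delta = 0.5 * (hf.UFF_NONBONDED["C"][1] + hf.UFF_NONBONDED["O"][1])
    v = hf.pair_energy(0.0, 0.0, "C", "O", delta)
    assert np.isclose(v, -eps, rtol=0, atol=1e-12)


def test_coulomb_constant_at_unit_conditions():
    v = hf.pair_energy(1.0, -1.0, "C", "C", 1.0)
    lj = hf.pair_energy(0.0, 0.0, "C", "C", 1.0)
    assert np.isclose(v - lj, -332.067)


def test_donor_acceptor_scan_minimum_at_scaled_distance():
    delta = 0.5 * (hf.UFF_NONBONDED["O"][1] + hf.UFF_NONBONDED["H"][1])
    distances = np.arange(1.5, 6.0, 0.001)
    energies = [
        hf.pair_energy(0.0, 0.0, "O", "H", d, is_donor_acceptor=True)
        for d in distances
    ]
    d_min = distances[int(np.argmin(energies))]
    assert abs(d_min - 0.79 * delta) < 0.002


def test_unknown_element_raises_parameter_error():
    with pytest.raises(ParameterError, match="AU"):
        hf.pair_energy(0.0, 0.0, "AU", "C", 2.0)


# ----------------------------------------------------------------------
# interaction pairs / cell list
# ----------------------------------------------------------------------
def test_atoms_beyond_cutoff_are_not_paired():
    eth = hf.make_molecule("ethanol")
    far = eth.add_atoms(["O"], [eth.coord[2] + [0, 0, 15.0]])
    groups = hf.find_rotatable_groups(far)
    params = hf.NonbondedParams.from_model(far, np.zeros(far.n_atoms))
    pairs = hf.interaction_pairs(far, groups, params)
    assert far.n_atoms - 1 not in set(pairs.pairs.ravel().tolist())


def test_exclusions_within_own_group(fixture_models):
    m = fixture_models["ethanol"]
    groups = hf.find_rotatable_groups(m)
    params = hf.NonbondedParams.from_model(m, np.zeros(m.n_atoms))
    interactions = hf.interaction_pairs(m, groups, params)
    methyl = next(g for g in groups if str(m.element[g.terminal]) == "C")
    forbidden = {int(methyl.terminal), int(methyl.axis_partner)} | {
        int(h) for h in methyl.hydrogens
    }
    for h in methyl.hydrogens:
        partners = {
            int(b) for a, b in interactions.pairs if a == h
        } | {int(a) for a, b in interactions.pairs if b == h}
        assert not partners & forbidden


@pytest.mark.parametrize("box_edge", [None, 18.0])
def test_cell_list_matches_brute_force(box_edge):
    model = make_liquid(n_molecules=56, seed=9, box_edge=box_edge)
    assert model.n_atoms == 504
    groups = hf.find_rotatable_groups(model)
    params = hf.NonbondedParams.from_model(model, np.zeros(model.n_atoms))
    interactions = hf.interaction_pairs(model, groups, params)
    got = {(int(a), int(b)) for a, b in interactions.pairs}
    expected = brute_force_pairs(model, groups, DEFAULT_CUTOFF)
    assert got == expected


def test_degenerate_box_is_an_error():
    m = hf.make_molecule("ethanol")
    m.box = np.array([10.0, 0.0, 10.0])
    groups = hf.find_rotatable_groups(m)
    params = hf.NonbondedParams.from_model(m, np.zeros(m.n_atoms))
    with pytest.raises(ValueError):
        hf.interaction_pairs(m, groups, params)


# ----------------------------------------------------------------------
# rotation geometry
# ----------------------------------------------------------------------
def test_full_turn_and_double_flip_are_identity(fixture_models):
    m = fixture_models["ethanol"]
    group = hf.find_rotatable_groups(m)[0]
    full = hf.rotate_group(m, group, 2 * np.pi)
    assert np.abs(full - m.coord[group.hydrogens]).max() < 1e-9
    once = rotated_hydrogen_coord(m.coord, group, np.pi, m.coord[group.hydrogens])
    twice = rotated_hydrogen_coord(m.coord, group, np.pi, once)
    assert np.abs(twice - m.coord[group.hydrogens]).max() < 1e-9


def test_rotation_preserves_distances_to_axis_atoms(fixture_models):
    m = fixture_models["ethanol"]
    rng = np.random.default_rng(2)
    for group in hf.find_rotatable_groups(m):
        for angle in rng.uniform(-np.pi, np.pi, 5):
            new = hf.rotate_group(m, group, angle)
            for row, h in zip(new, group.hydrogens):
                for anchor in (group.terminal, group.axis_partner):
                    d_new = np.linalg.norm(row - m.coord[anchor])
                    d_old = np.linalg.norm(m.coord[h] - m.coord[anchor])
                    assert abs(d_new - d_old) < 1e-9


# ----------------------------------------------------------------------
# delta energy vs full recomputation
# ----------------------------------------------------------------------
def test_delta_energy_matches_full_recomputation():
    model = make_liquid(n_molecules=34, seed=17)   # 306 atoms
    charges = hf.peoe_partial_charges(model)
    params = hf.NonbondedParams.from_model(model, charges)
    groups = hf.find_rotatable_groups(model)
    interactions = hf.interaction_pairs(model, groups, params)
    rng = np.random.default_rng(23)
    before = interactions.energy(model.coord)
    for _ in range(100):
        k = int(rng.integers(len(groups)))
        angle = float(rng.uniform(-np.pi, np.pi))
        proposal = rotated_hydrogen_coord(
            model.coord, groups[k], angle, model.coord[groups[k].hydrogens]
        )
        fast = hf.delta_energy(model.coord, k, proposal, groups, interactions)
        coord = model.coord.copy()
        coord[groups[k].hydrogens] = proposal
        slow = interactions.energy(coord) - before
        assert abs(fast - slow) <= 1e-8 * max(1.0, abs(slow))


def test_zero_angle_proposal_has_zero_delta(fixture_models):
    m = fixture_models["ethanol"]
    params = hf.NonbondedParams.from_model(m, np.zeros(m.n_atoms))
    groups = hf.find_rotatable_groups(m)
    interactions = hf.interaction_pairs(m, groups, params)
    dv = hf.delta_energy(
        m.coord, 0, m.coord[groups[0].hydrogens], groups, interactions
    )
    assert dv == 0.0


def test_group_without_interaction_partners_has_zero_delta():
    """A methane-like rotor with nothing in the cutoff contributes no
    energy change at any angle (empty pair sum)."""
    lone = hf.make_molecule("ethanol")
    groups = hf.find_rotatable_groups(lone)
    empty = hf.InteractionSet(
        pairs=np.empty((0, 2), dtype=np.int64), eps=np.empty(0),
        delta=np.empty(0), qq=np.empty(0),
        group_pairs=[np.empty(0, dtype=np.int64) for _ in groups],
    )
    for angle in np.linspace(0, 2 * np.pi, 7):
        proposal = rotated_hydrogen_coord(
            lone.coord, groups[0], angle, lone.coord[groups[0].hydrogens]
        )
        assert hf.delta_energy(lone.coord, 0, proposal, groups, empty) == 0.0


# ----------------------------------------------------------------------
# hill climbing
# ----------------------------------------------------------------------
def point_charge_probe(model, anchor_index, offset, charge=-1.0):
    """Attach a bare point charge (no LJ well) near ``anchor_index``."""
    probe = model.add_atoms(["CL"], [model.coord[anchor_index] + offset])
    q = hf.peoe_partial_charges(model)
    q = np.append(q, charge)
    params = hf.NonbondedParams.from_model(probe, q)
    params.epsilon[-1] = 0.0
    return probe, params


def test_no_rotatable_groups_returns_model_unchanged(fixture_models):
    m = fixture_models["benzene"]
    params = hf.NonbondedParams.from_model(m, np.zeros(m.n_atoms))
    result = hf.relax(m, params, full_output=True)
    assert np.array_equal(result.model.coord, m.coord)
    assert result.converged


def test_hydroxyl_relaxation_matches_grid_scan(fixture_models):
    """Single free group next to a fixed point charge: hill climbing lands
    within one increment of the exhaustive 10° grid minimum."""
    m = fixture_models["ethanol"]
    probe, params = point_charge_probe(m, 2, np.array([1.0, 2.5, 1.0]))
    groups = [
        g for g in hf.find_rotatable_groups(probe)
        if str(probe.element[g.terminal]) == "O"
    ]
    result = hf.relax(probe, params, groups=groups, full_output=True)
    interactions = hf.interaction_pairs(probe, groups, params)
    grid = []
    for k in range(36):
        coord = probe.coord.copy()
        coord[groups[0].hydrogens] = rotated_hydrogen_coord(
            probe.coord, groups[0], np.deg2rad(10 * k),
            probe.coord[groups[0].hydrogens],
        )
        grid.append(interactions.energy(coord))
    best_angle = 10 * int(np.argmin(grid))
    reached = np.rad2deg(groups[0].dihedral_offset) % 360
    distance = min(abs(reached - best_angle), 360 - abs(reached - best_angle))
    assert distance <= 10.0 + 1e-6
    assert result.final_energy <= min(grid) + 1e-9
    assert result.converged


def test_flip_group_chooses_lower_energy_state(fixture_models):
    m = hf.relabel_partial_double_bonds(fixture_models["formamide"])
    probe, params = point_charge_probe(m, 2, np.array([1.2, 2.2, 0.8]))
    groups = hf.find_rotatable_groups(probe)
    assert [g.mode for g in groups] == ["flip"]
    interactions = hf.interaction_pairs(probe, groups, params)
    e0 = interactions.energy(probe.coord)
    flipped = probe.coord.copy()
    flipped[groups[0].hydrogens] = rotated_hydrogen_coord(
        probe.coord, groups[0], np.pi, probe.coord[groups[0].hydrogens]
    )
    e1 = interactions.energy(flipped)
    result = hf.relax(probe, params, groups=groups, full_output=True)
    assert np.isclose(result.final_energy, min(e0, e1), atol=1e-9)


def test_energy_trace_strictly_decreases(fixture_models):
    m = fixture_models["ethanol"]
    probe, params = point_charge_probe(m, 2, np.array([1.0, 2.5, 1.0]))
    result = hf.relax(probe, params, full_output=True)
    trace = result.energy_trace
    assert all(b < a for a, b in zip(trace, trace[1:]))
    assert result.converged


def test_relax_is_deterministic_given_seed():
    model = make_liquid(n_molecules=6, seed=3)
    charges = hf.peoe_partial_charges(model)
    params = hf.NonbondedParams.from_model(model, charges)
    a = hf.relax(model, params, multistart=3, seed=11)
    b = hf.relax(model, params, multistart=3, seed=11)
    assert np.array_equal(a.coord, b.coord)


def test_heavy_atoms_and_fixed_hydrogens_bit_identical():
    model = make_liquid(n_molecules=6, seed=3)
    charges = hf.peoe_partial_charges(model)
    params = hf.NonbondedParams.from_model(model, charges)
    groups = hf.find_rotatable_groups(model)
    rotatable = {int(h) for g in groups for h in g.hydrogens}
    relaxed = hf.relax(model, params, groups=groups)
    for i in range(model.n_atoms):
        if i not in rotatable:
            assert np.array_equal(relaxed.coord[i], model.coord[i])


def test_multistart_never_worse_than_single_start():
    model = make_liquid(n_molecules=6, seed=3)
    charges = hf.peoe_partial_charges(model)
    params = hf.NonbondedParams.from_model(model, charges)
    groups = hf.find_rotatable_groups(model)
    interactions = hf.interaction_pairs(model, groups, params)
    single = hf.relax(model, params)
    multi = hf.relax(model, params, multistart=4, seed=1)
    assert (
        interactions.energy(multi.coord)
        <= interactions.energy(single.coord) + 1e-9
    )


def test_periodic_energy_invariant_under_lattice_shift():
    model = make_liquid(n_molecules=10, seed=8, box_edge=24.0)
    charges = hf.peoe_partial_charges(model)
    params = hf.NonbondedParams.from_model(model, charges)
    groups = hf.find_rotatable_groups(model)
    interactions = hf.interaction_pairs(model, groups, params)
    e0 = interactions.energy(model.coord)
    e1 = interactions.energy(model.coord + model.box)
    assert np.isclose(e0, e1, rtol=0, atol=1e-8)
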