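"""hydroforge: hydrogen addition to molecular models.

Missing hydrogens are predicted by splitting the target into per-heavy-atom
fragments, matching each against a library compiled from reference molecules
with known hydrogen positions, superimposing the matching library fragment
by rotation about the central atom, and finally relaxing rotatable terminal
groups by hill climbing over a UFF-derived non-bonded energy.
"""

from .model import BondOrder, MolecularModel, ModelError
from .io import (
    FormatError,
    connect_bonds,
    read_sdf_molecules,
    read_structure,
    write_structure,
)
from .fragments import (
    Fragment,
    FragmentKey,
    FragmentLibrary,
    build_library,
    compute_chirality,
    fragment_molecule,
    relabel_partial_double_bonds,
)
from .placement import RigidTransform, place_hydrogens, superimpose
from .charges import (
    PKA_TABLE,
    assign_formal_charges,
    peoe_partial_charges,
    read_charge_table,
)
from .relaxation import (
    InteractionSet,
    NonbondedParams,
    RelaxationResult,
    RotatableGroup,
    UFF_NONBONDED,
    delta_energy,
    find_rotatable_groups,
    interaction_pairs,
    pair_energy,
    relax,
    rotate_group,
)
from .naming import name_and_order_hydrogens
from .fixtures import available_fixtures, default_library, make_molecule

__version__ = "0.1.0"

__all__ = [
    "BondOrder", "MolecularModel", "ModelError", "FormatError",
    "read_structure", "read_sdf_molecules", "write_structure", "connect_bonds",
    "Fragment", "FragmentKey", "FragmentLibrary", "build_library",
    "compute_chirality", "fragment_molecule", "relabel_partial_double_bonds",
    "RigidTransform", "superimpose", "place_hydrogens",
    "PKA_TABLE", "assign_formal_charges", "peoe_partial_charges",
    "read_charge_table",
    "InteractionSet", "NonbondedParams", "RelaxationResult", "RotatableGroup",
    "UFF_NONBONDED", "delta_energy", "find_rotatable_groups",
    "interaction_pairs", "pair_energy", "relax", "rotate_group",
    "name_and_order_hydrogens",
    "available_fixtures", "default_library", "make_molecule",
    "add_hydrogens",
]


def add_hydrogens(
    model,
    library=None,
    ph=None,
    relax_groups=True,
    increment=10.0,
    max_iterations=100,
    multistart=0,
    seed=None,
    partial_charges=None,
    keep_existing=True,
):
    """High-level pipeline: charges → fragment/place → relax → name.

    Returns ``(model_with_hydrogens, unassigned_heavy_atom_indices)``.
    ``library`` defaults to the packaged fixture library; pass ``ph`` to
    recalculate amino-acid formal charges first.
    """
    if library is None:
        library = default_library()
    if ph is not None:
        model = assign_formal_charges(model, ph)
    model = relabel_partial_double_bonds(model)
    model, unassigned = place_hydrogens(model, library, keep_existing=keep_existing)
    if relax_groups:
        charges = (
            peoe_partial_charges(model)
            if partial_charges is None else partial_charges
        )
        params = NonbondedParams.from_model(model, charges)
        model = relax(
            model, params, increment=increment, max_iterations=max_iterations,
            multistart=multistart, seed=seed,
        )
    model = name_and_order_hydrogens(model)
    return model, unassigned
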