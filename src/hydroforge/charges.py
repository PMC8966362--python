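"""Partial and formal charges.

Partial charges for the non-bonded energy come from the PEOE method
(partial equalization of orbital electronegativities, Gasteiger-Marsili):
charge flows across each bond proportionally to the electronegativity
difference of the partners, damped by (1/2)^t per iteration, starting from
the formal charges.  The computation is delegated to biotite's
implementation with the standard 6 iterations; atoms without published
parameters fall back to zero charge with a warning.

Formal charges of ionizable amino-acid groups can optionally be
recalculated from a user-provided pH against tabulated pKa values of the
free amino acids.  The rule is all-or-nothing (no fractional protonation):
an acidic site is charged -1 iff pH > pKa, a basic site +1 iff pH < pKa;
at pH == pKa the neutral form is kept.  The charge sits on the
conventional atom of each group (carboxylate OD2/OE2, His ND1, Lys NZ,
Arg NH1, Cys SG, Tyr OH, backbone N / OXT at the termini).
"""

from __future__ import annotations

import contextlib
import warnings

import numpy as np
from biotite.structure import partial_charges as _biotite_peoe

from .io import to_atom_array
from .model import MolecularModel

__all__ = [
    "peoe_partial_charges",
    "assign_formal_charges",
    "read_charge_table",
    "PKA_TABLE",
]

#: pKa values of ionizable groups of the free amino acids
#: (CRC Handbook of Chemistry and Physics compilation).  Keys are
#: (residue name, site); sites "NTERM"/"CTERM" apply to backbone termini of
#: any amino acid.  User-replaceable: pass a modified mapping to
#: :func:`assign_formal_charges`.
PKA_TABLE: dict[tuple[str, str], float] = {
    ("ASP", "side"): 3.65,
    ("GLU", "side"): 4.25,
    ("HIS", "side"): 6.00,
    ("CYS", "side"): 8.18,
    ("TYR", "side"): 10.07,
    ("LYS", "side"): 10.53,
    ("ARG", "side"): 12.48,
    ("*", "NTERM"): 9.00,
    ("*", "CTERM"): 2.00,
}

#: (conventional atom, acidic?) per ionizable side chain.
_SIDE_SITES = {
    "ASP": ("OD2", True),
    "GLU": ("OE2", True),
    "CYS": ("SG", True),
    "TYR": ("OH", True),
    "HIS": ("ND1", False),
    "LYS": ("NZ", False),
    "ARG": ("NH1", False),
}

_AMINO_ACIDS = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})


@contextlib.contextmanager
def _reshape_newshape_compat():
    """Accept the pre-numpy-2.1 ``newshape`` keyword of ``np.reshape``
    while a wrapped call runs (needed by the installed PEOE backend)."""
    original = np.reshape

    def shim(a, *args, **kwargs):
        if "newshape" in kwargs:
            kwargs["shape"] = kwargs.pop("newshape")
        return original(a, *args, **kwargs)

    np.reshape = shim
    try:
        yield
    finally:
        np.reshape = original


def peoe_partial_charges(model: MolecularModel, iterations: int = 6) -> np.ndarray:
    """Per-atom PEOE partial charges (elementary charges, float64).

    Requires elements and bonds; hydrogens should already be present so
    that the charges describe the protonated molecule.  The sum over a
    molecule equals its total formal charge.  Atoms whose element or
    hybridization has no PEOE parameters get charge 0 with a warning.
    """
    arr = to_atom_array(model)
    # the PEOE backend parametrizes kekulized aromatic bond types only
    from biotite.structure import BondList, BondType
    rows = arr.bonds.as_array()
    rows[rows[:, 2] == int(BondType.AROMATIC), 2] = int(BondType.AROMATIC_SINGLE)
    arr.bonds = BondList(arr.array_length(), rows)
    with warnings.catch_warnings(), _reshape_newshape_compat():
        warnings.simplefilter("ignore")
        q = _biotite_peoe(arr, iteration_step_num=iterations)
    q = np.asarray(q, dtype=np.float64)
    bad = ~np.isfinite(q)
    if np.any(bad):
        elements = sorted(set(model.element[bad]))
        warnings.warn(
            f"no PEOE parameters for {elements}; zero charge assigned"
        )
        q[bad] = 0.0
    return q


def read_charge_table(path, n_atoms: int) -> np.ndarray:
    """Read user-supplied partial charges (two whitespace-separated columns:
    0-based atom index, charge); unlisted atoms get 0."""
    q = np.zeros(n_atoms, dtype=np.float64)
    with open(str(path)) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx_str, value = line.split()[:2]
            idx = int(idx_str)
            if not 0 <= idx < n_atoms:
                raise ValueError(f"charge table index {idx} out of range")
            q[idx] = float(value)
    return q


def _residue_runs(model: MolecularModel):
    """Yield (chain_id, res_id, res_name, atom index array) per residue, in
    atom order."""
    n = model.n_atoms
    start = 0
    for i in range(1, n + 1):
        if (
            i == n
            or model.res_id[i] != model.res_id[start]
            or model.chain_id[i] != model.chain_id[start]
        ):
            yield (
                str(model.chain_id[start]),
                int(model.res_id[start]),
                str(model.res_name[start]),
                np.arange(start, i),
            )
            start = i


def assign_formal_charges(
    model: MolecularModel, pH: float, pka_table=None
) -> MolecularModel:
    """Protonation-state formal charges for amino-acid residues at a pH.

    Applied *before* fragmentation, so that e.g. a deprotonated carboxylate
    forms a different library key than the neutral acid and receives no
    hydrogen.  Non-amino-acid residues are untouched.  Raising the pH never
    increases any site's charge.
    """
    if pka_table is None:
        pka_table = PKA_TABLE
    model = model.copy()
    runs = list(_residue_runs(model))
    amino_mask = [r[2] in _AMINO_ACIDS for r in runs]
    for pos, ((chain, _res_id, res_name, idx), is_aa) in enumerate(
        zip(runs, amino_mask)
    ):
        if not is_aa:
            continue
        names = model.atom_name[idx]

        def set_site(atom, pka, acidic):
            where = np.where(names == atom)[0]
            if len(where) == 0:
                return
            atom_index = idx[where[0]]
            if acidic:
                model.formal_charge[atom_index] = -1 if pH > pka else 0
            else:
                model.formal_charge[atom_index] = 1 if pH < pka else 0

        site = _SIDE_SITES.get(res_name)
        if site is not None:
            atom, acidic = site
            pka = pka_table.get((res_name, "side"))
            if pka is not None:
                set_site(atom, pka, acidic)
        # chain termini: first/last amino-acid residue of each chain
        prev_is_aa = pos > 0 and amino_mask[pos - 1] and runs[pos - 1][0] == chain
        next_is_aa = (
            pos + 1 < len(runs) and amino_mask[pos + 1] and runs[pos + 1][0] == chain
        )
        if not prev_is_aa:
            pka = pka_table.get(("*", "NTERM"))
            if pka is not None:
                set_site("N", pka, acidic=False)
        if not next_is_aa:
            pka = pka_table.get(("*", "CTERM"))
            if pka is not None:
                set_site("OXT" if "OXT" in names else "O", pka, acidic=True)
    return model
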