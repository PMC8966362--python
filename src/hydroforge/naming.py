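"""Hydrogen atom naming and canonical atom ordering.

Hydrogens are moved to sit directly after the heavy atoms of their residue.
For residues known to the Chemical Component Dictionary (amino acids,
canonical nucleotides, and every other CCD component bundled with biotite),
hydrogen names follow the CCD convention: the hydrogens bonded to a heavy
atom get the names the CCD assigns to that heavy atom's hydrogens, in
placement order (the CA hydrogen of an amino acid becomes "HA").  For
unknown residues a name is derived from the bonded heavy atom: element
prefix stripped, "H" prepended, and a 1..n suffix appended when the atom
carries several hydrogens ("C7" with three hydrogens gives "H71", "H72",
"H73").  Names are made unique within each residue.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import biotite.structure.info as info

from .model import MolecularModel

__all__ = ["name_and_order_hydrogens"]


def _ccd_hydrogen_names(res_name: str) -> dict[str, list[str]] | None:
    """Map heavy atom name -> CCD hydrogen names bonded to it, or None."""
    try:
        template = info.residue(res_name)
    except KeyError:
        return None
    if template is None:
        return None
    mapping: dict[str, list[str]] = {}
    is_h = template.element == "H"
    bonds = template.bonds.as_array() if template.bonds is not None else []
    for a, b, _ in bonds:
        a, b = int(a), int(b)
        if is_h[a] and not is_h[b]:
            mapping.setdefault(str(template.atom_name[b]), []).append(
                str(template.atom_name[a])
            )
        elif is_h[b] and not is_h[a]:
            mapping.setdefault(str(template.atom_name[a]), []).append(
                str(template.atom_name[b])
            )
    return mapping


def _fallback_names(heavy_name: str, element: str, count: int) -> list[str]:
    stem = heavy_name
    if stem.upper().startswith(element.upper()) and len(stem) > len(element):
        stem = stem[len(element):]
    elif re.fullmatch(r"[A-Za-z]+", stem):
        stem = stem[1:] if len(stem) > 1 else stem
    base = "H" + stem
    if count == 1:
        return [base]
    return [f"{base}{k + 1}" for k in range(count)]


def name_and_order_hydrogens(model: MolecularModel) -> MolecularModel:
    """Rename hydrogens and reorder atoms residue-wise.

    Returns a new model in which every residue lists its heavy atoms first
    (original order) followed by its hydrogens, ordered by the position of
    the bonded heavy atom; the bond table is re-indexed accordingly.  The
    operation is a pure permutation plus renaming, and idempotent.
    """
    model = model.copy()
    is_h = model.is_hydrogen
    heavy_of = {}
    for a, b, _ in model.bonds:
        a, b = int(a), int(b)
        if is_h[a] and not is_h[b]:
            heavy_of[a] = b
        elif is_h[b] and not is_h[a]:
            heavy_of[b] = a

    # residue runs in atom order
    runs = []
    start = 0
    n = model.n_atoms
    for i in range(1, n + 1):
        if (
            i == n
            or model.res_id[i] != model.res_id[start]
            or model.chain_id[i] != model.chain_id[start]
            or model.res_name[i] != model.res_name[start]
        ):
            runs.append(np.arange(start, i))
            start = i

    # hydrogens whose heavy atom sits in another residue run are moved to
    # the heavy atom's residue
    run_of_atom = np.empty(n, dtype=np.int64)
    for r, idx in enumerate(runs):
        run_of_atom[idx] = r
    for h, heavy in heavy_of.items():
        run_of_atom[h] = run_of_atom[heavy]

    permutation = []
    new_names = model.atom_name.copy()
    for r, idx in enumerate(runs):
        members = np.where(run_of_atom == r)[0]
        heavies = [i for i in members if not is_h[i]]
        hydrogens = [i for i in members if is_h[i]]
        hydrogens.sort(key=lambda h: (heavy_of.get(h, n), h))
        permutation.extend(heavies)
        permutation.extend(hydrogens)

        res_name = str(model.res_name[idx[0]])
        ccd = _ccd_hydrogen_names(res_name)
        used = {str(new_names[i]) for i in heavies}
        by_heavy: dict[int, list[int]] = {}
        for h in hydrogens:
            by_heavy.setdefault(heavy_of.get(h, -1), []).append(h)
        for heavy, hs in by_heavy.items():
            heavy_name = str(model.atom_name[heavy]) if heavy >= 0 else "X"
            element = str(model.element[heavy]) if heavy >= 0 else "X"
            names = None
            if ccd is not None and heavy_name in ccd and len(ccd[heavy_name]) >= len(hs):
                names = ccd[heavy_name][: len(hs)]
            if names is None:
                names = _fallback_names(heavy_name, element, len(hs))
            for h, name in zip(hs, names):
                if name in used:
                    k = 1
                    candidate = f"{name}{k}" if not name[-1].isdigit() else f"{name}A"
                    while candidate in used:
                        k += 1
                        candidate = f"{name}{k}" if not name[-1].isdigit() else f"{name}{'A' * k}"
                    warnings.warn(
                        f"hydrogen name collision for {name!r} in {res_name}; "
                        f"renamed to {candidate!r}"
                    )
                    name = candidate
                new_names[h] = name
                used.add(name)

    model.atom_name = new_names
    return model.reorder(np.asarray(permutation, dtype=np.int64))
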