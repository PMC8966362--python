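"""Idealized small-molecule fixtures.

Deterministic generators for a set of small molecules with hydrogens at
idealized geometry: sp3 angles 109.471°, sp2 angles 120°, aromatic rings as
planar regular polygons, standard bond lengths (C-H 1.09 Å, O-H 0.96 Å,
N-H 1.01 Å, C-C 1.54 Å single / 1.39 Å aromatic).  The set spans every
fragment situation the placement and relaxation machinery must handle:
isolated centers (water), terminal methyl/hydroxyl/amine rotors, aromatic
rings and their substituted analogs (benzene/toluene/isobutylene), planar
amide and guanidinium nitrogens (formamide, arginine side chain), a chiral
alpha carbon (alanine) and the five-/six-membered ring pair whose central
CH carbon shares one library key across the two ring geometries.

Idealized rather than experimental geometry is deliberate: round-trip
placement errors are then attributable to the algorithm, not the data.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .fragments import build_library, FragmentLibrary
from .model import BondOrder, MolecularModel

__all__ = ["make_molecule", "available_fixtures", "default_library", "FIXTURE_NAMES"]

TET_ANGLE = np.deg2rad(109.4712206344907)   # arccos(-1/3)
CC = 1.54
CC_AROMATIC = 1.39
CC_SP2 = 1.51          # sp3 carbon to sp2/aromatic carbon
CC_DOUBLE = 1.33
CH = 1.09
OH = 0.96
NH = 1.01
CO = 1.43
CN = 1.47
CN_SP2 = 1.35
CO_DOUBLE = 1.23

S, D, A, P = (
    int(BondOrder.SINGLE), int(BondOrder.DOUBLE),
    int(BondOrder.AROMATIC), int(BondOrder.PARTIAL_DOUBLE),
)


def _unit(v):
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v)


def _rot(axis, angle):
    x, y, z = _unit(axis)
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _perp(u):
    u = _unit(u)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, ref))


def _sp3_from_one(u, phase=0.0):
    """Three sp3 directions completing one existing bond direction ``u``."""
    u = _unit(u)
    w = _perp(u)
    directions = []
    for k in range(3):
        phi = phase + k * 2 * np.pi / 3
        d = (
            np.cos(TET_ANGLE) * u
            + np.sin(TET_ANGLE) * (np.cos(phi) * w + np.sin(phi) * np.cross(u, w))
        )
        directions.append(d)
    return directions


def _sp3_complete(u, v):
    """Two directions completing a (near-)tetrahedral pair ``u``, ``v``."""
    u, v = _unit(u), _unit(v)
    bisector = -_unit(u + v)
    normal = _unit(np.cross(u, v))
    # exact for ideal tetrahedral input; good approximation under ring strain
    half = np.sqrt(2.0 / 3.0)
    in_plane = np.sqrt(max(0.0, 1.0 - half**2))
    return [
        _unit(in_plane * bisector + half * normal),
        _unit(in_plane * bisector - half * normal),
    ]


def _sp2_others(u, normal):
    """The two remaining sp2 directions given one bond direction."""
    return [_rot(normal, 2 * np.pi / 3) @ _unit(u), _rot(normal, -2 * np.pi / 3) @ _unit(u)]


class _Builder:
    def __init__(self, res_name="UNL", hetero=True):
        self.elements, self.names, self.coords = [], [], []
        self.charges, self.bonds = [], []
        self.res_name = res_name
        self.hetero = hetero

    def atom(self, element, coord, name=None, charge=0):
        self.elements.append(element)
        self.coords.append(np.asarray(coord, dtype=np.float64))
        self.names.append(name)
        self.charges.append(charge)
        return len(self.elements) - 1

    def bond(self, a, b, order=S):
        self.bonds.append((a, b, order))

    def hydrogens(self, center, directions, length=CH):
        out = []
        for d in directions:
            h = self.atom("H", self.coords[center] + length * _unit(d))
            self.bond(center, h)
            out.append(h)
        return out

    def build(self):
        counters: dict[str, int] = {}
        names = []
        for e, n in zip(self.elements, self.names):
            if n is not None:
                names.append(n)
            else:
                counters[e] = counters.get(e, 0) + 1
                names.append(f"{e}{counters[e]}")
        return MolecularModel.from_arrays(
            self.elements, np.array(self.coords),
            atom_name=names,
            res_name=[self.res_name] * len(self.elements),
            is_hetero=[self.hetero] * len(self.elements),
            formal_charge=self.charges,
            bonds=self.bonds,
        )


# ----------------------------------------------------------------------
def _methane():
    b = _Builder()
    c = b.atom("C", [0, 0, 0])
    t = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
    b.hydrogens(c, t)
    return b.build()


def _ethane():
    b = _Builder()
    c1 = b.atom("C", [0, 0, 0])
    c2 = b.atom("C", [CC, 0, 0])
    b.bond(c1, c2)
    b.hydrogens(c1, _sp3_from_one([1, 0, 0], phase=0.0))
    b.hydrogens(c2, _sp3_from_one([-1, 0, 0], phase=np.pi))   # staggered
    return b.build()


def _ethanol():
    b = _Builder()
    c2 = b.atom("C", [0, 0, 0])                       # CH2
    c1 = b.atom("C", [-CC, 0, 0])                     # methyl
    o_dir = np.cos(TET_ANGLE) * np.array([-1.0, 0, 0]) + np.sin(TET_ANGLE) * np.array([0, 0, 1.0])
    o = b.atom("O", CO * o_dir)
    b.bond(c1, c2)
    b.bond(c2, o)
    b.hydrogens(c2, _sp3_complete([-1, 0, 0], o_dir))
    b.hydrogens(c1, _sp3_from_one([1, 0, 0], phase=np.pi))
    # hydroxyl H anti to the C1-C2 bond
    oh_dirs = _sp3_from_one(_unit(b.coords[c2] - b.coords[o]), phase=0.0)
    best = max(oh_dirs, key=lambda d: np.dot(d, [ -1, 0, 0]))
    b.hydrogens(o, [best], length=OH)
    return b.build()


def _water():
    b = _Builder(res_name="HOH")
    o = b.atom("O", [0, 0, 0])
    half = np.deg2rad(104.5) / 2
    b.hydrogens(o, [[np.sin(half), np.cos(half), 0], [-np.sin(half), np.cos(half), 0]],
                length=OH)
    return b.build()


def _ring(n_members, bond_length):
    """Planar regular ring coordinates in the xy plane."""
    radius = bond_length / (2 * np.sin(np.pi / n_members))
    return [
        radius * np.array([np.cos(2 * np.pi * k / n_members),
                           np.sin(2 * np.pi * k / n_members), 0.0])
        for k in range(n_members)
    ]


def _benzene():
    b = _Builder()
    ring = [b.atom("C", p) for p in _ring(6, CC_AROMATIC)]
    for k in range(6):
        b.bond(ring[k], ring[(k + 1) % 6], A)
        b.hydrogens(ring[k], [b.coords[ring[k]]])     # radial, ring is origin-centered
    return b.build()


def _toluene():
    b = _Builder()
    ring = [b.atom("C", p) for p in _ring(6, CC_AROMATIC)]
    for k in range(6):
        b.bond(ring[k], ring[(k + 1) % 6], A)
    out0 = _unit(b.coords[ring[0]])
    me = b.atom("C", b.coords[ring[0]] + CC_SP2 * out0)
    b.bond(ring[0], me)
    for k in range(1, 6):
        b.hydrogens(ring[k], [b.coords[ring[k]]])
    b.hydrogens(me, _sp3_from_one(-out0, phase=np.pi / 2))
    return b.build()


def _isobutylene():
    b = _Builder()
    c1 = b.atom("C", [0, 0, 0])                       # (CH3)2-C=
    c2 = b.atom("C", [CC_DOUBLE, 0, 0])               # =CH2
    b.bond(c1, c2, D)
    normal = np.array([0, 0, 1.0])
    for d in _sp2_others([1, 0, 0], normal):          # two methyl carbons on c1
        me = b.atom("C", CC_SP2 * d)
        b.bond(c1, me)
        b.hydrogens(me, _sp3_from_one(-d, phase=0.0))
    b.hydrogens(c2, _sp2_others([-1, 0, 0], normal))
    return b.build()


def _formamide():
    b = _Builder()
    c = b.atom("C", [0, 0, 0])
    normal = np.array([0, 0, 1.0])
    o_dir = np.array([np.cos(np.pi / 3), np.sin(np.pi / 3), 0.0])
    n_dir = np.array([np.cos(np.pi / 3), -np.sin(np.pi / 3), 0.0])
    o = b.atom("O", CO_DOUBLE * o_dir)
    n = b.atom("N", CN_SP2 * n_dir)
    b.bond(c, o, D)
    b.bond(c, n, S)                                   # relabeled partial-double downstream
    b.hydrogens(c, [-(o_dir + n_dir)])
    b.hydrogens(n, _sp2_others(_unit(-CN_SP2 * n_dir), normal), length=NH)
    return b.build()


def _methylamine():
    b = _Builder()
    c = b.atom("C", [0, 0, 0])
    n = b.atom("N", [CN, 0, 0])
    b.bond(c, n)
    b.hydrogens(c, _sp3_from_one([1, 0, 0], phase=np.pi))
    nh = _sp3_from_one([-1, 0, 0], phase=0.0)[:2]     # pyramidal: lone pair takes a slot
    b.hydrogens(n, nh, length=NH)
    return b.build()


def _alanine():
    b = _Builder(res_name="ALA", hetero=False)
    t = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
    ca = b.atom("C", [0, 0, 0], name="CA")
    n = b.atom("N", CN * t[0], name="N")
    c = b.atom("C", CC * t[1], name="C")
    cb = b.atom("C", CC * t[2], name="CB")
    b.bond(n, ca); b.bond(ca, c); b.bond(ca, cb)
    b.hydrogens(ca, [t[3]])                           # HA
    b.hydrogens(n, _sp3_from_one(-t[0], phase=0.0)[:2], length=NH)
    b.hydrogens(cb, _sp3_from_one(-t[2], phase=0.0))
    # carboxyl: sp2 at C in the plane spanned by the CA-C bond and z
    u = _unit(-CC * t[1])                             # C -> CA
    normal = _unit(np.cross(u, [0, 0, 1.0]))
    d_o, d_oxt = _sp2_others(u, normal)
    o = b.atom("O", b.coords[c] + CO_DOUBLE * d_o, name="O")
    oxt = b.atom("O", b.coords[c] + 1.34 * d_oxt, name="OXT")
    b.bond(c, o, D); b.bond(c, oxt, S)
    hx_dirs = _sp3_from_one(_unit(b.coords[c] - b.coords[oxt]), phase=0.0)
    best = max(hx_dirs, key=lambda dd: np.dot(dd, d_o))
    b.hydrogens(oxt, [best], length=OH)
    return b.build()


def _chair_ring():
    """Ideal chair cyclohexane skeleton: C-C 1.54 Å, all angles 109.471°."""
    def angle_at_vertex(z):
        r = np.sqrt(CC**2 - 4 * z**2)
        pts = [np.array([r * np.cos(k * np.pi / 3), r * np.sin(k * np.pi / 3),
                         (z if k % 2 == 0 else -z)]) for k in range(6)]
        v1 = pts[1] - pts[0]
        v2 = pts[5] - pts[0]
        return np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    z = brentq(lambda zz: angle_at_vertex(zz) - TET_ANGLE, 1e-6, CC / 2 - 1e-6)
    r = np.sqrt(CC**2 - 4 * z**2)
    return [np.array([r * np.cos(k * np.pi / 3), r * np.sin(k * np.pi / 3),
                      (z if k % 2 == 0 else -z)]) for k in range(6)]


def _hydroxy_ring(points):
    """Carbon ring from ``points`` with a hydroxyl on the first carbon; all
    other ring carbons get two hydrogens."""
    b = _Builder()
    ring = [b.atom("C", p) for p in points]
    n = len(points)
    for k in range(n):
        b.bond(ring[k], ring[(k + 1) % n])
    for k in range(n):
        here = b.coords[ring[k]]
        u = _unit(b.coords[ring[(k + 1) % n]] - here)
        v = _unit(b.coords[ring[(k - 1) % n]] - here)
        d1, d2 = _sp3_complete(u, v)
        if k == 0:
            o = b.atom("O", here + CO * d1)
            b.bond(ring[0], o)
            # H opposite the heavy substituents (exactly tetrahedral only
            # in the unstrained ring)
            b.hydrogens(ring[0], [-(u + v + d1)])
            oh_dirs = _sp3_from_one(_unit(here - b.coords[o]), phase=0.0)
            best = max(oh_dirs, key=lambda dd: np.dot(dd, d2))
            b.hydrogens(o, [best], length=OH)
        else:
            b.hydrogens(ring[k], [d1, d2])
    return b.build()


def _pyranose():
    return _hydroxy_ring(_chair_ring())


def _furanose():
    return _hydroxy_ring(_ring(5, CC))


def _arginine_sidechain():
    b = _Builder()
    normal = np.array([0, 0, 1.0])
    cz = b.atom("C", [0, 0, 0])
    ne_dir = np.array([1.0, 0, 0])
    nh1_dir, nh2_dir = _sp2_others(ne_dir, normal)
    ne = b.atom("N", CN_SP2 * ne_dir)
    nh1 = b.atom("N", CN_SP2 * nh1_dir, charge=1)
    nh2 = b.atom("N", CN_SP2 * nh2_dir)
    b.bond(cz, ne, S)       # partial-double after relabel
    b.bond(cz, nh1, D)      # protonated imine =NH2+
    b.bond(cz, nh2, S)      # partial-double after relabel
    cd = b.atom("C", b.coords[ne] + CN * _sp2_others(-ne_dir, normal)[0])
    b.bond(ne, cd)
    b.hydrogens(ne, [_sp2_others(-ne_dir, normal)[1]], length=NH)
    b.hydrogens(nh1, _sp2_others(-nh1_dir, normal), length=NH)
    b.hydrogens(nh2, _sp2_others(-nh2_dir, normal), length=NH)
    b.hydrogens(cd, _sp3_from_one(_unit(b.coords[ne] - b.coords[cd]), phase=0.0))
    return b.build()


_GENERATORS = {
    "methane": _methane,
    "ethane": _ethane,
    "ethanol": _ethanol,
    "water": _water,
    "benzene": _benzene,
    "toluene": _toluene,
    "isobutylene": _isobutylene,
    "formamide": _formamide,
    "methylamine": _methylamine,
    "alanine": _alanine,
    "pyranose": _pyranose,
    "furanose": _furanose,
    "arginine-sidechain": _arginine_sidechain,
}

_ALIASES = {
    "glucopyranose-like ring": "pyranose",
    "furanose-like ring": "furanose",
}

FIXTURE_NAMES = tuple(_GENERATORS)


def available_fixtures() -> tuple[str, ...]:
    return FIXTURE_NAMES


def make_molecule(name: str) -> MolecularModel:
    """Build a fixture molecule by name (deterministic coordinates)."""
    key = _ALIASES.get(name, name)
    try:
        generator = _GENERATORS[key]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return generator()


def default_library() -> FragmentLibrary:
    """The packaged starter library: all fixtures, in name order."""
    return build_library(make_molecule(n) for n in FIXTURE_NAMES)
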