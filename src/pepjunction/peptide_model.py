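"""Idealized all-atom peptide geometry builder and topology model.

Peptides studied in single-molecule junction experiments are short
(3-8 residues) methionine-anchored sequences drawn from the alphabet
{M, G, A, Y, W, P}.  This module builds self-consistent all-atom
conformations from backbone dihedral angles using ideal internal
coordinates (NeRF chain extension), defines the covalent topology, and
exposes the backbone constructs the downstream analyses rely on:

* the shared backbone heavy-atom subgraph used for distance-matrix
  featurization (N, CA, C, O per residue plus the C-terminal OXT,
  i.e. 4n + 1 atoms),
* the i -> i+3 backbone hydrogen-bond donor/acceptor pairs that define
  beta turns and 3_10 helices.

Termini are always built zwitterionic (ammonium N-terminus, carboxylate
C-terminus), matching aqueous conditions at neutral pH.  The pulling
axis is +z by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VALID_RESIDUES",
    "Atom",
    "BackboneTopology",
    "Conformation",
    "DihedralSet",
    "HBondPair",
    "build_topology",
    "build_conformation",
    "ConformationBuilder",
    "measure_dihedrals",
    "randomize_dihedrals",
    "shared_backbone_subgraph",
    "backbone_hbond_pairs",
    "write_pdb",
    "read_pdb",
    "write_xyz",
]

VALID_RESIDUES = frozenset("MGAYWP")

THREE_LETTER = {
    "M": "MET",
    "G": "GLY",
    "A": "ALA",
    "Y": "TYR",
    "W": "TRP",
    "P": "PRO",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}

# Ideal internal coordinates (lengths in A, angles in degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_C_OXT = 1.251
BOND_N_H = 1.010
BOND_CA_HA = 1.090
BOND_CA_CB = 1.530
BOND_S_C = 1.810

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_CA_C_OXT = 117.0
ANGLE_C_N_H = 119.0
ANGLE_CA_N_H = 109.5

# Ideal bond lengths by unordered element pair, used by the geometry
# self-check (|built - ideal| must stay within 15%).
IDEAL_BOND_LENGTH = {
    frozenset(["N", "C"]): 1.40,
    frozenset(["C", "C"]): 1.50,
    frozenset(["C", "O"]): 1.24,
    frozenset(["C", "S"]): 1.81,
    frozenset(["N", "H"]): 1.01,
    frozenset(["C", "H"]): 1.09,
    frozenset(["O", "H"]): 0.97,
}


@dataclass(frozen=True)
class Atom:
    """One atom of a peptide topology (ids 0-based, residues 1-based)."""

    atom_id: int
    element: str
    residue_index: int
    role: str


@dataclass
class BackboneTopology:
    """Covalent topology of one peptide: atoms, bonds, dihedral quadruples."""

    sequence: str
    atoms: list[Atom]
    covalent_bonds: list[tuple[int, int]]
    # (residue_index, name) -> 4-tuple of atom ids, or None if undefined
    dihedral_defs: dict[tuple[int, str], tuple[int, int, int, int] | None]
    _index: dict[tuple[int, str], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {(a.residue_index, a.role): a.atom_id for a in self.atoms}

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_id(self, residue_index: int, role: str) -> int:
        """Atom id of (residue, role); KeyError if absent."""
        return self._index[(residue_index, role)]

    def has_atom(self, residue_index: int, role: str) -> bool:
        return (residue_index, role) in self._index

    def sulfur_ids(self) -> tuple[int, int]:
        """Ids of the two thioether sulfurs (role SD), N-terminal first."""
        sd = [a for a in self.atoms if a.role == "SD"]
        if len(sd) != 2:
            raise ValueError(
                f"expected exactly 2 SD sulfurs, found {len(sd)} "
                f"in sequence {self.sequence!r}"
            )
        sd.sort(key=lambda a: a.residue_index)
        return sd[0].atom_id, sd[1].atom_id

    def sulfur_carbon_neighbors(self, sulfur_id: int) -> tuple[int, int]:
        """(CG, CE) carbon ids covalently bonded to a given sulfur."""
        res = self.atoms[sulfur_id].residue_index
        return self.atom_id(res, "CG"), self.atom_id(res, "CE")

    def bond_graph_adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j in self.covalent_bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj


@dataclass
class DihedralSet:
    """Per-residue backbone dihedrals in degrees, each in (-180, 180].

    phi of residue 1 and omega of residue 1 have no preceding atoms; they
    are carried but ignored by the builder.  psi of the last residue is
    defined against OXT (N-CA-C-OXT).
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        n = len(self.phi)
        if len(self.psi) != n or len(self.omega) != n:
            raise ValueError("phi, psi, omega must have equal lengths")

    @property
    def n_residues(self) -> int:
        return len(self.phi)

    def copy(self) -> "DihedralSet":
        return DihedralSet(self.phi.copy(), self.psi.copy(), self.omega.copy())


@dataclass
class Conformation:
    """A peptide geometry: topology plus per-atom Cartesian coords in A."""

    topology: BackboneTopology
    coords: np.ndarray  # (n_atoms, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"topology with {self.topology.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")


@dataclass(frozen=True)
class HBondPair:
    """Backbone i -> i+3 donor/acceptor pair (amide H of i+3, carbonyl O of i)."""

    donor_h_id: int
    acceptor_o_id: int
    label: str
    canonical: bool


def _validate_sequence(sequence: str) -> str:
    sequence = str(sequence).upper()
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise ValueError(f"unknown residue code(s) {sorted(bad)} in {sequence!r}")
    if not 3 <= len(sequence) <= 8:
        raise ValueError(f"sequence length must be 3-8, got {len(sequence)}")
    return sequence


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position of atom D bonded to c, with angle(b,c,D)
    and dihedral(a,b,c,D) given."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        bond * math.sin(ang) * math.sin(dih),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


# ---------------------------------------------------------------------------
# Side-chain definitions.
#
# Chain entries: (role, element, bond, angle_deg, dihedral_deg, ref_roles)
# where ref_roles are the (A, B, C) NeRF references within the same residue
# and the new atom is bonded to C.  "Improper" placements hang off CA using
# the (N, C, CA) triad, which makes the whole side chain rotate rigidly with
# phi about the N-CA axis.

_IMPROPER_CB = ("CB", "C", BOND_CA_CB, 110.1, 122.5, ("N", "C", "CA"))

_SIDE_CHAINS: dict[str, list[tuple]] = {
    "G": [],
    "A": [_IMPROPER_CB],
    "M": [
        _IMPROPER_CB,
        ("CG", "C", 1.520, 114.0, 180.0, ("N", "CA", "CB")),
        ("SD", "S", BOND_S_C, 112.7, 180.0, ("CA", "CB", "CG")),
        ("CE", "C", BOND_S_C, 100.2, 180.0, ("CB", "CG", "SD")),
    ],
    # Proline ring closed back onto N; chi values chosen so the N-CD
    # closure bond lands near its ideal 1.47 A (phi-independent, see
    # the rigid-rotation note above).
    "P": [
        ("CB", "C", BOND_CA_CB, 103.2, 115.0, ("N", "C", "CA")),
        ("CG", "C", 1.495, 104.5, 31.49, ("N", "CA", "CB")),
        ("CD", "C", 1.507, 105.5, -30.85, ("CA", "CB", "CG")),
    ],
    # Aromatic side chains: CB and CG by NeRF, rings by planar template.
    "Y": [
        _IMPROPER_CB,
        ("CG", "C", 1.510, 113.9, 180.0, ("N", "CA", "CB")),
    ],
    "W": [
        _IMPROPER_CB,
        ("CG", "C", 1.500, 113.6, 180.0, ("N", "CA", "CB")),
    ],
}

_SIDE_CHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "G": [],
    "A": [("CA", "CB")],
    "M": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "P": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "Y": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"),
          ("CE1", "CZ"), ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG"),
          ("CZ", "OH")],
    "W": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "NE1"),
          ("NE1", "CE2"), ("CE2", "CD2"), ("CD2", "CG"), ("CE2", "CZ2"),
          ("CZ2", "CH2"), ("CH2", "CZ3"), ("CZ3", "CE3"), ("CE3", "CD2")],
}


def _hexagon_template(side: float = 1.39) -> dict[str, np.ndarray]:
    """Planar phenol-ring template in 2D, CG at origin, ring along +x."""
    c = np.array([side, 0.0])
    roles = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    angles = [180.0, 120.0, 60.0, 0.0, -60.0, -120.0]
    tmpl = {r: c + side * np.array([math.cos(math.radians(a)),
                                    math.sin(math.radians(a))])
            for r, a in zip(roles, angles)}
    tmpl["OH"] = tmpl["CZ"] + np.array([1.36, 0.0])
    return tmpl


def _indole_template(side: float = 1.40) -> dict[str, np.ndarray]:
    """Planar indole template: regular pentagon fused to a regular hexagon
    on the CD2-CE2 edge, CG at origin."""
    r_pent = side / (2.0 * math.sin(math.pi / 5.0))
    c5 = np.array([r_pent, 0.0])
    roles5 = ["CG", "CD1", "NE1", "CE2", "CD2"]
    angles5 = [180.0, 108.0, 36.0, -36.0, -108.0]
    tmpl = {r: c5 + r_pent * np.array([math.cos(math.radians(a)),
                                       math.sin(math.radians(a))])
            for r, a in zip(roles5, angles5)}
    cd2, ce2 = tmpl["CD2"], tmpl["CE2"]
    mid = 0.5 * (cd2 + ce2)
    edge = (ce2 - cd2) / np.linalg.norm(ce2 - cd2)
    perp = np.array([edge[1], -edge[0]])
    if np.dot(perp, mid - c5) < 0:
        perp = -perp
    c6 = mid + perp * (side * math.sqrt(3.0) / 2.0)
    # hexagon order CD2 -> CE2 -> CZ2 -> CH2 -> CZ3 -> CE3
    a0 = math.atan2(*(cd2 - c6)[::-1])
    a1 = math.atan2(*(ce2 - c6)[::-1])
    step = a1 - a0
    step -= 2 * math.pi * round(step / (2 * math.pi) - 1e-9)  # wrap
    if abs(abs(step) - math.pi / 3.0) > 1e-6:
        step = math.copysign(math.pi / 3.0, step)
    for k, role in enumerate(["CZ2", "CH2", "CZ3", "CE3"], start=2):
        a = a0 + k * step
        tmpl[role] = c6 + side * np.array([math.cos(a), math.sin(a)])
    return tmpl


_RING_TEMPLATES = {"Y": _hexagon_template(), "W": _indole_template()}
_RING_ROLES = {
    "Y": ["CD1", "CE1", "CZ", "CE2", "CD2", "OH"],
    "W": ["CD1", "NE1", "CE2", "CD2", "CZ2", "CH2", "CZ3", "CE3"],
}
_RING_CHI2 = {"Y": 90.0, "W": 90.0}


def build_topology(sequence: str) -> BackboneTopology:
    """Covalent topology (atoms, bonds, dihedral definitions) for a sequence."""
    sequence = _validate_sequence(sequence)
    n = len(sequence)
    atoms: list[Atom] = []
    index: dict[tuple[int, str], int] = {}

    def add(res: int, role: str) -> None:
        aid = len(atoms)
        atoms.append(Atom(aid, role[0], res, role))
        index[(res, role)] = aid

    for i, code in enumerate(sequence, start=1):
        add(i, "N")
        if i == 1:
            n_h = 2 if code == "P" else 3
            for k in range(1, n_h + 1):
                add(i, f"H{k}")
        elif code != "P":
            add(i, "H")
        add(i, "CA")
        add(i, "HA")
        if code == "G":
            add(i, "HA2")
        for entry in _SIDE_CHAINS[code]:
            add(i, entry[0])
        if code in _RING_ROLES:
            for role in _RING_ROLES[code]:
                add(i, role)
        add(i, "C")
        add(i, "O")
        if i == n:
            add(i, "OXT")

    bonds: list[tuple[int, int]] = []

    def bond(res_a: int, role_a: str, res_b: int, role_b: str) -> None:
        bonds.append((index[(res_a, role_a)], index[(res_b, role_b)]))

    for i, code in enumerate(sequence, start=1):
        bond(i, "N", i, "CA")
        bond(i, "CA", i, "C")
        bond(i, "C", i, "O")
        if i == 1:
            for k in range(1, (2 if code == "P" else 3) + 1):
                bond(i, "N", i, f"H{k}")
        elif code != "P":
            bond(i, "N", i, "H")
        bond(i, "CA", i, "HA")
        if code == "G":
            bond(i, "CA", i, "HA2")
        for ra, rb in _SIDE_CHAIN_BONDS[code]:
            bond(i, ra, i, rb)
        if i < len(sequence):
            bond(i, "C", i + 1, "N")
        else:
            bond(i, "C", i, "OXT")

    dihedral_defs: dict[tuple[int, str], tuple[int, int, int, int] | None] = {}
    for i in range(1, n + 1):
        if i > 1:
            dihedral_defs[(i, "phi")] = (
                index[(i - 1, "C")], index[(i, "N")],
                index[(i, "CA")], index[(i, "C")])
            dihedral_defs[(i, "omega")] = (
                index[(i - 1, "CA")], index[(i - 1, "C")],
                index[(i, "N")], index[(i, "CA")])
        else:
            dihedral_defs[(i, "phi")] = None
            dihedral_defs[(i, "omega")] = None
        nxt = index[(i + 1, "N")] if i < n else index[(i, "OXT")]
        dihedral_defs[(i, "psi")] = (
            index[(i, "N")], index[(i, "CA")], index[(i, "C")], nxt)

    return BackboneTopology(sequence, atoms, bonds, dihedral_defs)


class ConformationBuilder:
    """Precompiled coordinate builder for one topology.

    Compiles the per-atom NeRF placement recipe (reference atom ids, ideal
    bond/angle, and which backbone dihedral drives each placement) once,
    so repeated builds — e.g. inside a Monte Carlo chain — avoid all
    per-call topology lookups.
    """

    def __init__(self, topology: BackboneTopology):
        self.topology = topology
        # instruction: (tgt, a, b, c, bond, angle_deg, dsrc, dconst)
        # dsrc: None | ("phi"|"psi"|"omega", residue_0based)
        #     | ("chi", flat_index); the dihedral used is
        # dihedrals.<dsrc>[res] + dconst (degrees), or chis[flat_index].
        self._steps: list[tuple] = []
        self._rings: list[tuple] = []  # (code, ca, cb, cg, [(tgt, tx, ty)..])
        #: (residue_index, chi_name) for each flexible side-chain torsion
        #: (methionine chi1/chi2/chi3 — the anchor-orienting torsions)
        self.chi_labels: list[tuple[int, str]] = []
        self.default_chis: np.ndarray = np.empty(0)
        self._compile()

    def _compile(self) -> None:
        topo = self.topology
        seq = topo.sequence
        n = topo.n_residues
        aid = topo.atom_id
        steps = self._steps
        for i in range(1, n + 1):
            code = seq[i - 1]
            if i > 1:
                steps.append((aid(i, "N"), aid(i - 1, "N"), aid(i - 1, "CA"),
                              aid(i - 1, "C"), BOND_C_N, ANGLE_CA_C_N,
                              ("psi", i - 2), 0.0))
                steps.append((aid(i, "CA"), aid(i - 1, "CA"), aid(i - 1, "C"),
                              aid(i, "N"), BOND_N_CA, ANGLE_C_N_CA,
                              ("omega", i - 1), 0.0))
                steps.append((aid(i, "C"), aid(i - 1, "C"), aid(i, "N"),
                              aid(i, "CA"), BOND_CA_C, ANGLE_N_CA_C,
                              ("phi", i - 1), 0.0))
                if code != "P":
                    steps.append((aid(i, "H"), aid(i - 1, "CA"),
                                  aid(i - 1, "C"), aid(i, "N"),
                                  BOND_N_H, ANGLE_C_N_H, None, 0.0))
            # carbonyl O anti to the next N (or to OXT for the last residue)
            steps.append((aid(i, "O"), aid(i, "N"), aid(i, "CA"), aid(i, "C"),
                          BOND_C_O, ANGLE_CA_C_O, ("psi", i - 1), 180.0))
            if i == n:
                steps.append((aid(i, "OXT"), aid(i, "N"), aid(i, "CA"),
                              aid(i, "C"), BOND_C_OXT, ANGLE_CA_C_OXT,
                              ("psi", i - 1), 0.0))
            if i == 1:
                n_h = 2 if code == "P" else 3
                for k in range(1, n_h + 1):
                    steps.append((aid(1, f"H{k}"), aid(1, "C"), aid(1, "CA"),
                                  aid(1, "N"), 1.040, ANGLE_CA_N_H,
                                  None, 60.0 + 120.0 * (k - 1)))
            steps.append((aid(i, "HA"), aid(i, "N"), aid(i, "C"),
                          aid(i, "CA"), BOND_CA_HA, 108.5, None, -116.0))
            if code == "G":
                steps.append((aid(i, "HA2"), aid(i, "N"), aid(i, "C"),
                              aid(i, "CA"), BOND_CA_HA, 110.1, None, 122.5))
            default_chis = list(self.default_chis)
            for role, _el, bnd, ang, dih, refs in _SIDE_CHAINS[code]:
                a, b, c = (aid(i, r) for r in refs)
                if code == "M" and role in ("CG", "SD", "CE"):
                    chi_name = {"CG": "chi1", "SD": "chi2", "CE": "chi3"}[role]
                    dsrc = ("chi", len(self.chi_labels))
                    self.chi_labels.append((i, chi_name))
                    default_chis.append(dih)
                    steps.append((aid(i, role), a, b, c, bnd, ang, dsrc, 0.0))
                else:
                    steps.append((aid(i, role), a, b, c, bnd, ang, None, dih))
            self.default_chis = np.array(default_chis)
            if code in _RING_TEMPLATES:
                tmpl = _RING_TEMPLATES[code]
                origin2d = tmpl["CG"]
                ring = [(aid(i, role), *(tmpl[role] - origin2d))
                        for role in _RING_ROLES[code]]
                self._rings.append((code, aid(i, "CA"), aid(i, "CB"),
                                    aid(i, "CG"), ring))

    def build(self, dihedrals: DihedralSet,
              chis: np.ndarray | None = None,
              rotation: np.ndarray | None = None) -> np.ndarray:
        """Coordinates (n_atoms, 3) for the given backbone dihedrals.

        ``chis`` overrides the flexible side-chain torsions listed in
        :attr:`chi_labels` (defaults used when None).  ``rotation``, a
        3x3 matrix, rigidly reorients the molecule about the origin —
        the builder's internal frame pins residue 1, so sampling in a
        z-dependent external potential needs this degree of freedom.
        """
        topo = self.topology
        if dihedrals.n_residues != topo.n_residues:
            raise ValueError(
                f"dihedral count {dihedrals.n_residues} != residue "
                f"count {topo.n_residues}")
        dih_arr = {"phi": dihedrals.phi, "psi": dihedrals.psi,
                   "omega": dihedrals.omega}
        chi_arr = self.default_chis if chis is None else np.asarray(chis)
        if len(chi_arr) != len(self.chi_labels):
            raise ValueError(
                f"expected {len(self.chi_labels)} chi values, "
                f"got {len(chi_arr)}")
        xyz = np.empty((topo.n_atoms, 3))
        # seed triad: N1 at origin, CA1 on +x, C1 in the xy-plane
        xyz[topo.atom_id(1, "N")] = (0.0, 0.0, 0.0)
        xyz[topo.atom_id(1, "CA")] = (BOND_N_CA, 0.0, 0.0)
        th = math.radians(ANGLE_N_CA_C)
        xyz[topo.atom_id(1, "C")] = (
            BOND_N_CA + BOND_CA_C * math.cos(math.pi - th),
            BOND_CA_C * math.sin(math.pi - th), 0.0)
        for tgt, a, b, c, bond, angle, dsrc, dconst in self._steps:
            if dsrc is None:
                dih = dconst
            elif dsrc[0] == "chi":
                dih = chi_arr[dsrc[1]]
            else:
                dih = dih_arr[dsrc[0]][dsrc[1]] + dconst
            xyz[tgt] = _place_fast(xyz[a], xyz[b], xyz[c], bond, angle, dih)
        for code, ca, cb, cg, ring in self._rings:
            _embed_ring(xyz, ca, cb, cg, _RING_CHI2[code], ring)
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation).T
        return xyz


def _place_fast(pa, pb, pc, bond: float, angle_deg: float,
                dihedral_deg: float):
    """Scalar-math NeRF placement (same convention as :func:`_place`)."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    ax, ay, az = pa
    bx, by, bz = pb
    cx, cy, cz = pc
    bcx, bcy, bcz = cx - bx, cy - by, cz - bz
    inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
    abx, aby, abz = bx - ax, by - ay, bz - az
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx * inv, ny * inv, nz * inv
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * math.cos(ang)
    d1 = bond * math.sin(ang) * math.cos(dih)
    d2 = bond * math.sin(ang) * math.sin(dih)
    return (cx + d0 * bcx + d1 * mx + d2 * nx,
            cy + d0 * bcy + d1 * my + d2 * ny,
            cz + d0 * bcz + d1 * mz + d2 * nz)


def _embed_ring(xyz: np.ndarray, ca: int, cb: int, cg: int,
                chi2_deg: float, ring: list[tuple]) -> None:
    """Embed a planar 2D ring template at CG; plane set by chi2 about CB-CG."""
    x = xyz[cg] - xyz[cb]
    x /= np.linalg.norm(x)
    w = xyz[ca] - xyz[cb]
    w = w - np.dot(w, x) * x
    w /= np.linalg.norm(w)
    chi2 = math.radians(chi2_deg)
    y = w * math.cos(chi2) + np.cross(x, w) * math.sin(chi2)
    for tgt, tx, ty in ring:
        xyz[tgt] = xyz[cg] + tx * x + ty * y


def build_conformation(sequence: str | BackboneTopology,
                       dihedrals: DihedralSet) -> Conformation:
    """Build an all-atom conformation with the requested backbone dihedrals.

    Bond lengths and angles are ideal; omega controls the peptide-bond
    geometry (180 = trans).  The constructed dihedrals round-trip through
    :func:`measure_dihedrals` to within 1e-6 degrees.
    """
    topo = sequence if isinstance(sequence, BackboneTopology) \
        else build_topology(sequence)
    return Conformation(topo, ConformationBuilder(topo).build(dihedrals))


def measure_dihedrals(conf: Conformation) -> DihedralSet:
    """Backbone dihedrals of a conformation; NaN where undefined."""
    topo = conf.topology
    n = topo.n_residues
    out = {name: np.full(n, np.nan) for name in ("phi", "psi", "omega")}
    for (res, name), quad in topo.dihedral_defs.items():
        if quad is None:
            continue
        p = [conf.coords[i] for i in quad]
        out[name][res - 1] = dihedral_angle(*p)
    return DihedralSet(out["phi"], out["psi"], out["omega"])


def randomize_dihedrals(topology: BackboneTopology,
                        rng_seed: int | np.random.Generator) -> DihedralSet:
    """Random initial backbone dihedrals: phi/psi uniform on (-180, 180],
    except proline phi uniform on [-80, -50]; omega fixed at 180 (trans).
    Deterministic given the seed."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    n = topology.n_residues
    phi = rng.uniform(-180.0, 180.0, size=n)
    psi = rng.uniform(-180.0, 180.0, size=n)
    # map the half-open [-180, 180) draw onto the (-180, 180] convention
    phi[phi == -180.0] = 180.0
    psi[psi == -180.0] = 180.0
    for i, code in enumerate(topology.sequence):
        if code == "P":
            phi[i] = rng.uniform(-80.0, -50.0)
    omega = np.full(n, 180.0)
    return DihedralSet(phi, psi, omega)


_SUBGRAPH_ROLES = ("N", "CA", "C", "O")


def shared_backbone_subgraph(
        topologies: list[BackboneTopology],
) -> tuple[list[tuple[int, str]], list[list[int]]]:
    """Backbone heavy-atom subgraph shared by equal-length sequences.

    Returns the ordered (residue_index, role) list -- N, CA, C, O per
    residue from N- to C-terminus, then the C-terminal OXT (4n + 1 atoms
    total) -- plus, per topology, the atom ids realizing it.
    """
    if not topologies:
        raise ValueError("need at least one topology")
    n = topologies[0].n_residues
    if any(t.n_residues != n for t in topologies):
        raise ValueError("topologies have mixed residue counts")
    roles = [(i, r) for i in range(1, n + 1) for r in _SUBGRAPH_ROLES]
    roles.append((n, "OXT"))
    mappings = [[t.atom_id(i, r) for i, r in roles] for t in topologies]
    return roles, mappings


def backbone_hbond_pairs(topology: BackboneTopology) -> list[HBondPair]:
    """All i -> i+3 backbone H-bond pairs (carbonyl O of residue i, amide H
    of residue i+3).  Pairs whose donor residue is proline (no amide H) are
    omitted.  For pentapeptides the 2 -> 5 pair is flagged canonical; for
    tetrapeptides 1 -> 4 is canonical."""
    n = topology.n_residues
    if n < 4:
        raise ValueError("i -> i+3 H-bonds require at least 4 residues")
    canonical_label = "2→5" if n >= 5 else "1→4"
    pairs: list[HBondPair] = []
    for i in range(1, n - 2):
        j = i + 3
        label = f"{i}→{j}"
        if not topology.has_atom(j, "H"):
            continue  # proline donor: no amide hydrogen
        pairs.append(HBondPair(
            donor_h_id=topology.atom_id(j, "H"),
            acceptor_o_id=topology.atom_id(i, "O"),
            label=label,
            canonical=(label == canonical_label),
        ))
    return pairs


# ---------------------------------------------------------------------------
# File I/O (PDB via Biopython, XYZ plain text)

def write_pdb(path, conformations: "Conformation | list[Conformation]") -> None:
    """Write one or more conformations of the same topology as a
    (multi-MODEL) PDB file, chain A, 1-based residue numbering."""
    from Bio.PDB import PDBIO
    from Bio.PDB.StructureBuilder import StructureBuilder

    confs = [conformations] if isinstance(conformations, Conformation) \
        else list(conformations)
    builder = StructureBuilder()
    builder.init_structure("pep")
    for model_i, conf in enumerate(confs):
        builder.init_model(model_i)
        builder.init_chain("A")
        builder.init_seg("    ")
        topo = conf.topology
        current_res = 0
        for atom in topo.atoms:
            if atom.residue_index != current_res:
                current_res = atom.residue_index
                resname = THREE_LETTER[topo.sequence[current_res - 1]]
                builder.init_residue(resname, " ", current_res, " ")
            builder.init_atom(
                atom.role, conf.coords[atom.atom_id].astype(np.float32),
                0.0, 1.0, " ", atom.role, atom.atom_id + 1, atom.element)
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def read_pdb(path, sequence: str | None = None) -> list[Conformation]:
    """Read conformations from a PDB written by :func:`write_pdb` (or any
    PDB whose atom naming matches the builder's).  Returns one Conformation
    per MODEL."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("pep", str(path))
    confs: list[Conformation] = []
    topo: BackboneTopology | None = None
    for model in structure:
        chain = next(iter(model))
        if topo is None:
            seq = sequence or "".join(
                ONE_LETTER[res.get_resname()] for res in chain)
            topo = build_topology(seq)
        xyz = np.full((topo.n_atoms, 3), np.nan)
        for res in chain:
            res_i = res.get_id()[1]
            for at in res:
                xyz[topo.atom_id(res_i, at.get_name())] = at.get_coord()
        confs.append(Conformation(topo, xyz))
    return confs


def write_xyz(path, conf: Conformation, comment: str = "") -> None:
    """Write a conformation in plain XYZ format."""
    lines = [str(conf.topology.n_atoms), comment]
    for atom in conf.topology.atoms:
        x, y, z = conf.coords[atom.atom_id]
        lines.append(f"{atom.element:2s} {x:12.6f} {y:12.6f} {z:12.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
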