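"""Implicit-gold restraint potentials for peptide junction sampling.

Three potentials stand in for the gold electrodes of a single-molecule
break junction, so that junction-like conformational ensembles can be
generated without explicit metal atoms:

* ``U1`` — a harmonic restraint on the *signed* z-projection of the
  sulfur-sulfur anchor displacement, ``U1 = 1/2 k1 (z_S2 - z_S1 - z0)^2``.
  Restraining the projection (rather than the distance) confines each
  sulfur to one of two parallel planes, mimicking two electrode surfaces.
* ``U2`` — the electrostatic energy of each atomic partial charge in the
  uniform field of a voltage-biased junction,
  ``U2 = sum_i -q_i E z_i`` with ``E = V / (z0 + 2 l_S_Au)``.
* ``U3`` — a lone-pair orienting potential.  For each terminal sulfur a
  surrogate lone-pair direction ``p_i = (r_S - r_CG) + (r_S - r_CE)``
  (normalized) is steered along +/- z:
  ``U3 = sum_i k3 (p_hat_i . z_hat) (-1)^i``, bounded in [-2 k3, +2 k3].

Energies are in kcal/mol, lengths in A, charges in elementary-charge
units, voltage in volts.  All forces are analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peptide_model import BackboneTopology, Conformation

__all__ = [
    "EV_TO_KCAL_PER_MOL",
    "RestraintParams",
    "EnergyForce",
    "default_charges",
    "u1_energy_force",
    "u2_energy_force",
    "u3_energy_force",
    "total_restraint_energy",
]

#: 1 eV per particle expressed in kcal/mol.
EV_TO_KCAL_PER_MOL = 23.0605


@dataclass
class RestraintParams:
    """Parameters of the three junction restraints.

    k1 : harmonic force constant, kcal/mol/A^2 (default 1).
    z0 : holding-stage displacement, A (study stages: 6, 9, 12).
    voltage : junction bias, V.
    l_s_au : sulfur-gold dative bond length, A (default 2.4).
    k3 : lone-pair orienting strength, kcal/mol (default 10).
    charges : per-atom partial charges in e; None selects the simplified
        zwitterion model (+1 on the N-terminal ammonium nitrogen, -0.5 on
        each carboxylate oxygen).
    """

    k1: float = 1.0
    z0: float = 6.0
    voltage: float = 0.25
    l_s_au: float = 2.4
    k3: float = 10.0
    charges: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.z0 <= 0 or self.l_s_au <= 0:
            raise ValueError("k1, z0 and l_s_au must be positive")
        if self.k3 < 0:
            raise ValueError("k3 must be non-negative")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)

    @property
    def field_strength(self) -> float:
        """Electric field magnitude V / (z0 + 2 l_S_Au), in V/A."""
        return self.voltage / (self.z0 + 2.0 * self.l_s_au)

    def charges_for(self, topology: BackboneTopology) -> np.ndarray:
        if self.charges is None:
            return default_charges(topology)
        if len(self.charges) != topology.n_atoms:
            raise ValueError(
                f"charge array length {len(self.charges)} != "
                f"{topology.n_atoms} atoms")
        return self.charges


@dataclass
class EnergyForce:
    """An energy (kcal/mol) with per-atom Cartesian forces (kcal/mol/A)."""

    energy: float
    forces: np.ndarray

    def __add__(self, other: "EnergyForce") -> "EnergyForce":
        return EnergyForce(self.energy + other.energy,
                           self.forces + other.forces)


def default_charges(topology: BackboneTopology) -> np.ndarray:
    """Simplified zwitterion charge set: +1 on the N-terminal nitrogen,
    -0.5 on each C-terminal carboxylate oxygen, zero elsewhere."""
    q = np.zeros(topology.n_atoms)
    n = topology.n_residues
    q[topology.atom_id(1, "N")] = 1.0
    q[topology.atom_id(n, "O")] = -0.5
    q[topology.atom_id(n, "OXT")] = -0.5
    return q


def u1_energy_force(conf: Conformation, params: RestraintParams) -> EnergyForce:
    """Harmonic restraint on the signed sulfur-sulfur z-displacement."""
    s1, s2 = conf.topology.sulfur_ids()
    dz = conf.coords[s2, 2] - conf.coords[s1, 2]
    delta = dz - params.z0
    energy = 0.5 * params.k1 * delta * delta
    forces = np.zeros_like(conf.coords)
    forces[s2, 2] = -params.k1 * delta
    forces[s1, 2] = params.k1 * delta
    return EnergyForce(energy, forces)


def u2_energy_force(conf: Conformation, params: RestraintParams) -> EnergyForce:
    """Uniform-field electrostatic potential of the biased junction."""
    q = params.charges_for(conf.topology)
    e_field = params.field_strength  # V/A -> eV per (e * A)
    z = conf.coords[:, 2]
    energy = float(-np.sum(q * e_field * z)) * EV_TO_KCAL_PER_MOL
    forces = np.zeros_like(conf.coords)
    forces[:, 2] = q * e_field * EV_TO_KCAL_PER_MOL
    return EnergyForce(energy, forces)


def _lone_pair_vector(conf: Conformation, s_id: int) -> tuple[np.ndarray, float]:
    cg, ce = conf.topology.sulfur_carbon_neighbors(s_id)
    p = 2.0 * conf.coords[s_id] - conf.coords[cg] - conf.coords[ce]
    norm = float(np.linalg.norm(p))
    if norm < 1e-8:
        raise ValueError(
            "degenerate lone-pair surrogate vector (collinear or "
            f"overlapping atoms at sulfur id {s_id})")
    return p, norm


def u3_energy_force(conf: Conformation, params: RestraintParams) -> EnergyForce:
    """Sulfur lone-pair orienting potential (bounded in [-2 k3, +2 k3])."""
    topo = conf.topology
    energy = 0.0
    forces = np.zeros_like(conf.coords)
    zhat = np.array([0.0, 0.0, 1.0])
    for i, s_id in enumerate(topo.sulfur_ids(), start=1):
        sign = (-1.0) ** i
        p, norm = _lone_pair_vector(conf, s_id)
        phat = p / norm
        cos_z = phat[2]
        energy += params.k3 * cos_z * sign
        # d(cos_z)/dp = (zhat - cos_z * phat) / |p|
        dcos_dp = (zhat - cos_z * phat) / norm
        # dp/dr_S = 2 I ; dp/dr_CG = dp/dr_CE = -I
        g = params.k3 * sign * dcos_dp
        cg, ce = topo.sulfur_carbon_neighbors(s_id)
        forces[s_id] -= 2.0 * g
        forces[cg] += g
        forces[ce] += g
    return EnergyForce(float(energy), forces)


def total_restraint_energy(conf: Conformation,
                           params: RestraintParams) -> EnergyForce:
    """Sum of the three junction restraints (energies and forces add)."""
    return (u1_energy_force(conf, params)
            + u2_energy_force(conf, params)
            + u3_energy_force(conf, params))
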