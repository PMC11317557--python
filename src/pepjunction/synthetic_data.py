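"""Synthetic inputs for the junction-analysis pipeline.

Two generators emulate the study's raw data:

1. :func:`sample_ensemble` — a Metropolis Monte Carlo sampler over
   backbone (phi, psi) dihedrals under the implicit-gold restraints plus
   a coarse intramolecular energy (soft-sphere sterics and a Gaussian
   backbone H-bond well).  It produces junction-holding conformational
   ensembles with the i -> i+3 H-bond structure the downstream analyses
   consume.  It is a desk-scale stand-in for explicit-solvent MD: the
   ensembles have the right analyzable structure (restrained anchor
   displacement, turn formation at short stages, H-bond loss at long
   stages) but carry no kinetic or solvent information.

2. :func:`generate_traces` — a break-junction conductance-trace
   simulator emitting molecular traces with a high plateau followed by a
   low plateau (sequential two-state behavior, i.e. dynamic
   heterogeneity by construction) mixed with background-only tunneling
   traces, on a uniform displacement grid of log10(G/G0) values.

Both generators are deterministic given their seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .gold_restraints import EV_TO_KCAL_PER_MOL, RestraintParams
from .peptide_model import (
    BackboneTopology,
    Conformation,
    ConformationBuilder,
    DihedralSet,
    backbone_hbond_pairs,
    build_topology,
    randomize_dihedrals,
)

__all__ = [
    "KB_KCAL",
    "SamplerConfig",
    "Ensemble",
    "TraceGenConfig",
    "ConductanceTrace",
    "coarse_energy",
    "sample_ensemble",
    "metropolis_chain",
    "generate_traces",
    "traces_to_dataframe",
    "traces_from_dataframe",
]

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872041

#: Soft-sphere contact radii by element, A (reduced vs. van der Waals so
#: that near-contact H-bond geometries are not penalized).
DEFAULT_RADII = {"C": 1.60, "N": 1.45, "O": 1.40, "S": 1.70}


@dataclass
class SamplerConfig:
    """Metropolis sampler settings.

    The move proposal perturbs one randomly chosen phi or psi by a
    Gaussian step (``move_width_deg``); proline phi is clamped to
    [-80, -50].  ``k_clash`` scales the quadratic steric overlap penalty;
    ``hbond_*`` parametrize the Gaussian donor-acceptor well applied to
    every backbone i -> i+3 O...H pair.
    """

    n_steps: int = 20000
    burn_in: int = 6000
    thin: int = 20
    temperature_K: float = 300.0
    move_width_deg: float = 15.0
    k_clash: float = 10.0  # kcal/mol/A^2
    radii: dict = field(default_factory=lambda: dict(DEFAULT_RADII))
    # Effective backbone H-bond well.  The depth is a free-energy-scale
    # effective strength (it must beat the conformational entropy of the
    # open ensemble at kT ~ 0.6), not a bare enthalpy, and the well is
    # kept wide and moderately deep rather than narrow and deep: the
    # same equilibrium turn occupancy with a far smaller kinetic barrier
    # for the Monte Carlo chain to bind/unbind.
    hbond_epsilon: float = 3.5  # kcal/mol
    hbond_d_opt: float = 2.0  # A
    hbond_width: float = 0.6  # A
    min_acceptance: float = 0.01
    # Parallel-tempering ladder (factors on temperature_K) and swap
    # attempt interval.  The H-bond well is several kT deep, so a
    # single-temperature chain freezes into or out of the turn basin for
    # entire runs; replica exchange with hot rungs restores ergodicity
    # and the retained (cold-rung) frames sample the true Boltzmann
    # ensemble.
    temperature_ladder: tuple = (1.0, 1.8, 3.24)
    swap_every: int = 5

    def __post_init__(self) -> None:
        if not self.n_steps > self.burn_in >= 0:
            raise ValueError("need n_steps > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        self.temperature_ladder = tuple(self.temperature_ladder)

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature_K


@dataclass
class Ensemble:
    """Sampled conformational ensemble for one (sequence, stage, seed)."""

    sequence: str
    stage: float
    replicate_seed: int
    topology: BackboneTopology
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    energies: np.ndarray  # kcal/mol, per frame
    acceptance_rate: float

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def conformation(self, i: int) -> Conformation:
        return Conformation(self.topology, self.frames[i])

    def iter_conformations(self):
        for i in range(self.n_frames):
            yield self.conformation(i)


class _CoarseEnergyModel:
    """Precomputed steric pair list + H-bond pairs for one topology."""

    def __init__(self, topology: BackboneTopology, config: SamplerConfig):
        self.config = config
        heavy = [a.atom_id for a in topology.atoms if a.element != "H"]
        # exclude pairs within 4 bonds (up to 1-5): nearer contacts are
        # fixed by the ideal internal coordinates, not real clashes
        adj = topology.bond_graph_adjacency()
        n = topology.n_atoms
        near: list[set[int]] = [set() for _ in range(n)]
        for i in range(n):
            frontier = {i}
            seen = {i}
            for _ in range(4):
                frontier = {k for j in frontier for k in adj[j]} - seen
                seen |= frontier
            near[i] = seen
        pairs_i, pairs_j, rmin = [], [], []
        for ii, i in enumerate(heavy):
            for j in heavy[ii + 1:]:
                if j in near[i]:
                    continue
                pairs_i.append(i)
                pairs_j.append(j)
                rmin.append(config.radii[topology.atoms[i].element]
                            + config.radii[topology.atoms[j].element])
        self.pairs_i = np.array(pairs_i, dtype=int)
        self.pairs_j = np.array(pairs_j, dtype=int)
        self.rmin = np.array(rmin)
        try:
            hb = backbone_hbond_pairs(topology)
        except ValueError:
            hb = []
        self.hb_h = np.array([p.donor_h_id for p in hb], dtype=int)
        self.hb_o = np.array([p.acceptor_o_id for p in hb], dtype=int)

    def energy(self, coords: np.ndarray) -> float:
        cfg = self.config
        e = 0.0
        if len(self.pairs_i):
            d = np.linalg.norm(coords[self.pairs_i] - coords[self.pairs_j],
                               axis=1)
            overlap = self.rmin - d
            overlap[overlap < 0] = 0.0
            e += cfg.k_clash * float(np.sum(overlap * overlap))
        if len(self.hb_h):
            d = np.linalg.norm(coords[self.hb_h] - coords[self.hb_o], axis=1)
            e -= cfg.hbond_epsilon * float(np.sum(
                np.exp(-((d - cfg.hbond_d_opt) ** 2)
                       / (2.0 * cfg.hbond_width ** 2))))
        return e


def coarse_energy(conf: Conformation,
                  sampler_config: SamplerConfig | None = None) -> float:
    """Coarse intramolecular energy: soft-sphere sterics over nonbonded
    heavy-atom pairs plus a Gaussian well on each backbone i -> i+3
    O...H distance.  kcal/mol."""
    cfg = sampler_config or SamplerConfig()
    return _CoarseEnergyModel(conf.topology, cfg).energy(conf.coords)


def metropolis_chain(x0, energy_fn, propose_fn, n_steps: int, kT,
                     rng: np.random.Generator):
    """Generic Metropolis chain.  Yields (state, energy, accepted) per step.

    ``propose_fn(state, rng)`` returns a candidate state; ``energy_fn``
    maps a state to kcal/mol.  ``kT`` is a constant (kcal/mol) or a
    callable step -> kT for annealing schedules.  Used both by the
    ensemble sampler and by low-dimensional calibration checks.
    """
    kT_fn = kT if callable(kT) else None
    x = x0
    e = energy_fn(x)
    for step in range(n_steps):
        kt = kT_fn(step) if kT_fn is not None else kT
        cand = propose_fn(x, rng)
        e_cand = energy_fn(cand)
        de = e_cand - e
        if de <= 0.0 or rng.random() < math.exp(-de / kt):
            x, e = cand, e_cand
            yield x, e, True
        else:
            yield x, e, False


@dataclass
class _SamplerState:
    """Full sampler state: backbone dihedrals, flexible Met chi torsions,
    and a rigid-body rotation of the whole molecule (the molecule must be
    free to reorient relative to the z-restraints, as it is in solution)."""

    dihedrals: DihedralSet
    chis: np.ndarray
    rotation: np.ndarray  # 3x3

    def copy(self) -> "_SamplerState":
        return _SamplerState(self.dihedrals.copy(), self.chis.copy(),
                             self.rotation.copy())


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _axis_angle_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    ux, uy, uz = axis
    c, s = math.cos(angle), math.sin(angle)
    cc = 1.0 - c
    return np.array([
        [c + ux * ux * cc, ux * uy * cc - uz * s, ux * uz * cc + uy * s],
        [uy * ux * cc + uz * s, c + uy * uy * cc, uy * uz * cc - ux * s],
        [uz * ux * cc - uy * s, uz * uy * cc + ux * s, c + uz * uz * cc],
    ])


def _propose_move(topology: BackboneTopology, config: SamplerConfig,
                  n_chis: int, uniform_fraction: float = 0.1,
                  rotation_fraction: float = 0.2):
    """Symmetric move mixture: a rigid-body rotation about a random axis,
    or a perturbation of one torsion (backbone phi/psi or a Met chi) —
    usually a Gaussian step, occasionally a full uniform redraw (aids
    barrier crossing).  Proline phi is clamped to [-80, -50]."""
    seq = topology.sequence
    n = topology.n_residues
    width = config.move_width_deg
    width_rad = math.radians(width)

    def wrap(val: float) -> float:
        val = (val + 180.0) % 360.0 - 180.0
        return 180.0 if val == -180.0 else val

    def propose(s: _SamplerState, rng: np.random.Generator) -> _SamplerState:
        cand = s.copy()
        if rng.random() < rotation_fraction:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            rot = _axis_angle_rotation(axis, rng.normal(0.0, width_rad))
            cand.rotation = rot @ cand.rotation
            return cand
        k = int(rng.integers(2 * n + n_chis))
        uniform = rng.random() < uniform_fraction
        if k >= 2 * n:  # Met side-chain chi
            j = k - 2 * n
            if uniform:
                cand.chis[j] = rng.uniform(-180.0, 180.0)
            else:
                cand.chis[j] = wrap(cand.chis[j] + rng.normal(0.0, width))
            return cand
        r, which = divmod(k, 2)
        arr = cand.dihedrals.phi if which == 0 else cand.dihedrals.psi
        if which == 0 and seq[r] == "P":
            if uniform:
                arr[r] = rng.uniform(-80.0, -50.0)
            else:
                arr[r] = min(-50.0, max(-80.0,
                                        arr[r] + rng.normal(0.0, width)))
        elif uniform:
            arr[r] = rng.uniform(-180.0, 180.0)
        else:
            arr[r] = wrap(arr[r] + rng.normal(0.0, width))
        return cand

    return propose


class _RestraintEnergyOnly:
    """Energy-only evaluation of the three gold restraints (no force
    arrays), precompiled for one topology -- the sampler's hot path."""

    def __init__(self, topology: BackboneTopology, params: RestraintParams):
        self.params = params
        self.s1, self.s2 = topology.sulfur_ids()
        self.cg1, self.ce1 = topology.sulfur_carbon_neighbors(self.s1)
        self.cg2, self.ce2 = topology.sulfur_carbon_neighbors(self.s2)
        self.charges = params.charges_for(topology)
        self.charged = np.nonzero(self.charges)[0]
        self.qvals = self.charges[self.charged]

    def energy(self, xyz: np.ndarray) -> float:
        p = self.params
        dz = xyz[self.s2, 2] - xyz[self.s1, 2]
        e = 0.5 * p.k1 * (dz - p.z0) ** 2
        e -= p.field_strength * EV_TO_KCAL_PER_MOL * float(
            np.dot(self.qvals, xyz[self.charged, 2]))
        for sign, s, cg, ce in ((-1.0, self.s1, self.cg1, self.ce1),
                                (1.0, self.s2, self.cg2, self.ce2)):
            v = 2.0 * xyz[s] - xyz[cg] - xyz[ce]
            norm = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
            if norm < 1e-8:
                raise ValueError("degenerate lone-pair surrogate vector")
            e += sign * p.k3 * v[2] / norm
        return float(e)


def sample_ensemble(sequence: str,
                    stage: float,
                    sampler_config: SamplerConfig | None = None,
                    restraint_params: RestraintParams | None = None,
                    seed: int = 0) -> Ensemble:
    """Sample a junction-holding conformational ensemble.

    The chain moves in backbone (phi, psi) space; each state's energy is
    the sum of the three gold restraints (with ``z0`` set to ``stage``)
    and the coarse intramolecular energy.  Frames are retained after
    burn-in at the configured thinning interval.

    Raises RuntimeError if the post-burn-in acceptance rate falls below
    ``sampler_config.min_acceptance`` (move width or restraints are
    misconfigured).
    """
    if stage <= 0:
        raise ValueError("stage (z0) must be positive")
    cfg = sampler_config or SamplerConfig()
    base = restraint_params or RestraintParams()
    params = replace(base, z0=float(stage))

    topology = build_topology(sequence)
    model = _CoarseEnergyModel(topology, cfg)
    builder = ConformationBuilder(topology)
    restraints = _RestraintEnergyOnly(topology, params)
    rng = np.random.default_rng(seed)
    chis0 = rng.uniform(-180.0, 180.0, size=len(builder.chi_labels))
    s0 = _SamplerState(randomize_dihedrals(topology, rng), chis0,
                       _random_rotation(rng))

    def energy_fn(s: _SamplerState) -> float:
        xyz = builder.build(s.dihedrals, s.chis, s.rotation)
        return restraints.energy(xyz) + model.energy(xyz)

    propose = _propose_move(topology, cfg, len(builder.chi_labels))

    # parallel tempering: one replica per ladder rung, cold rung retained
    kTs = [cfg.kT * f for f in cfg.temperature_ladder]
    n_rungs = len(kTs)
    states = [s0]
    for _ in range(1, n_rungs):
        chis = rng.uniform(-180.0, 180.0, size=len(builder.chi_labels))
        states.append(_SamplerState(randomize_dihedrals(topology, rng),
                                    chis, _random_rotation(rng)))
    erg = [energy_fn(s) for s in states]

    frames, energies = [], []
    n_acc = 0
    n_post = 0
    for step in range(cfg.n_steps):
        for k in range(n_rungs):
            cand = propose(states[k], rng)
            e_cand = energy_fn(cand)
            de = e_cand - erg[k]
            if de <= 0.0 or rng.random() < math.exp(-de / kTs[k]):
                states[k], erg[k] = cand, e_cand
                accepted = (k == 0)
            else:
                accepted = False
            if k == 0 and step >= cfg.burn_in:
                n_post += 1
                n_acc += accepted
        if n_rungs > 1 and step % cfg.swap_every == 0:
            j = int(rng.integers(n_rungs - 1))
            delta = (1.0 / kTs[j] - 1.0 / kTs[j + 1]) * (erg[j] - erg[j + 1])
            if delta >= 0.0 or rng.random() < math.exp(delta):
                states[j], states[j + 1] = states[j + 1], states[j]
                erg[j], erg[j + 1] = erg[j + 1], erg[j]
        if step >= cfg.burn_in and (step - cfg.burn_in) % cfg.thin == 0:
            frames.append(builder.build(states[0].dihedrals,
                                        states[0].chis,
                                        states[0].rotation))
            energies.append(erg[0])
    acc_rate = n_acc / max(n_post, 1)
    if acc_rate < cfg.min_acceptance:
        raise RuntimeError(
            f"acceptance rate {acc_rate:.4f} below "
            f"{cfg.min_acceptance} for {sequence} at stage {stage} A: "
            "check move width and restraint parameters")
    return Ensemble(sequence=topology.sequence, stage=float(stage),
                    replicate_seed=int(seed), topology=topology,
                    frames=np.array(frames), energies=np.array(energies),
                    acceptance_rate=acc_rate)


# ---------------------------------------------------------------------------
# Conductance-trace generator

@dataclass
class TraceGenConfig:
    """Break-junction trace generator settings.

    Molecular traces carry, sequentially, a high plateau near ``mu_high``
    and a low plateau near ``mu_low`` (log10 G/G0), then drop to the
    noise floor; the low plateau is longer, as observed for extended
    junction geometries.  Background traces are pure exponential
    tunneling decay.  ``plateau_mode`` = "sequential" emits both plateaus
    per molecular trace (dynamic heterogeneity); "single" emits one
    plateau per trace, split evenly between the two levels (static
    heterogeneity), as a contrast scenario for the classifier.
    """

    n_traces: int = 5000
    molecular_fraction: float = 0.90
    mu_high: float = -2.85
    mu_low: float = -4.2
    high_plateau_len: float = 0.5  # A (mean)
    low_plateau_len: float = 0.8  # A (mean)
    plateau_len_jitter: float = 0.15  # A (sd of plateau lengths)
    plateau_sigma: float = 0.15  # decades
    bg_slope: float = 4.0  # decades/A snap-back tunneling decay
    contact_slope: float = 8.0  # decades/A initial contact rupture decay
    noise_floor: float = -5.5  # decades
    floor_sigma: float = 0.2  # decades
    trace_step: float = 0.01  # A
    trace_length: float = 3.0  # A
    start_logg: float = 0.3
    plateau_mode: str = "sequential"  # or "single"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.molecular_fraction <= 1.0:
            raise ValueError("molecular_fraction must be in [0, 1]")
        if not self.mu_high > self.mu_low > self.noise_floor:
            raise ValueError("need mu_high > mu_low > noise_floor")
        if self.plateau_mode not in ("sequential", "single"):
            raise ValueError("plateau_mode must be 'sequential' or 'single'")


@dataclass
class ConductanceTrace:
    """One conductance-displacement trace: log10(G/G0) on a uniform grid."""

    displacement: np.ndarray  # A, strictly increasing
    logg: np.ndarray
    truth_label: str | None = None  # "molecular" | "background" (generator)

    def __post_init__(self) -> None:
        if len(self.displacement) != len(self.logg):
            raise ValueError("displacement and logg lengths differ")
        if np.any(np.diff(self.displacement) <= 0):
            raise ValueError("displacement must be strictly increasing")


def _molecular_profile(x: np.ndarray, cfg: TraceGenConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Noiseless piecewise profile of a molecular trace."""
    jit = cfg.plateau_len_jitter
    len_h = max(0.1, cfg.high_plateau_len + rng.normal(0.0, jit))
    len_l = max(0.1, cfg.low_plateau_len + rng.normal(0.0, jit))
    if cfg.plateau_mode == "single":
        if rng.random() < 0.5:
            len_l = 0.0
        else:
            len_h = 0.0
    d0 = (cfg.start_logg - cfg.mu_high) / cfg.contact_slope
    d1 = d0 + len_h
    d2 = d1 + (cfg.mu_high - cfg.mu_low) / cfg.contact_slope
    d3 = d2 + len_l
    d4 = d3 + (cfg.mu_low - cfg.noise_floor) / cfg.contact_slope
    y = np.empty_like(x)
    seg0 = x < d0
    y[seg0] = cfg.start_logg - cfg.contact_slope * x[seg0]
    y[(x >= d0) & (x < d1)] = cfg.mu_high
    seg2 = (x >= d1) & (x < d2)
    y[seg2] = cfg.mu_high - cfg.contact_slope * (x[seg2] - d1)
    y[(x >= d2) & (x < d3)] = cfg.mu_low
    seg4 = (x >= d3) & (x < d4)
    y[seg4] = cfg.mu_low - cfg.contact_slope * (x[seg4] - d3)
    y[x >= d4] = cfg.noise_floor
    return y


def generate_traces(config: TraceGenConfig) -> list[ConductanceTrace]:
    """Generate a seeded mixture of molecular and background traces."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_pts = int(round(cfg.trace_length / cfg.trace_step))
    x = np.arange(n_pts) * cfg.trace_step
    is_mol = rng.random(cfg.n_traces) < cfg.molecular_fraction
    traces: list[ConductanceTrace] = []
    for k in range(cfg.n_traces):
        if is_mol[k]:
            y = _molecular_profile(x, cfg, rng)
            above = y > cfg.noise_floor
            noise = np.where(above,
                             rng.normal(0.0, cfg.plateau_sigma, n_pts),
                             rng.normal(0.0, cfg.floor_sigma, n_pts))
            label = "molecular"
        else:
            y = cfg.start_logg - cfg.bg_slope * x
            y = np.maximum(y, cfg.noise_floor)
            above = y > cfg.noise_floor
            noise = np.where(above,
                             rng.normal(0.0, cfg.plateau_sigma, n_pts),
                             rng.normal(0.0, cfg.floor_sigma, n_pts))
            label = "background"
        traces.append(ConductanceTrace(x.copy(), y + noise, label))
    return traces


def traces_to_dataframe(traces: list[ConductanceTrace]):
    """Long-format DataFrame (trace_id, displacement_A, log_g, label)."""
    import pandas as pd

    frames = []
    for i, t in enumerate(traces):
        frames.append(pd.DataFrame({
            "trace_id": i,
            "displacement_A": t.displacement,
            "log_g": t.logg,
            "label": t.truth_label or "",
        }))
    return pd.concat(frames, ignore_index=True)


def traces_from_dataframe(df) -> list[ConductanceTrace]:
    """Inverse of :func:`traces_to_dataframe`."""
    traces = []
    for _, grp in df.groupby("trace_id", sort=True):
        label = None
        if "label" in grp and len(grp["label"]) and str(grp["label"].iloc[0]):
            label = str(grp["label"].iloc[0])
        traces.append(ConductanceTrace(
            grp["displacement_A"].to_numpy(),
            grp["log_g"].to_numpy(), label))
    return traces
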