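"""Backbone H-bond analysis, conformer selection and ensemble diagnostics.

The turn/extended two-state picture of peptide junctions is read off the
backbone i -> i+3 hydrogen bond: the carbonyl O of residue i to the
amide H of residue i+3 (a beta turn; consecutive turns form a 3_10
helix).  This module computes per-frame O...H distance series, selects
representative conformers at the peaks of their distance histograms
(turn conformers from short-stage ensembles, extended conformers from
long-stage ones), and provides ensemble-level diagnostics: Ramachandran
free-energy surfaces, split-half convergence, and the junction
orientation (sulfur-sulfur axis vs pulling axis) distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon

from .peptide_model import Conformation, HBondPair, backbone_hbond_pairs
from .synthetic_data import KB_KCAL, Ensemble

__all__ = [
    "HBondSeries",
    "ConformerSelection",
    "canonical_pair",
    "hbond_distance_series",
    "hbond_fraction",
    "select_conformer",
    "ramachandran_surface",
    "ensemble_convergence",
    "junction_orientation_analysis",
]

logger = logging.getLogger(__name__)

#: Default O...H presence cutoff in A for "H-bond formed".
HBOND_PRESENT_CUTOFF = 2.5


@dataclass
class HBondSeries:
    """Per-frame donor-acceptor O...H distance for one labeled pair."""

    label: str
    distances: np.ndarray  # A, one per frame

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances <= 0):
            raise ValueError("distances must be positive")


@dataclass
class ConformerSelection:
    """A representative frame picked at the mode of a distance histogram."""

    frame_index: int
    stage: float
    distance: float
    mode_center: float
    bin_width: float


def canonical_pair(ensemble_or_topology) -> HBondPair:
    """The canonical i -> i+3 pair: 1->4 for tetrapeptides, 2->5 for
    pentapeptides (and longer)."""
    topo = getattr(ensemble_or_topology, "topology", ensemble_or_topology)
    for p in backbone_hbond_pairs(topo):
        if p.canonical:
            return p
    raise ValueError(f"no canonical H-bond pair in {topo.sequence!r}")


def _resolve_pair(ensemble: Ensemble, pair: HBondPair | str | None) -> HBondPair:
    if pair is None:
        return canonical_pair(ensemble)
    if isinstance(pair, HBondPair):
        return pair
    for p in backbone_hbond_pairs(ensemble.topology):
        if p.label == pair:
            return p
    raise ValueError(
        f"pair {pair!r} not available in {ensemble.sequence!r} "
        "(proline donors carry no amide hydrogen)")


def hbond_distance_series(ensemble: Ensemble,
                          pair: HBondPair | str | None = None) -> HBondSeries:
    """Euclidean carbonyl-O to amide-H distance per frame for one pair
    (default: the canonical pair)."""
    p = _resolve_pair(ensemble, pair)
    d = np.linalg.norm(
        ensemble.frames[:, p.donor_h_id, :] -
        ensemble.frames[:, p.acceptor_o_id, :], axis=1)
    return HBondSeries(p.label, d)


def hbond_fraction(ensemble: Ensemble,
                   pair: HBondPair | str | None = None,
                   cutoff: float = HBOND_PRESENT_CUTOFF) -> float:
    """Fraction of frames with the pair's O...H distance below cutoff."""
    return float(np.mean(hbond_distance_series(ensemble, pair).distances
                         < cutoff))


def select_conformer(ensemble: Ensemble, series: HBondSeries,
                     bin_width: float = 0.1) -> ConformerSelection:
    """Pick the frame at the peak of the H-bond distance histogram.

    The mode bin is the histogram argmax (ties broken toward smaller
    distance, favoring the structured state); the returned frame is the
    one whose distance lies nearest the mode-bin center, ties broken by
    lowest frame index.
    """
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    d = series.distances
    if len(d) != ensemble.n_frames:
        raise ValueError("series length does not match ensemble")
    nbins = max(1, int(np.ceil(d.max() / bin_width)))
    edges = np.arange(nbins + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    mode_bin = int(np.argmax(counts))  # argmax takes the first (smallest) tie
    center = (mode_bin + 0.5) * bin_width
    frame = int(np.argmin(np.abs(d - center)))  # first index on ties
    return ConformerSelection(frame_index=frame, stage=ensemble.stage,
                              distance=float(d[frame]), mode_center=center,
                              bin_width=bin_width)


def ramachandran_surface(ensemble: Ensemble, residue_index: int,
                         grid_deg: float = 10.0,
                         temperature_K: float = 300.0):
    """Free-energy surface F(phi, psi) = -kT ln p for one non-terminal
    residue, minimum shifted to zero; empty bins are +inf.

    Returns (phi_edges, psi_edges, F) with F shaped (nphi, npsi).
    """
    topo = ensemble.topology
    if residue_index <= 1 or residue_index >= topo.n_residues:
        raise ValueError("Ramachandran surfaces are defined for "
                         "non-terminal residues only")
    quad_phi = topo.dihedral_defs[(residue_index, "phi")]
    quad_psi = topo.dihedral_defs[(residue_index, "psi")]
    from .peptide_model import dihedral_angle
    phis = np.array([dihedral_angle(*(f[list(quad_phi)]))
                     for f in ensemble.frames])
    psis = np.array([dihedral_angle(*(f[list(quad_psi)]))
                     for f in ensemble.frames])
    nbins = int(round(360.0 / grid_deg))
    edges = np.linspace(-180.0, 180.0, nbins + 1)
    counts, xe, ye = np.histogram2d(phis, psis, bins=[edges, edges])
    kT = KB_KCAL * temperature_K
    with np.errstate(divide="ignore"):
        f = -kT * np.log(counts / counts.sum())
    f -= f.min()
    return xe, ye, f


def ensemble_convergence(ensemble: Ensemble,
                         pair: HBondPair | str | None = None,
                         bin_width: float = 0.25,
                         min_frames: int = 100) -> float:
    """Split-half convergence score: Jensen-Shannon divergence (natural
    log; range [0, ln 2]) between the canonical H-bond distance
    histograms of the first and second halves of the chain.  Near-zero
    scores indicate a stationary, well-mixed ensemble."""
    if ensemble.n_frames < min_frames:
        raise ValueError(
            f"need at least {min_frames} frames, have {ensemble.n_frames}")
    d = hbond_distance_series(ensemble, pair).distances
    half = len(d) // 2
    a, b = d[:half], d[half:]
    hi = max(d.max(), bin_width)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    # scipy returns the JS distance = sqrt(divergence)
    return float(jensenshannon(pa, pb) ** 2)


def write_free_energy_tsv(path, x_edges: np.ndarray, y_edges: np.ndarray,
                          f: np.ndarray) -> None:
    """Write a free-energy grid as TSV with bin-center header row and
    column; empty bins appear as 'inf'."""
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    with open(path, "w") as fh:
        fh.write("phi\\psi\t" + "\t".join(f"{v:g}" for v in yc) + "\n")
        for i, x in enumerate(xc):
            row = "\t".join(f"{v:.6g}" for v in f[i])
            fh.write(f"{x:g}\t{row}\n")


def junction_orientation_analysis(ensemble: Ensemble,
                                  theta_c_deg: float = 30.0,
                                  bin_deg: float = 5.0,
                                  temperature_K: float = 300.0) -> dict:
    """Angle between the sulfur-sulfur axis and the pulling (z) axis.

    theta is axis-agnostic (folded into [0, 90] degrees).  Frames with
    theta < theta_c are classified "orthogonal" junction conformations
    (anchor axis aligned with pulling direction), the rest
    "nonorthogonal".  Also returns a 1D free-energy profile over theta.
    """
    s1, s2 = ensemble.topology.sulfur_ids()
    v = ensemble.frames[:, s2, :] - ensemble.frames[:, s1, :]
    norm = np.linalg.norm(v, axis=1)
    cos = np.abs(v[:, 2]) / norm
    theta = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    edges = np.arange(0.0, 90.0 + bin_deg, bin_deg)
    counts, _ = np.histogram(theta, bins=edges)
    kT = KB_KCAL * temperature_K
    with np.errstate(divide="ignore"):
        f = -kT * np.log(counts / counts.sum())
    f -= f.min()
    frac = float(np.mean(theta < theta_c_deg))
    return {
        "theta_deg": theta,
        "orthogonal_fraction": frac,
        "theta_c_deg": theta_c_deg,
        "profile_edges_deg": edges,
        "free_energy_kcal": f,
    }
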