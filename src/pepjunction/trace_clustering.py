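"""Unsupervised analysis of break-junction conductance traces.

Mirrors the standard single-molecule data-analysis stack: pooled 1D and
aligned 2D conductance histograms, Lorentzian peak fitting for the most
probable conductance of the high and low states, silhouette-scored
selection of the cluster count, Gaussian-mixture clustering of per-trace
histogram features, and classification of the origin of bimodal
conductance (dynamic vs static heterogeneity — whether the two
conductance states appear sequentially within single traces or
segregate into distinct trace subpopulations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .synthetic_data import ConductanceTrace

__all__ = [
    "TraceFeatures",
    "ClusterResult",
    "PeakFit",
    "trace_features",
    "histogram_1d",
    "histogram_2d",
    "fit_lorentzian_peaks",
    "silhouette_select_k",
    "gmm_cluster",
    "detect_plateaus",
    "molecular_cluster_id",
    "heterogeneity_classification",
]

#: Default log10(G/G0) histogram range and bin width.
LOGG_RANGE = (-6.5, 0.5)
LOGG_BIN = 0.1

#: Plateau detection defaults: a run of >= MIN_RUN consecutive points
#: within +/- WINDOW decades of a peak level.
PLATEAU_WINDOW = 0.3
PLATEAU_MIN_RUN = 10


def _default_edges() -> np.ndarray:
    lo, hi = LOGG_RANGE
    n = int(round((hi - lo) / LOGG_BIN))
    return lo + LOGG_BIN * np.arange(n + 1)


@dataclass
class TraceFeatures:
    """Per-trace normalized logG histograms on fixed bins."""

    X: np.ndarray  # (n_traces, n_bins); rows sum to 1 (0 if empty)
    edges: np.ndarray
    empty: np.ndarray  # bool flags for traces with no in-range points

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class PeakFit:
    """Sum-of-Lorentzians fit to a pooled conductance histogram."""

    centers: np.ndarray  # log10 G/G0, sorted descending
    widths: np.ndarray  # half-width gamma per peak
    amplitudes: np.ndarray
    residual: float
    converged: bool


@dataclass
class ClusterResult:
    """GMM clustering of trace features."""

    k: int
    assignments: np.ndarray
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    seed: int
    silhouette_by_k: dict = field(default_factory=dict)
    molecular_cluster: int | None = None

    @property
    def cluster_shares(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k) / \
            len(self.assignments)


def trace_features(traces: list[ConductanceTrace],
                   edges: np.ndarray | None = None) -> TraceFeatures:
    """Featurize traces as normalized logG histograms on fixed bins."""
    edges = _default_edges() if edges is None else np.asarray(edges)
    X = np.zeros((len(traces), len(edges) - 1))
    empty = np.zeros(len(traces), dtype=bool)
    for i, t in enumerate(traces):
        counts, _ = np.histogram(t.logg, bins=edges)
        tot = counts.sum()
        if tot == 0:
            empty[i] = True
        else:
            X[i] = counts / tot
    return TraceFeatures(X, edges, empty)


def histogram_1d(traces: list[ConductanceTrace],
                 edges: np.ndarray | None = None):
    """Pooled logG histogram over all trace points.

    Returns (counts, edges, overflow) where overflow counts the points
    outside the histogram range; counts.sum() + overflow equals the
    total number of trace points.
    """
    if not traces:
        raise ValueError("no traces")
    edges = _default_edges() if edges is None else np.asarray(edges)
    allg = np.concatenate([t.logg for t in traces])
    counts, _ = np.histogram(allg, bins=edges)
    overflow = int(len(allg) - counts.sum())
    return counts, edges, overflow


def histogram_2d(traces: list[ConductanceTrace],
                 align_threshold: float = -0.3,
                 disp_edges: np.ndarray | None = None,
                 logg_edges: np.ndarray | None = None):
    """Aligned 2D (displacement, logG) histogram.

    Each trace is re-origined at its first crossing below
    ``align_threshold``; traces that never cross are excluded and
    tallied.  Returns (counts, disp_edges, logg_edges, n_excluded).
    """
    logg_edges = _default_edges() if logg_edges is None \
        else np.asarray(logg_edges)
    if disp_edges is None:
        disp_edges = np.arange(-0.2, 2.5 + 0.01, 0.01)
    counts = np.zeros((len(disp_edges) - 1, len(logg_edges) - 1))
    n_excluded = 0
    for t in traces:
        below = np.nonzero(t.logg < align_threshold)[0]
        if len(below) == 0:
            n_excluded += 1
            continue
        origin = t.displacement[below[0]]
        h, _, _ = np.histogram2d(t.displacement - origin, t.logg,
                                 bins=[disp_edges, logg_edges])
        counts += h
    return counts, disp_edges, logg_edges, n_excluded


def _lorentzian_sum(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for k in range(0, len(params), 3):
        a, x0, g = params[k:k + 3]
        y = y + a * g * g / ((x - x0) ** 2 + g * g)
    return y


def fit_lorentzian_peaks(counts: np.ndarray, edges: np.ndarray,
                         n_peaks: int = 2) -> PeakFit:
    """Least-squares fit of a sum of Lorentzians to a pooled histogram.

    Initial centers are the ``n_peaks`` highest-prominence local maxima
    of the histogram.  Peak centers are returned sorted descending in
    logG (high-conductance state first).  Non-convergence is reported,
    not silently replaced.
    """
    counts = np.asarray(counts, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if np.count_nonzero(counts) < 5 * n_peaks:
        raise ValueError(
            f"histogram has fewer than {5 * n_peaks} nonzero bins")
    idx, props = find_peaks(counts, prominence=0.0)
    if len(idx) == 0:
        return PeakFit(np.array([]), np.array([]), np.array([]),
                       float(np.sum(counts ** 2)), False)
    order = np.argsort(props["prominences"])[::-1][:n_peaks]
    init_centers = centers[idx[order]]
    init_amps = counts[idx[order]]
    p0 = []
    for a, c in zip(init_amps, init_centers):
        p0 += [max(a, 1.0), c, 0.15]
    bin_w = edges[1] - edges[0]
    lo, hi = edges[0], edges[-1]
    bounds_lo = [0.0, lo, bin_w / 4] * len(init_centers)
    bounds_hi = [np.inf, hi, hi - lo] * len(init_centers)
    try:
        popt, _ = curve_fit(_lorentzian_sum, centers, counts, p0=p0,
                            bounds=(bounds_lo, bounds_hi), maxfev=20000)
        converged = True
    except RuntimeError:
        popt = np.array(p0)
        converged = False
    amps = popt[0::3]
    cent = popt[1::3]
    wid = popt[2::3]
    resid = float(np.sum((_lorentzian_sum(centers, *popt) - counts) ** 2))
    order = np.argsort(cent)[::-1]
    return PeakFit(cent[order], wid[order], amps[order], resid, converged)


def _fit_gmm(X: np.ndarray, k: int, seed: int,
             reg_covar: float = 1e-6) -> GaussianMixture:
    try:
        gmm = GaussianMixture(n_components=k, covariance_type="full",
                              reg_covar=reg_covar, n_init=5,
                              random_state=seed)
        gmm.fit(X)
        return gmm
    except ValueError:
        # singular covariance despite regularization: retry once, stiffer
        gmm = GaussianMixture(n_components=k, covariance_type="full",
                              reg_covar=reg_covar * 10, n_init=5,
                              random_state=seed)
        gmm.fit(X)
        return gmm


def silhouette_select_k(features: TraceFeatures,
                        k_range: range = range(2, 7),
                        seed: int = 0):
    """Choose the cluster count by mean silhouette over GMM assignments.

    For each candidate k a seeded GMM is fitted and the mean silhouette
    coefficient (Euclidean) of its assignments computed; k with empty
    clusters scores -1.  Ties break toward smaller k.

    Returns (chosen_k, {k: score}).
    """
    X = features.X
    if len(X) < 10:
        raise ValueError("need at least 10 traces")
    scores: dict[int, float] = {}
    for k in k_range:
        gmm = _fit_gmm(X, k, seed)
        labels = gmm.predict(X)
        if len(np.unique(labels)) < k:
            scores[k] = -1.0
            continue
        scores[k] = float(silhouette_score(X, labels, metric="euclidean"))
    chosen = min(scores, key=lambda k: (-scores[k], k))
    return chosen, scores


def gmm_cluster(features: TraceFeatures, k: int, seed: int = 0,
                traces: list[ConductanceTrace] | None = None,
                peak_levels: np.ndarray | None = None) -> ClusterResult:
    """Full-covariance GMM clustering of trace features.

    If ``traces`` and ``peak_levels`` are given, the cluster containing
    the majority of plateau-bearing traces is labeled molecular
    (``result.molecular_cluster``).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    gmm = _fit_gmm(features.X, k, seed)
    labels = gmm.predict(features.X)
    result = ClusterResult(k=k, assignments=labels, weights=gmm.weights_,
                           means=gmm.means_, covariances=gmm.covariances_,
                           seed=seed)
    if traces is not None and peak_levels is not None and k > 1:
        result.molecular_cluster = molecular_cluster_id(
            traces, labels, peak_levels)
    return result


def detect_plateaus(trace: ConductanceTrace, levels: np.ndarray,
                    window: float = PLATEAU_WINDOW,
                    min_run: int = PLATEAU_MIN_RUN) -> list[dict]:
    """Detect conductance plateaus near given levels.

    A plateau at a level is the maximal run of >= ``min_run`` consecutive
    points within +/- ``window`` decades of it.  Returns one dict per
    level: {"level", "found", "run_length", "start_index"}.
    """
    out = []
    for lv in np.asarray(levels, dtype=float):
        inside = np.abs(trace.logg - lv) < window
        best_len, best_start = 0, -1
        run, start = 0, 0
        for i, flag in enumerate(inside):
            if flag:
                if run == 0:
                    start = i
                run += 1
                if run > best_len:
                    best_len, best_start = run, start
            else:
                run = 0
        out.append({"level": float(lv), "found": best_len >= min_run,
                    "run_length": best_len, "start_index": best_start})
    return out


def molecular_cluster_id(traces: list[ConductanceTrace],
                         assignments: np.ndarray,
                         peak_levels: np.ndarray,
                         window: float = PLATEAU_WINDOW,
                         min_run: int = PLATEAU_MIN_RUN) -> int:
    """The cluster whose members most frequently contain detected
    plateaus at either peak level."""
    has_plateau = np.array([
        any(p["found"] for p in detect_plateaus(t, peak_levels, window,
                                                min_run))
        for t in traces])
    ks = np.unique(assignments)
    rates = {int(k): float(has_plateau[assignments == k].mean())
             for k in ks}
    return max(rates, key=lambda k: rates[k])


def heterogeneity_classification(traces: list[ConductanceTrace],
                                 assignments: np.ndarray,
                                 peak_levels: np.ndarray,
                                 window: float = PLATEAU_WINDOW,
                                 min_run: int = PLATEAU_MIN_RUN,
                                 majority: float = 0.6) -> dict:
    """Classify the origin of the bimodal conductance distribution.

    dynamic — the two conductance states appear sequentially (high before
    low) within individual traces; static — traces carry exactly one
    state each and the states segregate into different clusters;
    inconclusive otherwise.  Only plateau-bearing traces participate.

    Returns {"verdict", "both_levels_ordered_fraction",
    "single_level_fraction", "per_trace_flags"}.
    """
    if len(peak_levels) < 2:
        raise ValueError("need two peak levels")
    hi, lo = sorted(np.asarray(peak_levels, dtype=float))[::-1][:2]
    flags = []
    for t in traces:
        det = detect_plateaus(t, np.array([hi, lo]), window, min_run)
        flags.append((det[0], det[1]))
    n_plateau = 0
    n_both_ordered = 0
    n_single = 0
    single_level = []  # (cluster, level) for single-level traces
    for (fhi, flo), a in zip(flags, assignments):
        if not (fhi["found"] or flo["found"]):
            continue
        n_plateau += 1
        if fhi["found"] and flo["found"]:
            if fhi["start_index"] < flo["start_index"]:
                n_both_ordered += 1
        else:
            n_single += 1
            single_level.append((int(a), hi if fhi["found"] else lo))
    result = {
        "verdict": "inconclusive",
        "both_levels_ordered_fraction": 0.0,
        "single_level_fraction": 0.0,
        "n_plateau_traces": n_plateau,
        "per_trace_flags": flags,
    }
    if n_plateau == 0:
        return result
    f_both = n_both_ordered / n_plateau
    f_single = n_single / n_plateau
    result["both_levels_ordered_fraction"] = f_both
    result["single_level_fraction"] = f_single
    if f_both >= majority:
        result["verdict"] = "dynamic"
    elif f_single >= majority and _levels_segregate(single_level):
        result["verdict"] = "static"
    return result


def _levels_segregate(single_level: list[tuple[int, float]]) -> bool:
    """True if at least two clusters have differing majority levels among
    their single-level traces."""
    by_cluster: dict[int, list[float]] = {}
    for c, lv in single_level:
        by_cluster.setdefault(c, []).append(lv)
    majorities = set()
    for c, lvs in by_cluster.items():
        vals, cnts = np.unique(lvs, return_counts=True)
        majorities.add(float(vals[np.argmax(cnts)]))
    return len(majorities) >= 2
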