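"""Conductance histograms, Lorentzian fits, GMM clustering, and
heterogeneity classification."""

import numpy as np
import pytest

from pepjunction import trace_clustering as tc
from pepjunction.synthetic_data import (
    ConductanceTrace,
    TraceGenConfig,
    generate_traces,
)


def _flat_trace(level, n=300, step=0.01):
    x = np.arange(n) * step
    return ConductanceTrace(x, np.full(n, float(level)))


def test_histogram_conservation():
    """Counts + overflow equals total points, including out-of-range."""
    traces = [_flat_trace(-2.85), _flat_trace(-4.2), _flat_trace(2.0)]
    counts, edges, overflow = tc.histogram_1d(traces)
    assert counts.sum() + overflow == sum(len(t.logg) for t in traces)
    assert overflow == 300  # the +2.0 trace lies outside [-6.5, 0.5]
    centers = 0.5 * (edges[:-1] + edges[1:])
    assert counts[np.argmin(np.abs(centers + 2.85))] == 300


def test_histogram_bimodal():
    traces = [_flat_trace(-2.85)] * 3 + [_flat_trace(-4.2)] * 2
    counts, edges, _ = tc.histogram_1d(traces)
    nz = np.nonzero(counts)[0]
    assert len(nz) == 2


def test_trace_features_normalized(default_traces):
    feats = tc.trace_features(default_traces)
    sums = feats.X.sum(axis=1)
    assert np.allclose(sums[~feats.empty], 1.0)


class TestLorentzian:
    def _hist_from_lorentzian(self, centers_g):
        edges = np.arange(-6.5, 0.5001, 0.1)
        x = 0.5 * (edges[:-1] + edges[1:])
        y = np.zeros_like(x)
        for c, g, a in centers_g:
            y += a * g * g / ((x - c) ** 2 + g * g)
        return y, edges

    def test_single_peak_recovery(self):
        y, edges = self._hist_from_lorentzian([(-2.85, 0.15, 1000.0)])
        fit = tc.fit_lorentzian_peaks(y, edges, n_peaks=1)
        assert fit.converged
        assert abs(fit.centers[0] - (-2.85)) < 0.02

    def test_two_peak_recovery(self):
        y, edges = self._hist_from_lorentzian(
            [(-2.85, 0.15, 1000.0), (-4.2, 0.2, 600.0)])
        fit = tc.fit_lorentzian_peaks(y, edges, n_peaks=2)
        assert fit.converged
        assert abs(fit.centers[0] - (-2.85)) < 0.05
        assert abs(fit.centers[1] - (-4.2)) < 0.05
        assert fit.centers[0] > fit.centers[1]  # sorted descending

    def test_sparse_histogram_rejected(self):
        edges = np.arange(-6.5, 0.5001, 0.1)
        y = np.zeros(len(edges) - 1)
        y[3] = 5.0
        with pytest.raises(ValueError):
            tc.fit_lorentzian_peaks(y, edges, n_peaks=1)

    def test_generator_histogram_center_bias(self, default_traces):
        """Centers recovered from generator traces are within 0.02
        decades of the generating plateau levels."""
        counts, edges, _ = tc.histogram_1d(default_traces)
        # fit above the noise floor to isolate the molecular peaks
        keep = 0.5 * (edges[:-1] + edges[1:]) > -5.0
        lo = np.nonzero(keep)[0][0]
        fit = tc.fit_lorentzian_peaks(counts[keep], edges[lo:], n_peaks=2)
        assert fit.converged
        assert abs(fit.centers[0] - (-2.85)) < 0.02
        assert abs(fit.centers[1] - (-4.2)) < 0.02


class TestHistogram2D:
    def test_two_ridges(self):
        cfg = TraceGenConfig(n_traces=200, molecular_fraction=1.0,
                             plateau_sigma=0.0, floor_sigma=0.0,
                             plateau_len_jitter=0.0, seed=1)
        traces = generate_traces(cfg)
        counts, de, le, nex = tc.histogram_2d(traces)
        assert nex == 0
        gcent = 0.5 * (le[:-1] + le[1:])
        hi_bin = np.argmin(np.abs(gcent - cfg.mu_high))
        lo_bin = np.argmin(np.abs(gcent - cfg.mu_low))
        dcent = 0.5 * (de[:-1] + de[1:])
        hi_mass = counts[:, hi_bin]
        lo_mass = counts[:, lo_bin]
        assert hi_mass.sum() > 0 and lo_mass.sum() > 0
        # the low ridge extends to larger displacement than the high one
        mean_d_hi = np.average(dcent, weights=hi_mass)
        mean_d_lo = np.average(dcent, weights=lo_mass)
        assert mean_d_lo > mean_d_hi

    def test_never_crossing_excluded(self):
        t = _flat_trace(0.2)  # never crosses -0.3
        counts, _, _, nex = tc.histogram_2d([t])
        assert nex == 1
        assert counts.sum() == 0

    def test_empty_input(self):
        counts, _, _, nex = tc.histogram_2d([])
        assert counts.sum() == 0 and nex == 0


def _blob_features(n_blobs, n_per=60, dim=12, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_blobs):
        center = np.zeros(dim)
        center[b] = 1.0
        rows.append(center + rng.normal(0, 0.02, size=(n_per, dim)))
    X = np.abs(np.vstack(rows))
    X = X / X.sum(axis=1, keepdims=True)
    edges = np.linspace(-6.5, 0.5, dim + 1)
    return tc.TraceFeatures(X, edges, np.zeros(len(X), dtype=bool))


@pytest.mark.parametrize("n_blobs", [2, 3])
def test_silhouette_blob_recovery(n_blobs):
    feats = _blob_features(n_blobs)
    k, scores = tc.silhouette_select_k(feats, range(2, 7), seed=0)
    assert k == n_blobs
    assert scores[n_blobs] == max(scores.values())


def test_silhouette_needs_traces():
    with pytest.raises(ValueError):
        tc.silhouette_select_k(_blob_features(2, n_per=3), range(2, 4), 0)


def test_silhouette_k2_on_generator(default_traces):
    """The generator's molecular/background mixture clusters into two."""
    feats = tc.trace_features(default_traces)
    k, scores = tc.silhouette_select_k(feats, range(2, 7), seed=0)
    assert k == 2


def test_silhouette_stability_across_seeds(default_traces):
    """Chosen k is stable in >= 4/5 seeds."""
    feats = tc.trace_features(default_traces)
    ks = [tc.silhouette_select_k(feats, range(2, 5), seed=s)[0]
          for s in range(5)]
    assert sum(k == 2 for k in ks) >= 4


class TestGMM:
    def test_k1_trivial(self, default_traces):
        feats = tc.trace_features(default_traces[:100])
        res = tc.gmm_cluster(feats, k=1, seed=0)
        assert np.all(res.assignments == 0)
        assert res.weights == pytest.approx([1.0])

    def test_weights_normalized_and_deterministic(self, default_traces):
        feats = tc.trace_features(default_traces[:500])
        a = tc.gmm_cluster(feats, 2, seed=3)
        b = tc.gmm_cluster(feats, 2, seed=3)
        assert abs(a.weights.sum() - 1.0) < 1e-9
        assert np.array_equal(a.assignments, b.assignments)

    def test_symmetric_share_recovery(self):
        """A 50/50 molecular/background mixture is recovered to 3%."""
        cfg = TraceGenConfig(n_traces=2000, molecular_fraction=0.5,
                             seed=11)
        traces = generate_traces(cfg)
        feats = tc.trace_features(traces)
        res = tc.gmm_cluster(feats, 2, seed=0, traces=traces,
                             peak_levels=np.array([-2.85, -4.2]))
        share = np.mean(res.assignments == res.molecular_cluster)
        assert abs(share - 0.5) < 0.03

    def test_cluster_recovers_truth_labels(self, default_traces):
        feats = tc.trace_features(default_traces)
        res = tc.gmm_cluster(feats, 2, seed=0, traces=default_traces,
                             peak_levels=np.array([-2.85, -4.2]))
        truth = np.array([t.truth_label == "molecular"
                          for t in default_traces])
        pred = res.assignments == res.molecular_cluster
        agreement = np.mean(pred == truth)
        assert agreement > 0.95


class TestPlateauDetection:
    def test_flat_trace(self):
        t = _flat_trace(-2.85, n=50)
        det = tc.detect_plateaus(t, np.array([-2.85, -4.2]))
        assert det[0]["found"] and not det[1]["found"]
        assert det[0]["run_length"] == 50

    def test_short_run_not_found(self):
        x = np.arange(30) * 0.01
        y = np.full(30, -6.0)
        y[5:12] = -2.85  # only 7 points
        det = tc.detect_plateaus(ConductanceTrace(x, y),
                                 np.array([-2.85]))
        assert not det[0]["found"]


class TestHeterogeneity:
    def test_dynamic_on_sequential_generator(self, default_traces):
        feats = tc.trace_features(default_traces)
        res = tc.gmm_cluster(feats, 2, seed=0, traces=default_traces,
                             peak_levels=np.array([-2.85, -4.2]))
        het = tc.heterogeneity_classification(
            default_traces, res.assignments, np.array([-2.85, -4.2]))
        assert het["verdict"] == "dynamic"

    def test_static_on_single_plateau_generator(self):
        cfg = TraceGenConfig(n_traces=600, molecular_fraction=0.9,
                             plateau_mode="single", seed=21)
        traces = generate_traces(cfg)
        feats = tc.trace_features(traces)
        res = tc.gmm_cluster(feats, 2, seed=0, traces=traces,
                             peak_levels=np.array([-2.85, -4.2]))
        het = tc.heterogeneity_classification(
            traces, res.assignments, np.array([-2.85, -4.2]))
        assert het["verdict"] == "static"

    def test_inconclusive_on_background(self):
        cfg = TraceGenConfig(n_traces=300, molecular_fraction=0.0, seed=5)
        traces = generate_traces(cfg)
        het = tc.heterogeneity_classification(
            traces, np.zeros(300, dtype=int), np.array([-2.85, -4.2]))
        assert het["verdict"] == "inconclusive"
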