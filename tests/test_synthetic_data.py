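"""Monte Carlo sampler calibration and conductance-trace generator."""

import numpy as np
import pytest
from scipy import stats

from pepjunction import peptide_model as pm
from pepjunction import synthetic_data as sd


def test_coarse_energy_closed_forms():
    """Steric term vanishes at contact, H-bond well is -eps at d_opt."""
    cfg = sd.SamplerConfig()
    topo = pm.build_topology("MAAM")
    # extended chain: no clashes, H-bond far open
    ext = pm.build_conformation(topo, pm.DihedralSet(
        np.full(4, 180.0), np.full(4, 180.0), np.full(4, 180.0)))
    assert sd.coarse_energy(ext, cfg) == pytest.approx(0.0, abs=1e-4)

    # place the canonical O...H pair exactly at d_opt: well bottom
    pair = pm.backbone_hbond_pairs(topo)[0]
    coords = ext.coords.copy()
    coords[pair.donor_h_id] = coords[pair.acceptor_o_id] + \
        [0.0, 0.0, cfg.hbond_d_opt]
    e = sd.coarse_energy(pm.Conformation(topo, coords), cfg)
    assert e == pytest.approx(-cfg.hbond_epsilon, abs=1e-6)

    # two heavy atoms at exactly r_min: boundary, zero steric energy
    model = sd._CoarseEnergyModel(topo, cfg)
    i, j = model.pairs_i[0], model.pairs_j[0]
    coords = ext.coords.copy()
    direction = coords[j] - coords[i]
    coords[j] = coords[i] + direction / np.linalg.norm(direction) * \
        model.rmin[0]
    # isolate the (i, j) contribution
    d = np.linalg.norm(coords[model.pairs_i] - coords[model.pairs_j],
                       axis=1)
    overlap = np.clip(model.rmin - d, 0.0, None)
    assert overlap[0] == pytest.approx(0.0, abs=1e-12)


def test_sampler_seed_determinism():
    cfg = sd.SamplerConfig(n_steps=600, burn_in=200, thin=5)
    a = sd.sample_ensemble("MAAM", 6.0, cfg, seed=11)
    b = sd.sample_ensemble("MAAM", 6.0, cfg, seed=11)
    assert np.array_equal(a.frames, b.frames)
    assert np.array_equal(a.energies, b.energies)
    c = sd.sample_ensemble("MAAM", 6.0, cfg, seed=12)
    assert not np.array_equal(a.frames, c.frames)


def test_sampler_rejects_bad_stage():
    with pytest.raises(ValueError):
        sd.sample_ensemble("MAAM", -1.0)


def test_flat_energy_phi_marginal_uniform():
    """With restraints and coarse energy off, the sampled phi marginal is
    uniform (detailed-balance sanity; KS test on 10,000 thinned draws —
    thinning removes the chain's autocorrelation, which the iid KS test
    does not tolerate)."""
    topo = pm.build_topology("MAAM")
    cfg = sd.SamplerConfig(n_steps=250000, burn_in=0, thin=1)
    propose = sd._propose_move(topo, cfg, n_chis=0,
                               uniform_fraction=1.0,
                               rotation_fraction=0.0)
    rng = np.random.default_rng(5)
    s0 = sd._SamplerState(pm.randomize_dihedrals(topo, rng),
                          np.empty(0), np.eye(3))
    phis = []
    for step, (state, _e, _acc) in enumerate(sd.metropolis_chain(
            s0, lambda s: 0.0, propose, 250000, cfg.kT, rng)):
        if step % 25 == 0:
            phis.append(state.dihedrals.phi[1])
    u = (np.asarray(phis) + 180.0) / 360.0
    assert len(u) == 10000
    assert stats.kstest(u, "uniform").pvalue > 0.01


def test_boltzmann_variance_1dof():
    """Metropolis on U = k/2 (z - z0)^2 reproduces var = kT/k within 10%."""
    kT = sd.KB_KCAL * 300.0
    k1 = 1.0

    def energy(z):
        return 0.5 * k1 * (z - 6.0) ** 2

    def propose(z, rng):
        return z + rng.normal(0.0, 0.6)

    rng = np.random.default_rng(2)
    zs = [z for z, _e, _a in
          sd.metropolis_chain(6.0, energy, propose, 50000, kT, rng)]
    var = np.var(zs[5000:])
    assert var == pytest.approx(kT / k1, rel=0.10)


def test_stage_displacement_centered(stage_ensembles):
    """Retained frames center near z0 (within 1.5 A) at every stage."""
    for (seq, stage), ens in stage_ensembles.items():
        s1, s2 = ens.topology.sulfur_ids()
        dz = ens.frames[:, s2, 2] - ens.frames[:, s1, 2]
        assert abs(dz.mean() - stage) < 1.5, (seq, stage, dz.mean())


def test_stage12_mean_displacement_window(stage_ensembles):
    """Under k1 = 1 and kT ~ 0.6 the stage-12 mean lies in [10.5, 13.5]."""
    for seq in ("MAAM", "MGGGM"):
        ens = stage_ensembles[(seq, 12.0)]
        s1, s2 = ens.topology.sulfur_ids()
        dz = ens.frames[:, s2, 2] - ens.frames[:, s1, 2]
        assert 10.5 <= dz.mean() <= 13.5


def test_hbond_depopulation_with_stage(stage_ensembles):
    """Turn H-bonds are frequent at 6 A, monotonically rarer at 9 and
    essentially abolished at 12 A."""
    from pepjunction.hbond_conformers import hbond_fraction
    for seq in ("MAAM", "MGGGM"):
        fracs = [hbond_fraction(stage_ensembles[(seq, s)])
                 for s in (6.0, 9.0, 12.0)]
        assert fracs[0] >= fracs[1] >= fracs[2], (seq, fracs)
        assert fracs[0] - fracs[2] >= 0.2, (seq, fracs)
        assert fracs[2] <= 0.05, (seq, fracs)


def test_acceptance_rate_reported(stage_ensembles):
    for ens in stage_ensembles.values():
        assert 0.01 < ens.acceptance_rate < 1.0


# ---------------------------------------------------------------------------
# Trace generator

def test_trace_label_fraction():
    """Empirical molecular fraction within 2% of configured at n=5000."""
    cfg = sd.TraceGenConfig(n_traces=5000, molecular_fraction=0.9, seed=3)
    traces = sd.generate_traces(cfg)
    frac = np.mean([t.truth_label == "molecular" for t in traces])
    assert abs(frac - 0.9) < 0.02


def test_trace_determinism():
    a = sd.generate_traces(sd.TraceGenConfig(n_traces=50, seed=9))
    b = sd.generate_traces(sd.TraceGenConfig(n_traces=50, seed=9))
    for ta, tb in zip(a, b):
        assert np.array_equal(ta.logg, tb.logg)


def test_noiseless_two_plateau_limit():
    """sigma = 0: molecular traces hold exactly mu_H then exactly mu_L."""
    cfg = sd.TraceGenConfig(n_traces=20, molecular_fraction=1.0,
                            plateau_sigma=0.0, floor_sigma=0.0,
                            plateau_len_jitter=0.0, seed=4)
    for t in sd.generate_traces(cfg):
        assert np.any(t.logg == cfg.mu_high)
        assert np.any(t.logg == cfg.mu_low)
        i_hi = np.nonzero(t.logg == cfg.mu_high)[0]
        i_lo = np.nonzero(t.logg == cfg.mu_low)[0]
        assert i_hi.max() < i_lo.min()  # high plateau precedes low
        # plateaus are contiguous runs
        assert np.all(np.diff(i_hi) == 1)


def test_background_only_no_plateaus():
    """molecular_fraction = 0: no level is held for more than 0.2 A
    above the noise floor."""
    cfg = sd.TraceGenConfig(n_traces=100, molecular_fraction=0.0, seed=5)
    max_run_pts = int(0.2 / cfg.trace_step)
    for t in sd.generate_traces(cfg):
        assert t.truth_label == "background"
        above = t.logg > cfg.noise_floor + 3 * cfg.floor_sigma
        y = t.logg[above]
        # sliding window: range within any 20-pt window must exceed the
        # plateau criterion band (a true plateau would stay within it)
        for s in range(0, max(0, len(y) - max_run_pts)):
            w = y[s:s + max_run_pts]
            assert w.max() - w.min() > 0.2


def test_pooled_histogram_modes():
    """The pooled logG histogram recovers both plateau levels."""
    cfg = sd.TraceGenConfig(n_traces=5000, seed=6)
    traces = sd.generate_traces(cfg)
    allg = np.concatenate([t.logg for t in traces])
    edges = np.arange(-6.5, 0.5001, 0.1)
    counts, _ = np.histogram(allg, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    from scipy.signal import find_peaks
    idx, props = find_peaks(counts, prominence=0.0)
    top = idx[np.argsort(props["prominences"])[::-1]]
    # restrict to peaks above the noise floor
    top = [i for i in top if centers[i] > cfg.noise_floor + 0.5][:2]
    found = sorted(centers[i] for i in top)
    assert abs(found[0] - cfg.mu_low) <= 0.1
    assert abs(found[1] - cfg.mu_high) <= 0.1


def test_single_plateau_mode():
    cfg = sd.TraceGenConfig(n_traces=200, molecular_fraction=1.0,
                            plateau_mode="single", seed=7)
    n_hi = n_lo = 0
    for t in sd.generate_traces(cfg):
        near_hi = np.mean(np.abs(t.logg - cfg.mu_high) < 0.3)
        near_lo = np.mean(np.abs(t.logg - cfg.mu_low) < 0.3)
        if near_hi > near_lo:
            n_hi += 1
        else:
            n_lo += 1
    assert 0.35 < n_hi / (n_hi + n_lo) < 0.65


def test_trace_dataframe_roundtrip():
    traces = sd.generate_traces(sd.TraceGenConfig(n_traces=5, seed=1))
    df = sd.traces_to_dataframe(traces)
    back = sd.traces_from_dataframe(df)
    assert len(back) == 5
    for a, b in zip(traces, back):
        assert np.allclose(a.logg, b.logg)
        assert a.truth_label == b.truth_label


def test_config_validation():
    with pytest.raises(ValueError):
        sd.TraceGenConfig(molecular_fraction=1.5)
    with pytest.raises(ValueError):
        sd.TraceGenConfig(mu_high=-5.0, mu_low=-4.0)
    with pytest.raises(ValueError):
        sd.SamplerConfig(n_steps=100, burn_in=200)
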