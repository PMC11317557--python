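"""Implicit-gold restraint potentials: closed forms, finite-difference
force consistency, and symmetry invariances."""

import numpy as np
import pytest

from pepjunction import gold_restraints as gr
from pepjunction import peptide_model as pm


def _random_conf(seq="MAAM", seed=0):
    topo = pm.build_topology(seq)
    return pm.build_conformation(topo, pm.randomize_dihedrals(topo, seed))


def _with_dz(conf, dz):
    """Shift the C-terminal sulfur's z so z_S2 - z_S1 = dz (test helper)."""
    s1, s2 = conf.topology.sulfur_ids()
    coords = conf.coords.copy()
    coords[s2, 2] = coords[s1, 2] + dz
    return pm.Conformation(conf.topology, coords)


def _fd_force(fn, conf, params, h=1e-5):
    """Central finite-difference forces, -dU/dx."""
    coords = conf.coords
    out = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for ax in range(3):
            cp = coords.copy()
            cp[i, ax] += h
            ep = fn(pm.Conformation(conf.topology, cp), params).energy
            cm = coords.copy()
            cm[i, ax] -= h
            em = fn(pm.Conformation(conf.topology, cm), params).energy
            out[i, ax] = -(ep - em) / (2 * h)
    return out


class TestU1:
    def test_at_minimum(self):
        conf = _with_dz(_random_conf(), 6.0)
        res = gr.u1_energy_force(conf, gr.RestraintParams(z0=6.0))
        assert res.energy == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.forces, 0.0)

    def test_closed_form(self):
        conf = _with_dz(_random_conf(), 8.0)
        res = gr.u1_energy_force(conf, gr.RestraintParams(k1=1.0, z0=6.0))
        assert res.energy == pytest.approx(2.0)
        s1, s2 = conf.topology.sulfur_ids()
        assert res.forces[s2] == pytest.approx([0.0, 0.0, -2.0])
        assert res.forces[s1] == pytest.approx([0.0, 0.0, 2.0])

    def test_signed_displacement_penalized(self):
        """U1 uses the signed projection: dz = -6 is NOT a minimum."""
        conf = _with_dz(_random_conf(), -6.0)
        res = gr.u1_energy_force(conf, gr.RestraintParams(z0=6.0))
        assert res.energy == pytest.approx(72.0)

    def test_nonnegative_many(self):
        params = gr.RestraintParams(z0=9.0)
        for seed in range(30):
            e = gr.u1_energy_force(_random_conf(seed=seed), params).energy
            assert e >= 0.0


class TestU2:
    def test_zero_charges(self):
        conf = _random_conf()
        params = gr.RestraintParams(
            charges=np.zeros(conf.topology.n_atoms))
        assert gr.u2_energy_force(conf, params).energy == 0.0

    def test_single_charge_closed_form(self):
        """q = +1 e moved from z=0 to z = z0 + 2 l gains -V in eV."""
        conf = _random_conf()
        topo = conf.topology
        q = np.zeros(topo.n_atoms)
        probe = 5
        q[probe] = 1.0
        params = gr.RestraintParams(z0=6.0, l_s_au=2.4, voltage=0.25,
                                    charges=q)
        c0 = conf.coords.copy()
        c0[probe] = [0.0, 0.0, 0.0]
        e0 = gr.u2_energy_force(pm.Conformation(topo, c0), params).energy
        c1 = c0.copy()
        c1[probe, 2] = 6.0 + 2 * 2.4
        e1 = gr.u2_energy_force(pm.Conformation(topo, c1), params).energy
        assert e0 == pytest.approx(0.0, abs=1e-12)
        assert e1 == pytest.approx(-0.25 * gr.EV_TO_KCAL_PER_MOL)
        assert e1 == pytest.approx(-5.765, abs=1e-3)

    def test_neutral_molecule_translation_invariant(self):
        """The field couples only to the dipole of a net-neutral system."""
        conf = _random_conf("MGGGM", seed=3)
        params = gr.RestraintParams()
        q = params.charges_for(conf.topology)
        assert q.sum() == pytest.approx(0.0)
        e0 = gr.u2_energy_force(conf, params).energy
        shifted = pm.Conformation(conf.topology, conf.coords + [0, 0, 7.3])
        e1 = gr.u2_energy_force(shifted, params).energy
        assert e1 == pytest.approx(e0, abs=1e-9)


class TestU3:
    def _oriented_conf(self, up_first=True):
        """Conformation with p1 along +z and p2 along -z (global min)."""
        topo = pm.build_topology("MAAM")
        conf = pm.build_conformation(topo, pm.randomize_dihedrals(topo, 1))
        coords = conf.coords.copy()
        for idx, s in enumerate(topo.sulfur_ids()):
            cg, ce = topo.sulfur_carbon_neighbors(s)
            sign = 1.0 if (idx == 0) == up_first else -1.0
            coords[cg] = coords[s] + [1.0, 0.0, -sign * 1.0]
            coords[ce] = coords[s] + [-1.0, 0.0, -sign * 1.0]
        return pm.Conformation(topo, coords)

    def test_global_minimum(self):
        conf = self._oriented_conf(up_first=True)
        res = gr.u3_energy_force(conf, gr.RestraintParams(k3=10.0))
        assert res.energy == pytest.approx(-20.0)

    def test_perpendicular_vanishes(self):
        topo = pm.build_topology("MAAM")
        conf = pm.build_conformation(topo, pm.randomize_dihedrals(topo, 2))
        coords = conf.coords.copy()
        for s in topo.sulfur_ids():
            cg, ce = topo.sulfur_carbon_neighbors(s)
            coords[cg] = coords[s] + [1.0, 1.0, 0.0]
            coords[ce] = coords[s] + [-1.0, 1.0, 0.0]
        res = gr.u3_energy_force(pm.Conformation(topo, coords),
                                 gr.RestraintParams())
        assert res.energy == pytest.approx(0.0, abs=1e-12)

    def test_bounds_and_invariances(self):
        params = gr.RestraintParams(k3=10.0)
        for seed in range(50):
            conf = _random_conf("MGGGM", seed=seed)
            e = gr.u3_energy_force(conf, params).energy
            assert -20.0 - 1e-9 <= e <= 20.0 + 1e-9
            # rigid translation invariance
            shifted = pm.Conformation(conf.topology,
                                      conf.coords + [1.1, -2.2, 3.3])
            assert gr.u3_energy_force(shifted, params).energy == \
                pytest.approx(e)

    def test_z_rotation_invariance(self):
        """U1 and U3 are invariant under rotations about the z-axis."""
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0],
                        [0, 0, 1.0]])
        params = gr.RestraintParams(z0=9.0)
        for seed in (0, 5):
            conf = _random_conf("MAAM", seed=seed)
            rotated = pm.Conformation(conf.topology, conf.coords @ rot.T)
            for fn in (gr.u1_energy_force, gr.u3_energy_force):
                assert fn(rotated, params).energy == \
                    pytest.approx(fn(conf, params).energy)


@pytest.mark.parametrize("fn", [gr.u1_energy_force, gr.u2_energy_force,
                                gr.u3_energy_force])
def test_forces_match_finite_differences(fn):
    """Analytic forces match central differences to 1e-6 relative."""
    params = gr.RestraintParams(z0=6.0)
    for seed in range(10):
        conf = _random_conf("MAAM", seed=seed)
        analytic = fn(conf, params).forces
        numeric = _fd_force(fn, conf, params)
        scale = max(np.abs(numeric).max(), 1.0)
        assert np.max(np.abs(analytic - numeric)) / scale < 1e-6


def test_force_sums():
    """U1/U3 are internal (forces sum to zero); U2's net force is
    (0, 0, E_conv * sum q)."""
    for seed in range(10):
        conf = _random_conf("MGGGM", seed=seed)
        params = gr.RestraintParams(z0=9.0)
        for fn in (gr.u1_energy_force, gr.u3_energy_force):
            assert np.allclose(fn(conf, params).forces.sum(axis=0), 0.0,
                               atol=1e-9)
        f2 = gr.u2_energy_force(conf, params).forces.sum(axis=0)
        q = params.charges_for(conf.topology)
        expected = params.field_strength * gr.EV_TO_KCAL_PER_MOL * q.sum()
        assert f2 == pytest.approx([0.0, 0.0, expected], abs=1e-12)


def test_total_additivity():
    for seed in range(5):
        conf = _random_conf("MYYM", seed=seed)
        params = gr.RestraintParams(z0=6.0)
        total = gr.total_restraint_energy(conf, params)
        parts = [f(conf, params) for f in
                 (gr.u1_energy_force, gr.u2_energy_force,
                  gr.u3_energy_force)]
        assert total.energy == pytest.approx(sum(p.energy for p in parts))
        assert np.allclose(total.forces,
                           sum(p.forces for p in parts), atol=1e-12)


def test_param_validation():
    with pytest.raises(ValueError):
        gr.RestraintParams(k1=-1.0)
    with pytest.raises(ValueError):
        gr.RestraintParams(k3=-0.1)
    conf = _random_conf()
    with pytest.raises(ValueError):
        gr.u2_energy_force(conf, gr.RestraintParams(charges=np.zeros(3)))
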