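"""Generators: uniform sphere, Platonic shells, the dipolar-shell Metropolis
chain, charge-jump protocol, Brownian walks, occupancy fixtures, water boxes."""

import numpy as np
import pytest
from scipy import stats

from hydrashell.core import Box, min_image_displacement
from hydrashell.synth import (
    McParams,
    brownian_walk,
    charge_jump_protocol,
    platonic_shell,
    sample_uniform_sphere,
    shell_mc_simulate,
    stretched_occupancy,
    toy_water_box,
)

TETRA_ANGLE = np.degrees(np.arccos(-1.0 / 3.0))


def pair_angles_deg(points):
    u = points / np.linalg.norm(points, axis=1)[:, None]
    c = np.clip(u @ u.T, -1, 1)
    iu = np.triu_indices(len(u), k=1)
    return np.degrees(np.arccos(c[iu]))


class TestUniformSphere:
    def test_radii_and_reproducibility(self):
        a = sample_uniform_sphere(50, 2.8, seed=9)
        b = sample_uniform_sphere(50, 2.8, seed=9)
        assert np.allclose(np.linalg.norm(a, axis=1), 2.8, atol=1e-9)
        assert np.array_equal(a, b)

    def test_pair_angle_law(self):
        """cos(phi) of independent point pairs is uniform on [-1, 1]."""
        pts = sample_uniform_sphere(2000, 1.0, seed=1)
        u = pts / np.linalg.norm(pts, axis=1)[:, None]
        cos = np.einsum("ij,ij->i", u[0::2], u[1::2])  # disjoint pairs
        res = stats.kstest(cos, stats.uniform(loc=-1, scale=2).cdf)
        assert res.pvalue > 0.01

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            sample_uniform_sphere(0, 1.0)
        with pytest.raises(ValueError):
            sample_uniform_sphere(5, -1.0)


class TestPlatonicShell:
    def test_tetrahedron_angles(self):
        ang = pair_angles_deg(platonic_shell(4, 2.8))
        assert np.allclose(ang, TETRA_ANGLE, atol=1e-9)

    def test_octahedron_angle_multiset(self):
        ang = np.sort(pair_angles_deg(platonic_shell(6, 1.0)))
        assert np.allclose(ang[:12], 90.0, atol=1e-9)
        assert np.allclose(ang[12:], 180.0, atol=1e-9)

    @pytest.mark.parametrize("n", [4, 6, 8, 12, 20])
    def test_radius_scaling(self, n):
        pts = platonic_shell(n, 3.1)
        assert np.allclose(np.linalg.norm(pts, axis=1), 3.1, atol=1e-12)

    def test_unsupported_count(self):
        with pytest.raises(ValueError):
            platonic_shell(5, 1.0)


MC_BASE = dict(n_shell=6, shell_spring=20.0, n_equil=800, seed=11)


class TestShellMc:
    def test_neutral_ion_has_no_dipolar_order(self):
        res = shell_mc_simulate(McParams(ion_charge=0.0, n_steps=6000,
                                         **{**MC_BASE, "seed": 2}))
        assert abs(res.mean_cos_theta()) < 0.08
        assert 0.0 < res.acceptance_rate < 1.0

    def test_dipolar_order_monotone_in_charge(self):
        means = []
        for q in [0.0, 0.5, 1.0, 2.0, 4.0]:
            res = shell_mc_simulate(McParams(ion_charge=q, n_steps=3000, **MC_BASE))
            means.append(res.mean_cos_theta())
        # common seed; allow small sampling slack between adjacent rungs
        assert all(b > a - 0.03 for a, b in zip(means, means[1:]))
        assert means[-1] > 0.9

    def test_energy_bookkeeping_identity(self):
        res = shell_mc_simulate(McParams(ion_charge=1.0, n_steps=1500, **MC_BASE))
        assert res.final_energy_tracked == pytest.approx(
            res.final_energy_recomputed, abs=1e-6)

    def test_histogram_reweighting_between_temperatures(self):
        """Detailed-balance diagnostic: energies sampled at T_a, reweighted by
        exp(-(1/kT_b - 1/kT_a) E), reproduce the mean energy of a direct run
        at T_b on the overlapping support."""
        from hydrashell.core import KB
        # weak dipolar coupling keeps the 4-particle shell ergodic, so the
        # two chains sample the same basin and the histograms overlap
        base = dict(n_shell=4, ion_charge=0.5, dipole_moment=0.2,
                    shell_spring=20.0, n_steps=8000, n_equil=1000,
                    sample_every=5)
        ta, tb = 280.0, 310.0
        ea = shell_mc_simulate(McParams(temperature=ta, seed=21, **base)).energies
        eb = shell_mc_simulate(McParams(temperature=tb, seed=22, **base)).energies
        dbeta = 1.0 / (KB * tb) - 1.0 / (KB * ta)
        w = np.exp(-dbeta * (ea - ea.mean()))
        reweighted = float((ea * w).sum() / w.sum())
        assert reweighted == pytest.approx(float(eb.mean()), abs=1.5)
        # and the reweighting moves the estimate off the raw T_a mean
        assert abs(reweighted - ea.mean()) > 0.5

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            McParams(n_shell=0)
        with pytest.raises(ValueError):
            McParams(temperature=-10.0)
        with pytest.raises(ValueError):
            McParams(translation_scale=0.0)


JUMP_BASE = dict(n_shell=6, shell_spring=20.0, sample_every=4, n_steps=600)


class TestChargeJump:
    def test_null_protocol_is_stationary(self):
        res = charge_jump_protocol(
            McParams(seed=5, n_shell=6, shell_spring=20.0,
                     sample_every=20, n_steps=1200),
            q_before=1.0, q_after=1.0, n_replicas=8, equil_steps=2000)
        # thin to ~decorrelated spacing: Mann-Kendall assumes independence
        m = res.mean_cos_theta()[::3]
        tau, p = stats.kendalltau(res.steps[::3], m)
        assert p > 0.01  # no monotone trend

    def test_relaxation_toward_equilibrium_endpoint(self):
        res = charge_jump_protocol(McParams(seed=6, **JUMP_BASE),
                                   q_before=0.0, q_after=2.0,
                                   n_replicas=10, equil_steps=400)
        m = res.mean_cos_theta()
        eq = shell_mc_simulate(McParams(ion_charge=2.0, n_steps=3000,
                                        n_equil=800, n_shell=6,
                                        shell_spring=20.0, seed=77))
        assert m[0] < 0.7          # starts far from the ordered state
        assert m[-1] > m[0]        # relaxes upward
        assert m[-10:].mean() == pytest.approx(eq.mean_cos_theta(), abs=0.1)

    def test_replica_count_honoured_and_equal_charge_guard(self):
        res = charge_jump_protocol(McParams(seed=5, n_shell=4, n_steps=100,
                                            shell_spring=20.0),
                                   q_before=0.2, q_after=0.4,
                                   n_replicas=3, equil_steps=50)
        assert res.n_replicas == 3
        with pytest.raises(ValueError):
            charge_jump_protocol(McParams(n_shell=4), 1.0, 1.0,
                                 n_replicas=1, equil_steps=10,
                                 require_change=True)


class TestBrownianWalk:
    def test_zero_diffusion_is_static(self):
        t = brownian_walk(0.0, 0.1, 50, 7, seed=0)
        assert np.all(t.positions == t.positions[0])

    def test_seeded_reproducibility(self):
        a = brownian_walk(0.2, 0.05, 100, 5, seed=3)
        b = brownian_walk(0.2, 0.05, 100, 5, seed=3)
        assert np.array_equal(a.positions, b.positions)

    def test_increment_variance(self):
        t = brownian_walk(0.2, 0.05, 400, 200, seed=4)
        inc = np.diff(t.positions, axis=0)
        assert inc.var() == pytest.approx(2 * 0.2 * 0.05, rel=0.05)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            brownian_walk(-0.1, 0.1, 10, 1)
        with pytest.raises(ValueError):
            brownian_walk(0.1, 0.0, 10, 1)


class TestStretchedOccupancy:
    def test_exact_values(self):
        t = np.arange(0.0, 50.25, 0.25)  # grid contains t = tau = 10 exactly
        s = stretched_occupancy(10.0, 1.0, t)
        assert s.p[t == 10.0][0] == pytest.approx(np.exp(-1), abs=1e-12)
        s = stretched_occupancy(10.0, 0.8, t)
        assert s.p[t == 10.0][0] == pytest.approx(np.exp(-1), abs=1e-12)
        assert s.p[0] == 1.0

    def test_noiseless_curve_strictly_decreasing(self):
        s = stretched_occupancy(5.0, 0.7, np.linspace(0, 30, 100))
        assert np.all(np.diff(s.p) < 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            stretched_occupancy(-1.0, 1.0, [0, 1])
        with pytest.raises(ValueError):
            stretched_occupancy(1.0, 2.5, [0, 1])
        with pytest.raises(ValueError):
            stretched_occupancy(1.0, 1.0, [0, 2, 1])


class TestHbondDimer:
    def test_geometry_and_attraction(self):
        from hydrashell.core import Frame
        from hydrashell.energetics import TIP4P2005_OO, pair_potential
        from hydrashell.hbond import detect_hbonds
        from hydrashell.synth import hbond_dimer

        donor, acceptor = hbond_dimer([5.0, 5.0, 5.0], d_oo=2.8)
        donor.check_rigid()
        acceptor.check_rigid()
        frame = Frame(time=0.0, ions=[], waters=[donor, acceptor],
                      box=Box(20.0), wrap=False)
        bonds = detect_hbonds(frame)
        assert len(bonds) == 1 and bonds[0].angle < 1e-6
        e = pair_potential(donor.sites(), acceptor.sites(), TIP4P2005_OO)
        assert e < -15.0  # a genuine hydrogen bond


class TestToyWaterBox:
    def test_geometry_count_and_packing(self):
        box = Box(15.0)
        frame = toy_water_box(30, box, seed=8)
        assert len(frame.waters) == 30
        opos = frame.oxygen_positions()
        for w in frame.waters:
            w.check_rigid(box)
        for i in range(len(opos)):
            d = np.linalg.norm(
                min_image_displacement(opos[i], opos[i + 1:], box), axis=-1)
            if d.size:
                assert d.min() >= 2.2

    def test_motif_inserted_verbatim(self):
        from hydrashell.core import build_water
        motif = build_water([3.0, 3.0, 3.0])
        frame = toy_water_box(5, Box(12.0), seed=1, motifs=[motif])
        assert frame.waters[0] is motif
        assert np.allclose(frame.waters[0].oxygen.position, [3.0, 3.0, 3.0])

    def test_packing_failure_raises(self):
        with pytest.raises(RuntimeError):
            toy_water_box(200, Box(5.0), seed=0, max_attempts_per_water=20)
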