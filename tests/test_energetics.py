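"""LJ/Coulomb pair sums, closed-form charge-dipole cross-checks, and the
shell energy scales E_w-w, dE_ion-water, E_hbond."""

import numpy as np
import pytest

from hydrashell.core import (
    Box,
    Frame,
    KE_COULOMB,
    Site,
    build_water,
)
from hydrashell.energetics import (
    AnalysisError,
    PairParams,
    TIP4P2005_OO,
    charge_dipole_energy,
    dipole_dipole_energy,
    hbond_energy_bulk,
    ion_water_energy,
    lj_energy,
    pair_potential,
    shell_pair_energy,
)
from hydrashell.shell import ShellAssignment

from helpers import attractive_dimer, water_with_oh_toward


class TestPairPotential:
    def test_lj_minimum(self):
        params = PairParams(epsilon=0.8, sigma=3.0)
        a = [Site([0, 0, 0], 0.0)]
        b = [Site([3.0 * 2 ** (1 / 6), 0, 0], 0.0)]
        assert pair_potential(a, b, params) == pytest.approx(-0.8, abs=1e-12)

    def test_lj_zero_at_sigma(self):
        params = PairParams(epsilon=0.8, sigma=3.0)
        a = [Site([0, 0, 0], 0.0)]
        b = [Site([3.0, 0, 0], 0.0)]
        assert pair_potential(a, b, params) == pytest.approx(0.0, abs=1e-12)

    def test_coulomb_constant(self):
        params = PairParams(epsilon=0.0, sigma=1.0)
        a = [Site([0, 0, 0], 1.0)]
        b = [Site([1.0, 0, 0], 1.0)]
        assert pair_potential(a, b, params, lj_pair=None) == pytest.approx(
            1389.35458, abs=1e-6)

    def test_symmetric_and_translation_invariant(self):
        params = PairParams(epsilon=0.5, sigma=2.8)
        rng = np.random.default_rng(0)
        a = [Site(rng.uniform(0, 5, 3), 0.4), Site(rng.uniform(0, 5, 3), -0.4)]
        b = [Site(rng.uniform(0, 5, 3), 0.2), Site(rng.uniform(0, 5, 3), -0.2)]
        e_ab = pair_potential(a, b, params)
        e_ba = pair_potential(b, a, params)
        assert e_ab == pytest.approx(e_ba, rel=1e-12)
        shift = np.array([11.0, -3.0, 7.0])
        a2 = [Site(s.position + shift, s.charge) for s in a]
        b2 = [Site(s.position + shift, s.charge) for s in b]
        assert pair_potential(a2, b2, params) == pytest.approx(e_ab, rel=1e-12)

    def test_zero_separation_rejected(self):
        params = PairParams(epsilon=0.5, sigma=2.8)
        with pytest.raises(ValueError):
            pair_potential([Site([1, 1, 1], 1.0)], [Site([1, 1, 1], 1.0)],
                           params, lj_pair=None)


class TestClosedFormDipoles:
    def test_charge_dipole_closed_form(self):
        q, p, d = 1.3, 0.48, 2.6
        mu = np.array([0.0, 0.0, p])           # aligned radially outward
        r_vec = np.array([0.0, 0.0, d])
        expected = -KE_COULOMB * q * p / d**2
        assert charge_dipole_energy(q, mu, r_vec) == pytest.approx(
            expected, abs=1e-9)

    def test_radial_dipoles_90_degrees_apart_repel(self):
        """Two radially aligned dipoles a quarter-circle apart on a shell:
        closed form +1.5 k_e p^2 / r^3 > 0."""
        p, R = 0.48, 2.4
        x1, x2 = np.array([R, 0, 0]), np.array([0, R, 0])
        mu1, mu2 = p * np.array([1, 0, 0]), p * np.array([0, 1, 0])
        r = np.linalg.norm(x2 - x1)
        expected = 1.5 * KE_COULOMB * p**2 / r**3
        e = dipole_dipole_energy(mu1, mu2, x2 - x1)
        assert e == pytest.approx(expected, abs=1e-9)
        assert e > 0


def shell_of(frame, indices, d=2.3, r1=3.0):
    return ShellAssignment(d=d, r1=r1, n=float(len(indices)),
                           membership=[[np.asarray(indices)]])


class TestShellPairEnergy:
    def test_hbonded_dimer_negative_matches_site_sum(self):
        L = 20.0
        o1 = np.array([8.0, 10.0, 10.0])
        donor, acceptor = attractive_dimer(o1)
        ion = Site(np.array([9.4, 12.5, 10.0]), 1.0, "ION")
        frame = Frame(time=0.0, ions=[ion], waters=[donor, acceptor],
                      box=Box(L), wrap=False)
        res = shell_pair_energy(frame, shell_of(frame, [0, 1]))
        # independent site-site summation oracle
        expected = lj_energy(2.8, TIP4P2005_OO.epsilon, TIP4P2005_OO.sigma)
        for sa in donor.sites():
            for sb in acceptor.sites():
                if sa.charge and sb.charge:
                    r = np.linalg.norm(sa.position - sb.position)
                    expected += KE_COULOMB * sa.charge * sb.charge / r
        assert res.mean == pytest.approx(expected, abs=1e-9)
        assert res.mean < 0  # a hydrogen bond is attractive

    def test_single_water_flagged(self):
        frame = Frame(time=0.0, ions=[Site([5, 5, 5], 1.0)],
                      waters=[build_water([7.0, 5.0, 5.0])],
                      box=Box(20.0), wrap=False)
        with pytest.raises(AnalysisError):
            shell_pair_energy(frame, shell_of(frame, [0]))


class TestIonWaterEnergy:
    def test_neutral_ion_at_lj_minimum(self):
        L = 20.0
        params = PairParams(epsilon=0.79, sigma=2.6)
        ion = Site(np.full(3, 10.0), 0.0, "M")
        w = build_water(ion.position + np.array([2.6 * 2 ** (1 / 6), 0, 0]))
        frame = Frame(time=0.0, ions=[ion], waters=[w], box=Box(L), wrap=False)
        res = ion_water_energy(frame, shell_of(frame, [0]), params)
        assert res.mean == pytest.approx(0.79, abs=1e-9)  # |-epsilon|

    def test_coulomb_part_follows_charge_dipole_power_law(self):
        """|Coulomb ion-water energy| of a radially aligned rigid water is a
        clean power law in d, approaching the far-field charge-dipole 1/d^2."""
        from scipy.spatial.transform import Rotation
        params = PairParams(epsilon=0.0, sigma=2.6)
        L = 60.0
        rot, _ = Rotation.align_vectors([[1.0, 0, 0]], [[0, 0, 1.0]])
        energies, dists = [], np.linspace(4.0, 10.0, 12)
        for d in dists:
            ion = Site(np.full(3, 30.0), 1.0, "ION")
            # dipole (bisector) exactly radial, pointing away from the ion
            w = build_water(ion.position + np.array([d, 0, 0]), rot.as_matrix())
            frame = Frame(time=0.0, ions=[ion], waters=[w], box=Box(L),
                          wrap=False)
            res = ion_water_energy(frame, shell_of(frame, [0], r1=d + 0.5),
                                   params)
            energies.append(res.mean)
        logd, loge = np.log(dists), np.log(energies)
        slope, intercept = np.polyfit(logd, loge, 1)
        pred = slope * logd + intercept
        r2 = 1 - ((loge - pred) ** 2).sum() / ((loge - loge.mean()) ** 2).sum()
        assert r2 > 0.999
        assert slope == pytest.approx(-2.0, abs=0.1)


class TestHbondEnergyBulk:
    def _dimer_frame(self, origin, d_oo=2.9):
        o1 = np.asarray(origin, dtype=float)
        o2 = o1 + np.array([d_oo, 0.0, 0.0])
        donor = water_with_oh_toward(o1, o2)
        acceptor = water_with_oh_toward(o2, o2 + np.array([0.0, 0.0, 1.0]))
        return donor, acceptor

    def test_single_dimer_mean_and_zero_band(self):
        d, a = self._dimer_frame([5.0, 10.0, 10.0])
        frame = Frame(time=0.0, ions=[], waters=[d, a], box=Box(25.0),
                      wrap=False)
        res = hbond_energy_bulk(frame)
        expected = pair_potential(d.sites(), a.sites(), TIP4P2005_OO, frame.box)
        assert res.mean == pytest.approx(expected, abs=1e-9)
        assert res.sd == pytest.approx(0.0, abs=1e-12)

    def test_two_dimers_population_arithmetic(self):
        d1, a1 = self._dimer_frame([4.0, 5.0, 5.0], d_oo=2.8)
        d2, a2 = self._dimer_frame([4.0, 15.0, 15.0], d_oo=3.2)
        frame = Frame(time=0.0, ions=[], waters=[d1, a1, d2, a2],
                      box=Box(25.0), wrap=False)
        res = hbond_energy_bulk(frame)
        e1 = pair_potential(d1.sites(), a1.sites(), TIP4P2005_OO, frame.box)
        e2 = pair_potential(d2.sites(), a2.sites(), TIP4P2005_OO, frame.box)
        assert res.mean == pytest.approx((e1 + e2) / 2, abs=1e-9)
        assert res.sd == pytest.approx(abs(e1 - e2) / 2, abs=1e-9)

    def test_randomized_box_matches_bond_list_loop(self):
        from hydrashell.hbond import detect_hbonds
        from hydrashell.synth import toy_water_box
        frame = toy_water_box(40, Box(12.0), seed=19)
        try:
            res = hbond_energy_bulk(frame)
        except AnalysisError:
            pytest.skip("seeded box produced no H-bonds")
        seen, energies = set(), []
        for b in detect_hbonds(frame):
            key = frozenset((b.donor, b.acceptor))
            if key in seen:
                continue
            seen.add(key)
            i, j = sorted(key)
            energies.append(pair_potential(frame.waters[i].sites(),
                                           frame.waters[j].sites(),
                                           TIP4P2005_OO, frame.box))
        assert res.mean == pytest.approx(np.mean(energies), abs=1e-9)
        assert res.n_pairs == len(energies)

    def test_no_bonds_rejected(self):
        w1 = build_water([2.0, 2.0, 2.0])
        w2 = build_water([10.0, 10.0, 10.0])
        frame = Frame(time=0.0, ions=[], waters=[w1, w2], box=Box(21.0),
                      wrap=False)
        with pytest.raises(AnalysisError):
            hbond_energy_bulk(frame)
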