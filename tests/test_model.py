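"""Mechanics: potentials, forces, system construction, Langevin dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromsilence import (
    Affinity,
    ChromatinState,
    ForceField,
    bending_energy,
    bond_energy,
    bond_minimum,
    build_system,
    langevin_step,
    make_interaction_table,
    pair_energy,
    total_energy,
    total_force,
)
from chromsilence.core import WCA_CUT, min_image_distance
from chromsilence.model import IntegrationError, relax

from conftest import interacting_system


# --------------------------------------------------------------------------
# scalar potentials
# --------------------------------------------------------------------------

class TestBondEnergy:
    def test_harmonic_zero_at_rest_length(self):
        ff = ForceField(bond_type="harmonic", bond_k=10.0, bond_r0=1.1)
        assert bond_energy(1.1, ff) == 0.0

    def test_fene_matches_independent_formula(self, ff):
        # independent transcription of -0.5 K R0^2 ln(1 - (r/R0)^2)
        expected = -0.5 * 30.0 * 1.6 ** 2 * math.log(1.0 - (1.0 / 1.6) ** 2)
        assert bond_energy(1.0, ff) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(19.0203, abs=1e-3)

    def test_fene_diverges_monotonically_near_r0(self, ff):
        rs = np.linspace(1.55, 1.6 - 1e-9, 50)
        es = bond_energy(rs, ff)
        assert np.all(np.diff(es) > 0)
        assert es[-1] > 500.0  # ~ -0.5 K R0^2 ln(eps) at r -> R0
        with pytest.raises(ValueError, match="blow-up"):
            bond_energy(1.6, ff)

    def test_combined_bond_minimum_near_one_sigma(self, ff):
        assert 0.9 < bond_minimum(ff) < 1.0


class TestBendingEnergy:
    @pytest.mark.parametrize(
        "theta,expected",
        [(0.0, 0.0), (np.pi / 2, 3.0), (np.pi, 6.0)],
    )
    def test_kratky_porod_values(self, theta, expected):
        assert bending_energy(theta, 3.0) == pytest.approx(expected, abs=1e-12)

    def test_zero_iff_collinear(self):
        assert bending_energy(1e-3, 2.0) > 0


class TestPairEnergy:
    @pytest.mark.parametrize("affinity", list(Affinity))
    def test_exactly_zero_at_and_beyond_cutoff(self, affinity, ff):
        cut = WCA_CUT if affinity == Affinity.STERIC else ff.attraction_cutoff
        for r in (cut, cut + 1e-12, 2.5, 10.0):
            assert pair_energy(r, affinity, ff) == 0.0

    def test_wca_minimum_at_cutoff(self, ff):
        assert pair_energy(WCA_CUT, Affinity.STERIC, ff) == 0.0
        # zero slope at the WCA cutoff: energy just inside is ~ O(h^2)
        h = 1e-6
        assert abs(pair_energy(WCA_CUT - h, Affinity.STERIC, ff)) < 1e-9

    def test_strong_minimum_matches_shifted_lj_formula(self, ff):
        # independent transcription of the truncated-shifted LJ at its minimum
        rc = ff.attraction_cutoff
        shift = 4.0 * 8.0 * ((1.0 / rc) ** 12 - (1.0 / rc) ** 6)
        expected = -8.0 - shift
        assert pair_energy(2 ** (1 / 6), Affinity.STRONG, ff) == pytest.approx(
            expected, rel=1e-12
        )

    def test_depth_ordering(self, ff):
        r = 2 ** (1 / 6)
        e_weak = pair_energy(r, Affinity.WEAK, ff)
        e_strong = pair_energy(r, Affinity.STRONG, ff)
        assert e_strong < e_weak < 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(r=st.floats(0.8, 3.0), aff=st.sampled_from(list(Affinity)))
    def test_continuity_and_truncation_property(self, r, aff):
        ff = ForceField()
        e = pair_energy(r, aff, ff)
        cut = WCA_CUT if aff == Affinity.STERIC else ff.attraction_cutoff
        if r >= cut:
            assert e == 0.0
        else:
            assert np.isfinite(e)


# --------------------------------------------------------------------------
# system construction
# --------------------------------------------------------------------------

class TestBuildSystem:
    def test_paper_scale_counts(self, ff):
        rng = np.random.default_rng(5)
        tu_ids = np.sort(rng.choice(1000, 39, replace=False) + 1)
        st_ = build_system(1000, tu_ids, 40, 40, 20, 60.0, seed=1, ff=ff)
        assert st_.n_beads == 1000
        assert st_.is_tu.sum() == 39
        assert (st_.chromatin_state[st_.is_tu] == ChromatinState.TU_ACTIVE).all()
        assert st_.n_tf == 80
        assert st_.tf_state.sum() == 40  # 20 ON per species
        assert st_.tf_state[st_.tf_species == 0].sum() == 20
        st_.validate()
        # bonds at the bond-potential minimum
        d = min_image_distance(st_.bead_pos[:-1], st_.bead_pos[1:], 60.0)
        assert np.allclose(d, bond_minimum(ff), atol=1e-9)

    def test_minimal_two_bead_chain(self, ff):
        st_ = build_system(2, [], 0, 0, 0, 10.0, seed=0, ff=ff)
        assert st_.n_beads == 2 and st_.n_tf == 0
        assert not st_.is_tu.any()

    def test_same_seed_bitwise_identical(self, ff):
        a = build_system(50, [10, 20], 4, 4, 2, 20.0, seed=42, ff=ff)
        b = build_system(50, [10, 20], 4, 4, 2, 20.0, seed=42, ff=ff)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.tf_state, b.tf_state)

    @pytest.mark.parametrize("bad", [[5, 5], [0], [13]])
    def test_invalid_tu_ids_rejected(self, bad, ff):
        with pytest.raises(ValueError):
            build_system(12, bad, 2, 2, 1, 12.0, seed=0, ff=ff)

    def test_non_dilute_box_rejected(self, ff):
        with pytest.raises(ValueError, match="dilute"):
            build_system(200, [1], 0, 0, 0, 10.0, seed=0, ff=ff)


# --------------------------------------------------------------------------
# forces
# --------------------------------------------------------------------------

class TestForces:
    def test_matches_numerical_gradient(self, ff, table_positive):
        st_ = interacting_system(ff, seed=3)
        F = total_force(st_, table_positive, ff, method="allpairs")
        h = 1e-6
        G = np.zeros_like(F)
        for i in range(st_.pos.shape[0]):
            for d in range(3):
                p0 = st_.pos[i, d]
                st_.pos[i, d] = p0 + h
                ep = total_energy(st_, table_positive, ff, method="allpairs")
                st_.pos[i, d] = p0 - h
                em = total_energy(st_, table_positive, ff, method="allpairs")
                st_.pos[i, d] = p0
                G[i, d] = -(ep - em) / (2 * h)
        scale = np.abs(F).max()
        assert np.abs(F - G).max() / scale < 1e-5

    def test_newtons_third_law(self, ff, table_positive):
        st_ = interacting_system(ff, seed=11)
        F = total_force(st_, table_positive, ff)
        assert np.abs(F.sum(axis=0)).max() < 1e-9 * max(np.abs(F).max(), 1.0)

    def test_cell_list_matches_allpairs(self, ff, table_positive):
        st_ = interacting_system(ff, seed=5, n_beads=40, n_tf=8, box=20.0)
        Fa = total_force(st_, table_positive, ff, method="allpairs")
        Fc = total_force(st_, table_positive, ff, method="cells")
        assert np.allclose(Fa, Fc, rtol=1e-12, atol=1e-12)

    def test_isolated_off_tf_feels_no_force(self, ff, table_positive):
        st_ = interacting_system(ff, seed=1)
        # move the last TF (OFF state) far from everything
        st_.tf_state[-1] = 0
        st_.pos[-1] = (st_.pos[:-1].mean(axis=0) + st_.box_length / 2) % st_.box_length
        F = total_force(st_, table_positive, ff, method="allpairs")
        d = min_image_distance(st_.pos[:-1], st_.pos[-1], st_.box_length)
        if d.min() > 2.0:  # out of every interaction range
            assert np.allclose(F[-1], 0.0)


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

class TestLangevin:
    def test_zero_temperature_fixed_point(self, ff, table_positive):
        # two beads at the bond + WCA minimum, kT = 0: stationary
        b0 = bond_minimum(ff)
        st_ = build_system(2, [], 0, 0, 0, 20.0, seed=0, ff=ff)
        st_.pos[0] = [5.0, 5.0, 5.0]
        st_.pos[1] = [5.0 + b0, 5.0, 5.0]
        before = st_.pos.copy()
        rng = np.random.default_rng(0)
        langevin_step(st_, table_positive, ff, dt=0.01, gamma=1.0, kT=0.0,
                      rng=rng, n_steps=100)
        assert np.allclose(st_.pos, before, atol=1e-9)

    def test_free_diffusion_msd_slope(self, ff, table_positive):
        # 150 isolated TFs in a huge box == independent free particles
        n = 150
        st_ = build_system(1, [], n, 0, 0, 400.0, seed=3, ff=ff)
        st_.pos[0] = 0.0  # lone bead far away in a corner
        rng = np.random.default_rng(12)
        start = st_.tf_pos.copy()
        dt, steps = 0.01, 10_000
        kT, gamma = 1.0, 1.0
        times, msd = [], []
        for chunk in range(10):
            langevin_step(st_, table_positive, ff, dt=dt, gamma=gamma, kT=kT,
                          rng=rng, n_steps=steps // 10)
            times.append(st_.time)
            from chromsilence.core import min_image

            disp = min_image(st_.tf_pos - start, st_.box_length)
            msd.append(np.mean(np.sum(disp ** 2, axis=1)))
        # fit the diffusive regime (t >> 1/gamma); slope = 6 D = 6 kT/gamma
        t = np.asarray(times)[3:]
        y = np.asarray(msd)[3:]
        slope = np.polyfit(t, y, 1)[0]
        assert slope == pytest.approx(6.0 * kT / gamma, rel=0.10)

    def test_harmonic_dimer_samples_boltzmann(self, ff, table_positive):
        from scipy.stats import kstest

        ffh = ForceField(bond_type="harmonic", bond_k=3.0, bond_r0=1.5)
        st_ = build_system(2, [], 0, 0, 0, 30.0, seed=1, ff=ffh)
        rng = np.random.default_rng(7)
        # equilibrate, then sample the bond length every 20 steps
        langevin_step(st_, table_positive, ffh, 0.01, 1.0, 1.0, rng, n_steps=2000)
        samples = []
        for _ in range(10_000):
            langevin_step(st_, table_positive, ffh, 0.01, 1.0, 1.0, rng, n_steps=20)
            samples.append(
                float(min_image_distance(st_.pos[0], st_.pos[1], st_.box_length))
            )
        # radial Boltzmann CDF of the actual bond + steric potential
        from chromsilence import bond_energy, pair_energy

        r_grid = np.linspace(0.3, 4.0, 2000)
        u = bond_energy(r_grid, ffh) + pair_energy(r_grid, Affinity.STERIC, ffh)
        w = r_grid ** 2 * np.exp(-u)
        cdf = np.cumsum(w)
        cdf /= cdf[-1]

        def target_cdf(x):
            return np.interp(x, r_grid, cdf)

        stat = kstest(samples, target_cdf).statistic
        assert stat < 0.05

    def test_blowup_raises_integration_error(self, ff, table_positive):
        st_ = build_system(5, [], 0, 0, 0, 20.0, seed=0, ff=ff)
        st_.pos[2] = st_.pos[1] + [0.05, 0.0, 0.0]  # deep overlap
        rng = np.random.default_rng(0)
        with pytest.raises(IntegrationError):
            for _ in range(50):
                langevin_step(st_, table_positive, ff, dt=0.05, gamma=0.1,
                              kT=5.0, rng=rng, n_steps=100)

    def test_trajectory_deterministic_given_seed(self, ff, table_positive):
        results = []
        for _ in range(2):
            st_ = interacting_system(ff, seed=9)
            relax(st_, table_positive, ff)
            rng = np.random.default_rng(123)
            langevin_step(st_, table_positive, ff, 0.01, 1.0, 1.0, rng, n_steps=500)
            results.append(st_.pos.copy())
        assert np.array_equal(results[0], results[1])


class TestPolymerStatistics:
    def test_persistence_increases_with_bending_stiffness(self, table_positive):
        """Bond-vector correlation decays more slowly for stiffer chains."""
        corr = {}
        for kb in (0.0, 6.0):
            ffk = ForceField(bending_kb=kb)
            st_ = build_system(60, [], 0, 0, 0, 40.0, seed=2, ff=ffk)
            relax(st_, table_positive, ffk)
            rng = np.random.default_rng(4)
            acc = []
            for _ in range(40):
                langevin_step(st_, table_positive, ffk, 0.01, 1.0, 1.0, rng,
                              n_steps=200)
                from chromsilence.core import min_image

                b = min_image(np.diff(st_.bead_pos, axis=0), st_.box_length)
                b /= np.linalg.norm(b, axis=1, keepdims=True)
                acc.append(np.mean(np.sum(b[:-3] * b[3:], axis=1)))
            corr[kb] = np.mean(acc[20:])
        assert corr[6.0] > corr[0.0] + 0.1
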