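"""Microscopic field computation and signal simulation."""

import numpy as np
import pytest

from microrelax import (
    DEFAULT_CONSTANTS,
    FrequencyField,
    MCConfig,
    SusceptibilityVolume,
    dipole_field,
    generate_inclusion_map,
    mc_signal,
    sdr_signal,
    simulate_and_fit,
)
from microrelax.microstructure import omega2_forward
from microrelax.simulator import load_susceptibility_volume

TE16 = 1.25e-3 + 1.2e-3 * np.arange(16)
TE16_SNAPPED = np.round(TE16 / 1e-4) * 1e-4  # on the default MC step grid


@pytest.fixture(scope="module")
def sphere_map():
    """Random non-overlapping spheres at zeta ~ 0.03 (sparse suspension)."""
    return generate_inclusion_map((96, 96, 96), voxel_size=1.0,
                                  cluster_radius=6.0, zeta=0.03,
                                  chi_inclusion=1.0, seed=3)


@pytest.fixture(scope="module")
def sphere_field(sphere_map):
    return dipole_field(sphere_map)


@pytest.fixture(scope="module")
def small_sphere_field():
    """Small inclusions (r = 2 um): diffusion-narrowing territory."""
    vol = generate_inclusion_map((64, 64, 64), voxel_size=1.0,
                                 cluster_radius=2.0, zeta=0.03,
                                 chi_inclusion=1.0, seed=2)
    return dipole_field(vol)


class TestInclusionMap:
    def test_zero_zeta_uniform_background(self):
        vol = generate_inclusion_map((16, 16, 16), 2.0, 5.0, 0.0,
                                     chi_inclusion=1.0, chi_background=0.2)
        assert np.all(vol.chi == 0.2)
        assert vol.provenance["n_spheres"] == 0

    def test_realized_zeta_within_10pct(self, sphere_map):
        assert sphere_map.provenance["zeta_realized"] == pytest.approx(
            0.03, rel=0.10)

    def test_same_seed_identical(self):
        a = generate_inclusion_map((32, 32, 32), 2.0, 6.0, 0.02,
                                   chi_inclusion=1.0, seed=9)
        b = generate_inclusion_map((32, 32, 32), 2.0, 6.0, 0.02,
                                   chi_inclusion=1.0, seed=9)
        assert np.array_equal(a.chi, b.chi)

    def test_unreachable_zeta_reports_achieved_fraction(self):
        with pytest.raises(RuntimeError, match="achieved fraction"):
            generate_inclusion_map((20, 20, 20), 2.0, 10.0, 0.5,
                                   chi_inclusion=1.0, seed=0,
                                   max_attempts=200)

    def test_npz_loader_round_trip(self, tmp_path):
        vol = generate_inclusion_map((16, 16, 16), 2.0, 3.0, 0.05,
                                     chi_inclusion=1.0, seed=4)
        p = tmp_path / "chi.npz"
        np.savez(p, chi=vol.chi, voxel_size=vol.voxel_size)
        back = load_susceptibility_volume(str(p))
        assert np.array_equal(back.chi, vol.chi)
        assert back.voxel_size == vol.voxel_size


class TestDipoleField:
    def test_uniform_chi_zero_field(self):
        vol = SusceptibilityVolume(chi=np.full((16, 16, 16), 3.0),
                                   voxel_size=2.0)
        fld = dipole_field(vol)
        assert np.allclose(fld.omega, 0.0, atol=1e-8)

    def test_isolated_sphere_matches_analytic_dipole(self):
        """External field of a uniform sphere: (dchi/3) gamma B0 (R/r)^3
        (3 cos^2 - 1), checked away from the sphere and the grid edge."""
        n, pitch, R = 96, 1.0, 8.0
        c = (np.arange(n) + 0.5) * pitch
        X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
        ctr = n * pitch / 2
        r2 = (X - ctr) ** 2 + (Y - ctr) ** 2 + (Z - ctr) ** 2
        chi = np.where(r2 <= R**2, 1.0, 0.0)
        fld = dipole_field(SusceptibilityVolume(chi=chi, voxel_size=pitch))
        gb = DEFAULT_CONSTANTS.gamma_b0 * 1e-6
        mid = n // 2
        for di, dj, dk in [(0, 0, 16), (16, 0, 0), (12, 12, 0), (0, 10, 10)]:
            i, j, k = mid + di, mid + dj, mid + dk
            pos = np.array([c[i] - ctr, c[j] - ctr, c[k] - ctr])
            r = np.linalg.norm(pos)
            analytic = gb / 3 * (R / r) ** 3 * (3 * (pos[2] / r) ** 2 - 1)
            assert fld.omega[i, j, k] == pytest.approx(analytic, rel=0.05)

    def test_field_variance_matches_suspension_formula(self, sphere_map,
                                                       sphere_field):
        """Key cross-module consistency: var(omega) of a random sphere map
        equals (4/45) zeta (1-zeta) (gamma B0 dchi)^2 within 15%."""
        zeta = sphere_map.provenance["zeta_realized"]
        predicted = float(omega2_forward(zeta, 1.0))
        assert sphere_field.variance == pytest.approx(predicted, rel=0.15)

    def test_zero_mean_convention(self, sphere_field):
        assert abs(sphere_field.omega.mean()) < 1e-8 * sphere_field.width

    def test_nonfinite_chi_rejected(self):
        chi = np.zeros((16, 16, 16))
        chi[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            SusceptibilityVolume(chi=chi, voxel_size=1.0)


class TestSDRSignal:
    def _field(self, omega):
        return FrequencyField(omega=omega, voxel_size=1.0,
                              B0=DEFAULT_CONSTANTS.B0)

    def test_zero_field_unit_signal(self):
        fld = self._field(np.zeros((8, 8, 8)))
        assert np.allclose(sdr_signal(fld, TE16), 1.0)

    def test_two_valued_field_cosine(self):
        omega0 = 150.0
        omega = np.empty((8, 8, 8))
        omega[:4], omega[4:] = omega0, -omega0
        s = sdr_signal(self._field(omega), TE16)
        assert np.allclose(s, np.abs(np.cos(omega0 * TE16)), atol=1e-12)

    def test_lorentzian_field_exponential_decay(self, rng):
        a = 40.0  # Lorentzian scale -> exp(-a TE)
        omega = a * np.tan(np.pi * (rng.uniform(0, 1, 32**3) - 0.5))
        s = sdr_signal(self._field(omega.reshape(32, 32, 32)), TE16)
        assert np.allclose(s, np.exp(-a * TE16), rtol=0.05)


class TestMCSignal:
    def test_zero_field_unit_signal(self):
        fld = FrequencyField(omega=np.zeros((16, 16, 16)), voxel_size=1.0,
                             B0=3.0)
        te, s = mc_signal(fld, MCConfig(n_walkers=500, seed=1),
                          echo_times=TE16_SNAPPED)
        assert np.allclose(s, 1.0)

    def test_signal_bounded_and_normalized(self, small_sphere_field):
        te, s = mc_signal(small_sphere_field,
                          MCConfig(n_walkers=5000, seed=5, te_max=30e-3))
        assert np.all(s <= 1.0 + 1e-12)
        assert np.all(s > 0.0)

    def test_diffusionless_limit_matches_sdr(self, sphere_field):
        cfg = MCConfig(D=1e-6, n_walkers=20_000, seed=7)
        te, s, sem = mc_signal(sphere_field, cfg, echo_times=TE16_SNAPPED,
                               return_sem=True)
        s_sdr = sdr_signal(sphere_field, te)
        assert np.all(np.abs(s - s_sdr) <= 3.0 * sem + 1e-12)

    def test_three_seeds_agree_within_sem(self, sphere_field):
        runs = [mc_signal(sphere_field,
                          MCConfig(n_walkers=10_000, seed=s),
                          echo_times=TE16_SNAPPED, return_sem=True)
                for s in (11, 12, 13)]
        for i in range(3):
            for j in range(i + 1, 3):
                _, si, semi = runs[i]
                _, sj, semj = runs[j]
                comb = np.hypot(semi, semj)
                assert np.all(np.abs(si - sj) <= 3.0 * comb + 1e-12)

    def test_sem_scales_as_sqrt_n(self, small_sphere_field):
        _, _, sem1 = mc_signal(small_sphere_field,
                               MCConfig(n_walkers=4000, seed=3),
                               echo_times=TE16_SNAPPED, return_sem=True)
        _, _, sem4 = mc_signal(small_sphere_field,
                               MCConfig(n_walkers=16_000, seed=3),
                               echo_times=TE16_SNAPPED, return_sem=True)
        ratio = np.median(sem1 / sem4)
        assert 1.6 < ratio < 2.4  # 4x walkers -> ~2x smaller SEM

    def test_motional_narrowing_long_te_rate(self, small_sphere_field):
        """Diffusion averages the field of small inclusions: the MC decay
        rate at long TE stays below the static-dephasing rate."""
        cfg = MCConfig(D=1.0, dt=1e-4, n_walkers=20_000, seed=11,
                       te_max=50e-3)
        te, s = mc_signal(small_sphere_field, cfg)
        s_sdr = sdr_signal(small_sphere_field, te)
        m = te > 20e-3
        rate_mc = -np.polyfit(te[m], np.log(s[m]), 1)[0]
        rate_sdr = -np.polyfit(te[m], np.log(s_sdr[m]), 1)[0]
        assert rate_mc < rate_sdr

    def test_echo_snap_warning(self):
        fld = FrequencyField(omega=np.zeros((16, 16, 16)), voxel_size=1.0,
                             B0=3.0)
        with pytest.warns(UserWarning, match="snapped"):
            mc_signal(fld, MCConfig(n_walkers=100, seed=0),
                      echo_times=np.array([1.25e-3]))


class TestSimulateAndFit:
    def test_pure_exponential_rates_agree(self):
        te = np.arange(1, 41) * 1.25e-3
        sig = np.exp(-25.0 * te)
        fits = simulate_and_fit(te, sig, r2_nano=0.0)
        r_exp = fits["exponential"].params.R2_star
        r_pade = fits["pade"].params.R2_micro
        assert r_exp == pytest.approx(25.0, rel=0.01)
        assert r_pade == pytest.approx(r_exp, rel=0.01)

    def test_diffusion_in_smooth_gaussian_field_recovers_variance(self, rng):
        """Diffusion through a smooth Gaussian random field produces an
        AW-like decay (Gaussian onset, exponential tail); the Pade fit
        recovers the field variance as Omega2 within 20% (the short-time
        curvature is <omega^2> by the phase-accumulation expansion)."""
        from scipy.ndimage import gaussian_filter

        w = gaussian_filter(rng.normal(0, 1, (48, 48, 48)), 2.0, mode="wrap")
        w = (w - w.mean()) / w.std() * 100.0  # variance 1e4 rad^2/s^2
        fld = FrequencyField(omega=w, voxel_size=1.0, B0=3.0)
        te = np.round(np.arange(1, 17) * 1.25e-3 / 1e-4) * 1e-4
        te, s = mc_signal(fld, MCConfig(D=1.0, n_walkers=20_000, seed=5),
                          echo_times=te)
        fits = simulate_and_fit(te, s, r2_nano=0.0)
        assert fits["pade"].params.Omega2 == pytest.approx(fld.variance,
                                                           rel=0.20)

    def test_sparse_sphere_decay_pade_beats_exponential(self, sphere_field):
        """Judged on all echoes, the Pade fit captures the short-TE
        Gaussian phase that the extrapolated exponential tail fit misses."""
        te = np.arange(1, 41) * 1.25e-3
        s = sdr_signal(sphere_field, te)
        fits = simulate_and_fit(te, s, r2_nano=0.0)
        assert fits["mse_pade"] <= fits["mse_exponential_all_echoes"]

    def test_nano_rate_steepens_decay(self, sphere_field):
        te = np.arange(1, 17) * 1.25e-3
        s = sdr_signal(sphere_field, te)
        f0 = simulate_and_fit(te, s, r2_nano=0.0)
        f10 = simulate_and_fit(te, s, r2_nano=10.0)
        # R2_nano enters multiplicatively; the micro fit is unchanged
        assert f10["pade"].params.R2_micro == pytest.approx(
            f0["pade"].params.R2_micro, rel=0.02)
        assert f10["exponential"].params.R2_star == pytest.approx(
            f0["exponential"].params.R2_star + 10.0, rel=0.02)
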