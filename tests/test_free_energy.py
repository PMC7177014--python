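"""Umbrella windows, WHAM unbiasing, sensing force and conversions."""
import numpy as np
import pytest

from memthin import (
    UmbrellaWindow,
    ZoneGeometry,
    convert_force,
    plan_windows,
    reparameterize_thickness,
    sensing_force,
    to_kbt,
    wham,
)
from memthin.fixtures import REFERENCE_SIGMOID, umbrella_harmonic
from memthin.free_energy import FreeEnergyProfile
from memthin.thickness import SigmoidFit
from memthin.units import KB


class TestPlanWindows:
    def test_reference_ladder_has_111_windows(self):
        centers = plan_windows(27.5, 5.5, 0.2)
        assert centers.size == 111
        assert centers[0] == 27.5
        assert centers[-1] == pytest.approx(5.5)
        np.testing.assert_allclose(np.diff(centers), -0.2)

    @pytest.mark.parametrize(
        "a,b,sp,expect",
        [(0.0, 1.0, 0.5, [0.0, 0.5, 1.0]), (5.0, 5.2, 0.2, [5.0, 5.2])],
    )
    def test_small_ladders(self, a, b, sp, expect):
        np.testing.assert_allclose(plan_windows(a, b, sp), expect)

    def test_non_commensurate_rejected(self):
        with pytest.raises(ValueError, match="commensurate"):
            plan_windows(0.0, 1.0, 0.3)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            plan_windows(1.0, 1.0, 0.1)


class TestWham:
    def test_harmonic_landscape_recovered(self):
        """Boltzmann-exact samples from a known harmonic landscape: WHAM
        returns it within 0.2 kJ/mol RMS."""
        windows, truth = umbrella_harmonic(c=5.0, x_min=8.0, n_samples=10000,
                                           seed=4)
        prof = wham(windows, T=truth["T"], bin_width=0.05)
        m = prof.support > 50
        f_true = 0.5 * truth["c"] * (prof.x[m] - truth["x_min"]) ** 2
        diff = prof.F[m] - f_true
        diff -= diff.mean()  # profiles are defined up to a constant
        assert np.sqrt(np.mean(diff**2)) < 0.2

    def test_curvature_recovered_within_5pct(self):
        windows, truth = umbrella_harmonic(c=8.0, x_min=5.0, n_samples=10000,
                                           seed=11)
        prof = wham(windows, T=truth["T"], bin_width=0.05)
        m = prof.support > 100
        coef = np.polyfit(prof.x[m], prof.F[m], 2)
        assert 2 * coef[0] == pytest.approx(truth["c"], rel=0.05)

    def test_single_unbiased_window_is_log_histogram(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(3.0, 0.4, 20000)
        w = UmbrellaWindow(center=3.0, k_u=1e-12, samples=samples)
        prof = wham([w], T=310.0, bin_width=0.1)
        counts, edges = np.histogram(samples, bins=np.append(prof.x - 0.05,
                                                             prof.x[-1] + 0.05))
        m = counts > 0
        expect = -KB * 310.0 * np.log(counts[m] / counts.sum())
        expect -= expect.min()
        np.testing.assert_allclose(prof.F[m], expect, atol=1e-6)

    def test_invariant_under_sample_duplication(self):
        windows, truth = umbrella_harmonic(n_samples=2000, seed=3)
        prof1 = wham(windows, T=truth["T"])
        doubled = [
            UmbrellaWindow(w.center, w.k_u, np.concatenate([w.samples] * 2))
            for w in windows
        ]
        prof2 = wham(doubled, T=truth["T"])
        m = prof1.support > 0
        np.testing.assert_allclose(prof1.F[m], prof2.F[m], atol=1e-9)

    def test_translation_invariance(self):
        """Shifting every center and sample by a constant translates F."""
        windows, truth = umbrella_harmonic(n_samples=4000, seed=6)
        prof1 = wham(windows, T=truth["T"], bin_width=0.05)
        shift = 2.0
        shifted = [
            UmbrellaWindow(w.center + shift, w.k_u, w.samples + shift)
            for w in windows
        ]
        prof2 = wham(shifted, T=truth["T"],
                     grid=np.append(prof1.x - 0.025, prof1.x[-1] + 0.025) + shift)
        m = (prof1.support > 0) & (prof2.support > 0)
        np.testing.assert_allclose(prof1.F[m], prof2.F[m], atol=1e-9)

    def test_min_anchored_at_zero(self):
        windows, truth = umbrella_harmonic(n_samples=3000, seed=8)
        prof = wham(windows, T=truth["T"])
        assert np.nanmin(prof.F) == pytest.approx(0.0, abs=1e-12)


class TestSensingForce:
    def _geom(self):
        return ZoneGeometry(X_box=55.0, A_thin=10.0, A_buffer=10.0)

    def _profile_from_slope(self, slope, geom, noise=0.0, seed=0):
        """F increasing away from the thin center at the given rate."""
        x = np.arange(0.05, geom.X_box, 0.1)
        delta = np.abs(x - geom.x_c)
        F = slope * delta
        if noise:
            F = F + np.random.default_rng(seed).normal(0, noise, x.size)
        return FreeEnergyProfile(x=x, F=F - F.min(),
                                 support=np.full(x.size, 100))

    def test_reference_conversion_pair(self):
        """A linear profile of slope 6.89 kJ/mol/nm reads 11.44 pN."""
        geom = self._geom()
        prof = self._profile_from_slope(6.89, geom)
        sf = sensing_force(prof, geom)
        assert sf.slope_kj_mol_nm == pytest.approx(6.89, abs=1e-9)
        assert sf.force_pn == pytest.approx(11.44, abs=5e-3)

    def test_flat_profile_zero_force(self):
        geom = self._geom()
        prof = self._profile_from_slope(0.0, geom)
        sf = sensing_force(prof, geom)
        assert sf.slope_kj_mol_nm == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_within_2se(self):
        geom = self._geom()
        prof = self._profile_from_slope(4.0, geom, noise=0.5, seed=3)
        sf = sensing_force(prof, geom)
        assert abs(sf.slope_kj_mol_nm - 4.0) < 2 * sf.slope_se + 1e-9

    def test_too_few_points_rejected(self):
        geom = self._geom()
        x = np.array([27.0, 27.5, 28.0])
        prof = FreeEnergyProfile(x=x, F=np.zeros(3), support=np.ones(3))
        with pytest.raises(ValueError):
            sensing_force(prof, geom)


class TestConversions:
    def test_reference_force_pair(self):
        assert round(convert_force(6.89), 2) == 11.44

    def test_zero(self):
        assert convert_force(0.0) == 0.0

    def test_unit_force(self):
        assert convert_force(1.0) == pytest.approx(1.6605, abs=1e-4)

    def test_reference_kbt(self):
        assert to_kbt(25.0, 310.0) == pytest.approx(9.70, abs=0.005)
        assert round(to_kbt(25.0, 310.0)) == 10

    def test_kbt_identity(self):
        assert to_kbt(KB * 310.0, 310.0) == pytest.approx(1.0, rel=1e-12)
        assert to_kbt(2.5776, 310.0) == pytest.approx(1.000, abs=5e-4)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            to_kbt(1.0, 0.0)


class TestReparameterizeThickness:
    def _fit(self):
        p = REFERENCE_SIGMOID
        return SigmoidFit(L=p["L"], kappa=p["kappa"], x0=p["x0"], b=p["b"],
                          cov=np.zeros((4, 4)), rms=0.0)

    def _linear_profile(self, geom, slope=5.0):
        x = np.arange(0.05, geom.X_box, 0.05)
        F = slope * np.abs(x - geom.x_c)
        return FreeEnergyProfile(x=x, F=F - F.min(),
                                 support=np.full(x.size, 10))

    def test_endpoint_differences_preserved(self):
        geom = ZoneGeometry(X_box=55.0, A_thin=10.0, A_buffer=10.0)
        fit = self._fit()
        prof = self._linear_profile(geom)
        a, Fa = reparameterize_thickness(prof, fit, geom, T=310.0)
        # F(a) spans the same range as F(x) across the buffer zone
        dF_x = 5.0 * geom.A_buffer
        assert Fa.max() - Fa.min() == pytest.approx(dF_x, rel=0.02)
        # monotone: thin (small a) side carries the lower free energy
        assert Fa[0] < Fa[-1]
        assert np.all(np.diff(Fa) > -1e-9)

    def test_identity_sigmoid_rescales(self):
        geom = ZoneGeometry(X_box=55.0, A_thin=10.0, A_buffer=10.0)
        # a nearly linear 'sigmoid' over the buffer: shallow kappa
        fit = SigmoidFit(L=-1.0, kappa=-0.01, x0=5.0, b=4.0,
                         cov=np.zeros((4, 4)), rms=0.0)
        prof = self._linear_profile(geom)
        a, Fa = reparameterize_thickness(prof, fit, geom, T=310.0)
        # nearly-affine map => F(a) nearly linear in a
        coef = np.polyfit(a, Fa, 1)
        resid = Fa - np.polyval(coef, a)
        assert np.abs(resid).max() < 0.02 * (Fa.max() - Fa.min())

    def test_jacobian_correction_on_flat_profile(self):
        geom = ZoneGeometry(X_box=55.0, A_thin=10.0, A_buffer=10.0)
        fit = self._fit()
        x = np.arange(0.05, geom.X_box, 0.05)
        prof = FreeEnergyProfile(x=x, F=np.zeros(x.size),
                                 support=np.full(x.size, 10))
        a, Fa = reparameterize_thickness(prof, fit, geom, T=310.0,
                                         jacobian_correction=True)
        # closed form: -kBT ln|dx/da| + const, compared away from the
        # saturated asymptote where the map's slope diverges
        m = np.abs(a - fit.b) > 1e-9
        u = a[m] - fit.b
        dxda = fit.L / (fit.kappa * u * (fit.L - u))
        expect = -KB * 310.0 * np.log(np.abs(dxda))
        offset = (Fa[m] - expect).mean()
        np.testing.assert_allclose(Fa[m], expect + offset, atol=1e-9)

    def test_degenerate_fit_rejected(self):
        geom = ZoneGeometry(X_box=55.0, A_thin=10.0, A_buffer=10.0)
        fit = SigmoidFit(L=0.0, kappa=0.0, x0=0.0, b=4.0,
                         cov=np.zeros((4, 4)), rms=0.0, degenerate=True)
        prof = self._linear_profile(geom)
        with pytest.raises(ValueError):
            reparameterize_thickness(prof, fit, geom)
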