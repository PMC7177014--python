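"""Thickness profiling, symmetrization and the sigmoid fit."""
import numpy as np
import pytest

from memthin import ZoneGeometry, fit_sigmoid, sigmoid, symmetrize, thickness_by_bin
from memthin.fixtures import REFERENCE_SIGMOID, flat_membrane, sigmoid_membrane
from memthin.thickness import ThicknessProfile, buffer_zone_points, fit_profile_sigmoid

REF = REFERENCE_SIGMOID  # L=-1.22, kappa=-19.14, x0=1.11, b=4.08 (nm)


class TestThicknessByBin:
    def test_flat_leaflets_exact(self, ref_geom):
        traj, truth = flat_membrane(thickness=4.0, geom=ref_geom, n_frames=3)
        prof = thickness_by_bin(traj, ref_geom, n_bins=55)
        ok = prof.defined
        np.testing.assert_allclose(prof.mean_thickness[ok], 4.0, atol=1e-9)
        np.testing.assert_allclose(prof.std_thickness[ok], 0.0, atol=1e-9)

    def test_single_frame_single_bin_equals_hand_average(self, ref_geom):
        traj, _ = flat_membrane(thickness=4.0, geom=ref_geom, noise=0.3,
                                n_frames=1, seed=7)
        prof = thickness_by_bin(traj, ref_geom, n_bins=1)
        x, z, leaf = traj.head_xz(0)
        expected = z[leaf > 0].mean() - z[leaf < 0].mean()
        assert prof.mean_thickness[0] == pytest.approx(expected, abs=1e-12)

    def test_sigmoid_membrane_recovers_profile(self, ref_geom):
        traj, _ = sigmoid_membrane(geom=ref_geom, n_frames=12, seed=3)
        n_bins = 110
        prof = thickness_by_bin(traj, ref_geom, n_bins=n_bins)
        # oracle: analytic average of a(x) over each bin (fine subsampling),
        # since bins spanning the steep step differ from their center value
        w = ref_geom.X_box / n_bins
        sub = np.linspace(-0.5, 0.5, 51) * w
        xs = prof.bin_centers[:, None] + sub[None, :]
        xi = np.abs(xs - ref_geom.x_c) - ref_geom.thin_half
        expect = sigmoid(xi, REF["L"], REF["kappa"], REF["x0"], REF["b"]).mean(axis=1)
        ok = prof.defined
        assert np.nanmax(np.abs(prof.mean_thickness[ok] - expect[ok])) < 0.08

    def test_empty_bins_flagged(self, ref_geom):
        traj, _ = flat_membrane(thickness=4.0, geom=ref_geom, n_frames=1)
        # strip all heads from the first tenth of the box
        keep = traj.frames[0][:, 0] > ref_geom.X_box / 10
        traj.frames = traj.frames[:, keep]
        traj.is_head = traj.is_head[keep]
        traj.is_tail = traj.is_tail[keep]
        traj.leaflet = traj.leaflet[keep]
        traj.lipid_id = traj.lipid_id[keep]
        traj.radii = traj.radii[keep]
        prof = thickness_by_bin(traj, ref_geom, n_bins=20)
        assert not prof.defined[0]
        assert np.isnan(prof.mean_thickness[0])


class TestSymmetrize:
    def _profile(self, values, geom):
        n = len(values)
        w = geom.X_box / n
        return ThicknessProfile(
            bin_centers=(np.arange(n) + 0.5) * w,
            mean_thickness=np.asarray(values, float),
            std_thickness=np.zeros(n),
            n_samples=np.ones(n, dtype=np.int64),
        )

    def test_symmetric_profile_unchanged(self, ref_geom):
        n = 20
        base = np.concatenate([np.arange(10)[::-1], np.arange(10)])
        prof = self._profile(base + 3.0, ref_geom)
        half = symmetrize(prof, ref_geom)
        np.testing.assert_allclose(half.mean_thickness, np.arange(10) + 3.0)

    def test_antisymmetric_noise_cancels(self, ref_geom):
        base = np.full(20, 4.0)
        noise = np.concatenate([np.linspace(0.3, 0.1, 10)[::-1] * -1,
                                np.linspace(0.3, 0.1, 10)[::-1]])[::-1]
        # construct mirror-odd perturbation around the center
        pert = np.zeros(20)
        pert[10:] = np.linspace(0.5, 0.1, 10)
        pert[:10] = -pert[10:][::-1]
        half = symmetrize(self._profile(base + pert, ref_geom), ref_geom)
        np.testing.assert_allclose(half.mean_thickness, 4.0, atol=1e-12)

    def test_matches_bruteforce_pairwise_mean(self, ref_geom, rng):
        vals = rng.normal(4.0, 0.3, 30)
        prof = self._profile(vals, ref_geom)
        half = symmetrize(prof, ref_geom)
        n = 30
        expect = 0.5 * (vals[n // 2:] + vals[: n // 2][::-1])
        np.testing.assert_allclose(half.mean_thickness, expect, atol=1e-12)
        assert half.bin_centers.size == (n + 1) // 2


class TestFitSigmoid:
    def test_noiseless_recovery_exact(self):
        xi = np.linspace(0.0, 10.0, 120)
        y = sigmoid(xi, REF["L"], REF["kappa"], REF["x0"], REF["b"])
        fit = fit_sigmoid(xi, y, A_buffer=10.0)
        assert fit.L == pytest.approx(REF["L"], abs=1e-6)
        assert fit.kappa == pytest.approx(REF["kappa"], abs=1e-4)
        assert fit.x0 == pytest.approx(REF["x0"], abs=1e-6)
        assert fit.b == pytest.approx(REF["b"], abs=1e-6)

    def test_midpoint_value(self):
        """At the midpoint the sigmoid reads b + L/2 = 3.47 nm."""
        mid = sigmoid(REF["x0"], REF["L"], REF["kappa"], REF["x0"], REF["b"])
        assert mid == pytest.approx(REF["b"] + REF["L"] / 2, abs=1e-12)
        assert mid == pytest.approx(3.47, abs=1e-9)

    def test_flat_profile_degenerate(self):
        xi = np.linspace(0, 10, 50)
        fit = fit_sigmoid(xi, np.full(50, 4.0), A_buffer=10.0)
        assert fit.degenerate
        assert fit.L == 0.0
        assert fit.b == pytest.approx(4.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid(np.arange(5.0), np.arange(5.0))

    def test_parameter_recovery_under_noise(self):
        """All four parameters within 5% (median over 50 seeds) at
        sigma = 0.05 nm on 100 buffer-zone samples."""
        xi = np.linspace(0.0, 10.0, 100)
        clean = sigmoid(xi, REF["L"], REF["kappa"], REF["x0"], REF["b"])
        ests = {"L": [], "kappa": [], "x0": [], "b": []}
        for seed in range(50):
            rng = np.random.default_rng(seed)
            fit = fit_sigmoid(xi, clean + rng.normal(0, 0.05, xi.size),
                              A_buffer=10.0)
            for k in ests:
                ests[k].append(getattr(fit, k))
        for k, truth in (("L", REF["L"]), ("kappa", REF["kappa"]),
                         ("x0", REF["x0"]), ("b", REF["b"])):
            med = float(np.median(ests[k]))
            assert abs(med - truth) / abs(truth) < 0.05, (k, med, truth)

    def test_fit_idempotence(self):
        xi = np.linspace(0, 10, 100)
        rng = np.random.default_rng(1)
        y = sigmoid(xi, REF["L"], REF["kappa"], REF["x0"], REF["b"])
        y = y + rng.normal(0, 0.03, xi.size)
        fit1 = fit_sigmoid(xi, y, A_buffer=10.0)
        refit = fit_sigmoid(xi, fit1(xi), A_buffer=10.0)
        assert refit.L == pytest.approx(fit1.L, rel=1e-4)
        assert refit.b == pytest.approx(fit1.b, rel=1e-4)

    def test_asymptotes_match_zone_means(self, ref_geom):
        """Fitted b ~ normal-zone mean; b + L ~ thin-zone mean."""
        traj, _ = sigmoid_membrane(geom=ref_geom, noise=0.05, n_frames=8, seed=2)
        prof = thickness_by_bin(traj, ref_geom, n_bins=110)
        half = symmetrize(prof, ref_geom)
        fit = fit_profile_sigmoid(half, ref_geom)
        thin_m, thin_se = prof.zone_mean(ref_geom, "thin")
        norm_m, norm_se = prof.zone_mean(ref_geom, "normal")
        assert abs(fit.b - norm_m) < max(2 * norm_se, 0.05)
        assert abs(fit.thin_asymptote() - thin_m) < max(2 * thin_se, 0.05)
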