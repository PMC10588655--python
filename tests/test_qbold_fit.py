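import numpy as np
import pytest
from scipy import ndimage

from hemomap import (
    AseProtocol,
    ase_signal_stack,
    delta_omega,
    fit_volume,
    fit_voxel,
    group_average_map,
    oef_from_r2p_dbv,
    oef_map,
    physiological_exclusion,
    smooth_volume,
)
from hemomap.qbold_fit import ParameterMaps, ase_model_signal


class TestSmoothVolume:
    def test_sigma_zero_identity(self, rng):
        vol = rng.random((6, 6, 6))
        out = smooth_volume(vol, 0.0, (3, 3, 3))
        np.testing.assert_array_equal(out, vol)
        assert out is not vol

    def test_constant_preserved(self):
        vol = np.full((8, 8, 8), 7.0)
        out = smooth_volume(vol, 4.0, (3, 3, 3))
        np.testing.assert_allclose(out, 7.0, rtol=1e-12)

    def test_impulse_peak_matches_sampled_kernel(self):
        sigma_mm, vox = 4.0, 2.0
        sigma_v = sigma_mm / vox
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        out = smooth_volume(vol, sigma_mm, (vox, vox, vox))
        # independent construction of the sampled, normalized 1-D kernel
        radius = int(4.0 * sigma_v + 0.5)
        k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma_v) ** 2)
        k /= k.sum()
        assert out[10, 10, 10] == pytest.approx(k[radius] ** 3, rel=1e-10)
        assert out.sum() == pytest.approx(1.0, rel=1e-6)  # interior intensity conserved

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            smooth_volume(np.zeros((4, 4, 4)), -1.0, (3, 3, 3))
        with pytest.raises(ValueError):
            smooth_volume(np.zeros((4, 4, 4)), 2.0, (3, 0, 3))


class TestFitVoxel:
    def test_noise_free_recovery_at_prior_means(self, proto, const, priors):
        sig = ase_signal_stack(1.0, 0.2035, 0.036, const, proto)
        post = fit_voxel(sig, proto, const, priors)
        assert post.r2p == pytest.approx(2.6, rel=0.01)
        assert post.dbv == pytest.approx(0.036, rel=0.01)
        assert post.converged

    def test_noise_free_recovery_off_prior(self, proto, const, priors):
        true_dbv, true_oef = 0.06, 0.5
        sig = ase_signal_stack(1.2, true_oef, true_dbv, const, proto)
        post = fit_voxel(sig, proto, const, priors)
        true_r2p = true_dbv * delta_omega(true_oef, const, proto.b0)
        assert post.r2p == pytest.approx(true_r2p, rel=0.01)
        assert post.dbv == pytest.approx(true_dbv, rel=0.01)
        assert post.s0 == pytest.approx(1.2, rel=0.01)

    def test_degenerate_constant_signal(self, proto, const, priors):
        # no R2' decay at all: R2' -> 0+, DBV regularized to the prior mean
        sig = np.full(len(proto.taus), np.exp(-const.r2t * proto.te))
        post = fit_voxel(sig, proto, const, priors)
        assert 0 < post.r2p < 0.05
        assert post.dbv == pytest.approx(priors.mu0_dbv, rel=0.05)

    def test_invalid_signal_flagged_not_raised(self, proto, const, priors):
        post = fit_voxel(np.zeros(len(proto.taus)), proto, const, priors)
        assert not post.valid
        post = fit_voxel(np.full(len(proto.taus), np.nan), proto, const, priors)
        assert not post.valid

    def test_shape_mismatch_raises(self, proto, const, priors):
        with pytest.raises(ValueError):
            fit_voxel(np.ones(3), proto, const, priors)

    def test_requires_tau_zero(self, const, priors):
        proto = AseProtocol(taus=(0.016, 0.020, 0.024, 0.028))
        with pytest.raises(ValueError):
            fit_voxel(np.ones(4), proto, const, priors)

    def test_posterior_shrinkage_monotone(self, proto, const, priors):
        # on a fixed dataset the estimate approaches the prior means as the
        # (fixed) noise SD grows
        sig = ase_signal_stack(1.0, 0.45, 0.06, const, proto)
        dist = []
        for sd in (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0):
            p = fit_voxel(sig, proto, const, priors, noise_sd=sd)
            dist.append(abs(p.r2p - priors.mu0_r2p) / priors.sigma0_r2p
                        + abs(p.dbv - priors.mu0_dbv) / priors.sigma0_dbv)
        assert all(b <= a + 1e-9 for a, b in zip(dist, dist[1:]))
        p = fit_voxel(sig, proto, const, priors, noise_sd=50.0)
        assert p.r2p == pytest.approx(priors.mu0_r2p, rel=0.05)
        assert p.dbv == pytest.approx(priors.mu0_dbv, rel=0.05)

    def test_model_consistent_with_forward_stack(self, proto, const):
        oef, dbv = 0.37, 0.045
        r2p = dbv * delta_omega(oef, const, proto.b0)
        np.testing.assert_allclose(
            ase_model_signal(1.1, r2p, dbv, const, proto),
            ase_signal_stack(1.1, oef, dbv, const, proto),
            rtol=1e-10,
        )


class TestFitVolume:
    def _toy_data(self, const, proto, shape=(3, 2, 2)):
        oef = np.full(shape, 0.35)
        dbv = np.full(shape, 0.035)
        return ase_signal_stack(np.ones(shape), oef, dbv, const, proto)

    def test_three_voxel_bookkeeping(self, proto, const, priors):
        data = self._toy_data(const, proto)
        mask = np.zeros(data.shape[:-1], dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = mask[2, 0, 1] = True
        maps = fit_volume(data, mask, proto, const, priors, smooth_sigma_mm=0.0)
        assert int(maps.valid.sum()) == 3
        assert np.all(np.isnan(maps.r2p[~mask]))

    def test_tau_count_mismatch_raises(self, proto, const, priors):
        data = np.ones((3, 3, 3, 5))
        with pytest.raises(ValueError):
            fit_volume(data, np.ones((3, 3, 3), bool), proto, const, priors)

    def test_mask_shape_mismatch_raises(self, proto, const, priors):
        data = np.ones((3, 3, 3, len(proto.taus)))
        with pytest.raises(ValueError):
            fit_volume(data, np.ones((4, 3, 3), bool), proto, const, priors)

    def test_deterministic(self, proto, const, priors, rng):
        data = self._toy_data(const, proto) + rng.normal(0, 0.005, (3, 2, 2, len(proto.taus)))
        mask = np.ones(data.shape[:-1], dtype=bool)
        m1 = fit_volume(data, mask, proto, const, priors, smooth_sigma_mm=0.0)
        m2 = fit_volume(data, mask, proto, const, priors, smooth_sigma_mm=0.0)
        np.testing.assert_array_equal(m1.r2p, m2.r2p)
        np.testing.assert_array_equal(m1.dbv, m2.dbv)

    def test_noise_free_phantom_recovery(self, proto, const, priors):
        shape = (4, 4, 2)
        oef = np.full(shape, 0.4)
        dbv = np.full(shape, 0.05)
        data = ase_signal_stack(np.ones(shape), oef, dbv, const, proto)
        maps = fit_volume(data, np.ones(shape, bool), proto, const, priors,
                          smooth_sigma_mm=0.0)
        true_r2p = 0.05 * delta_omega(0.4, const, proto.b0)
        err = np.abs(maps.r2p - true_r2p) / true_r2p
        assert np.median(err) < 0.01


class TestOefMapAndExclusion:
    def _maps(self, r2p, dbv):
        r2p = np.asarray(r2p, float)
        return ParameterMaps(r2p=r2p, dbv=np.asarray(dbv, float),
                             valid=np.isfinite(r2p))

    def test_oef_reference_value(self, const):
        m = self._maps([[[2.6]]], [[[0.036]]])
        out = oef_map(m, const, 3.0)
        assert out.oef[0, 0, 0] == pytest.approx(0.2035, abs=5e-4)

    def test_oef_zero_and_linearity(self, const):
        m = self._maps([[[0.0, 2.6, 5.2]]], [[[0.036, 0.036, 0.036]]])
        out = oef_map(m, const, 3.0)
        assert out.oef[0, 0, 0] == 0.0
        assert out.oef[0, 0, 2] == pytest.approx(2 * out.oef[0, 0, 1], rel=1e-12)

    def test_dbv_zero_invalid(self, const):
        m = self._maps([[[2.6]]], [[[0.0]]])
        out = oef_map(m, const, 3.0)
        assert not out.valid[0, 0, 0]
        assert np.isnan(out.oef[0, 0, 0])

    def test_exclusion_thresholds(self, const):
        r2p = np.array([[[1.0, 2.0, 3.0]]])
        dbv = np.full((1, 1, 3), 0.05)
        m = oef_map(self._maps(r2p, dbv), const, 3.0)
        m.oef = np.array([[[0.5, 1.2, 0.8]]])
        out, report = physiological_exclusion(m)
        assert list(out.valid[0, 0]) == [True, False, True]
        assert report["excluded_pct"] == pytest.approx(100 / 3)

    def test_boundary_retained(self, const):
        # strictly greater than 20 s^-1 excluded, equality retained
        m = oef_map(self._maps([[[20.0, 20.0001]]], [[[0.2, 0.2]]]), const, 3.0)
        out, _ = physiological_exclusion(m)
        assert out.valid[0, 0, 0]
        assert not out.valid[0, 0, 1]

    def test_roundtrip_with_forward_relation(self, const):
        oef_true = 0.44
        dbv_true = 0.03
        r2p = dbv_true * delta_omega(oef_true, const, 3.0)
        out = oef_map(self._maps([[[r2p]]], [[[dbv_true]]]), const, 3.0)
        assert out.oef[0, 0, 0] == pytest.approx(oef_true, rel=1e-12)


class TestGroupAverageMap:
    def test_support_threshold_n8(self):
        shape = (2, 1, 1)
        vols = []
        for i in range(8):
            v = np.full(shape, np.nan)
            if i < 3:
                v[0, 0, 0] = 0.5          # only 3 of 8 valid -> excluded
            if i < 4:
                v[1, 0, 0] = [0.2, 0.3, 0.4, 0.5][i]  # 4 of 8 -> included
            vols.append(v)
        mean, support = group_average_map(vols)
        assert np.isnan(mean[0, 0, 0])
        assert support[0, 0, 0] == 3
        assert mean[1, 0, 0] == pytest.approx(0.35)
        assert support[1, 0, 0] == 4

    def test_single_subject(self):
        v = np.array([[[1.0, np.nan]]])
        mean, support = group_average_map([v])
        assert mean[0, 0, 0] == 1.0
        assert np.isnan(mean[0, 0, 1])

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            group_average_map([np.zeros((2, 2, 2)), np.zeros((3, 2, 2))])

    def test_empty(self):
        with pytest.raises(ValueError):
            group_average_map([])
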