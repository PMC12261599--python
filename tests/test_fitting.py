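"""B1 / DESPOT1 / DESPOT2 estimators and the volume driver."""

import dataclasses

import numpy as np
import pytest

from lc_relaxo.fitting import (
    STATUS_CLAMPED,
    STATUS_DEGENERATE,
    STATUS_FAILED,
    STATUS_OK,
    B1Map,
    fit_dam_b1,
    fit_despot1,
    fit_despot2,
    fit_volume,
    interpolate_b1,
)
from lc_relaxo.forward import bssfp_signal, spgr_signal, dam_signal_pair
from lc_relaxo.params import AcquisitionProtocol, TissueParameters
from lc_relaxo.phantom import generate_phantom, make_b1_field, simulate_acquisition


class TestDamB1:
    def test_unit_kappa_from_sqrt2_ratio(self):
        b1 = fit_dam_b1((np.array(np.sin(np.pi / 4)), np.array(1.0)), 45.0)
        assert b1.kappa == pytest.approx(1.0, rel=1e-6)
        assert b1.status == STATUS_OK

    def test_equal_signals_give_four_thirds(self):
        # S2/(2 S1) = 0.5 -> arccos = 60 deg -> kappa = 60/45
        b1 = fit_dam_b1((np.array(1.0), np.array(1.0)), 45.0)
        assert b1.kappa == pytest.approx(60.0 / 45.0, rel=1e-12)

    def test_clamped_and_undefined_voxels_flagged(self):
        s1 = np.array([1.0, 1.0, 0.0])
        s2 = np.array([np.sqrt(2.0), 2.5, 1.0])
        b1 = fit_dam_b1((s1, s2), 45.0)
        assert b1.status[0] == STATUS_OK
        assert b1.status[1] == STATUS_CLAMPED
        assert b1.kappa[1] == pytest.approx(0.0)  # ratio clamped to arccos(1)
        assert b1.status[2] == STATUS_DEGENERATE
        assert np.isnan(b1.kappa[2])

    def test_round_trip_through_forward_model(self):
        for kappa in (0.8, 1.0, 1.25):
            pair = dam_signal_pair(TissueParameters(m0=3.0, b1_scale=kappa))
            b1 = fit_dam_b1((np.asarray(pair[0]), np.asarray(pair[1])), 45.0)
            assert b1.kappa == pytest.approx(kappa, rel=1e-12)


class TestInterpolateB1:
    def test_constant_maps_to_constant(self):
        b1 = B1Map(kappa=np.full((4, 4, 4), 1.1), voxel_size=2.0)
        out = interpolate_b1(b1, (8, 8, 8), 1.0)
        np.testing.assert_allclose(out.kappa, 1.1, rtol=1e-14)
        assert out.interpolated

    def test_linear_ramp_exact_at_interior(self):
        ramp = make_b1_field((10, 6, 6), "ramp", ramp_axis=0, ramp_range=(0.9, 1.1))
        b1 = B1Map(kappa=ramp, voxel_size=2.0)
        out = interpolate_b1(b1, (20, 12, 12), 1.0)
        # interior target voxels sit strictly between source centers
        expected_x = 0.9 + (0.2 / 9) * (((np.arange(20) + 0.5) * 1.0) / 2.0 - 0.5)
        np.testing.assert_allclose(out.kappa[2:-2, 6, 6], expected_x[2:-2], rtol=1e-12)

    def test_identity_on_same_grid(self):
        rng = np.random.default_rng(0)
        field = 1.0 + 0.1 * rng.standard_normal((5, 5, 5))
        b1 = B1Map(kappa=field, voxel_size=1.0)
        out = interpolate_b1(b1, (5, 5, 5), 1.0)
        np.testing.assert_allclose(out.kappa, field, rtol=1e-12)


class TestDespot1:
    def _signals(self, protocol, t1=1000.0, m0=500.0, kappa=1.0, angles=None):
        angles = protocol.spgr_flip_angles if angles is None else angles
        p = TissueParameters(m0=m0, t1_single=t1, b1_scale=kappa)
        return np.array([float(spgr_signal(p, a, protocol.spgr_te_tr)) for a in angles])

    def test_round_trip(self, protocol):
        s = self._signals(protocol)[:, None]
        t1, m0, status, _ = fit_despot1(s, protocol.spgr_flip_angles, protocol.spgr_tr, 1.0)
        assert t1[0] == pytest.approx(1000.0, rel=1e-6)
        assert m0[0] == pytest.approx(500.0, rel=1e-6)
        assert status[0] == STATUS_OK

    def test_kappa_correction_matters(self, protocol):
        s = self._signals(protocol, kappa=0.8)[:, None]
        t1_ok, _, _, _ = fit_despot1(s, protocol.spgr_flip_angles, protocol.spgr_tr,
                                     np.full(1, 0.8))
        t1_biased, _, _, _ = fit_despot1(s, protocol.spgr_flip_angles, protocol.spgr_tr, 1.0)
        assert t1_ok[0] == pytest.approx(1000.0, rel=1e-6)
        # ignoring B1 biases T1 substantially — this is why DAM is acquired
        assert abs(t1_biased[0] - 1000.0) > 100.0

    def test_two_angles_exact(self, protocol):
        s = self._signals(protocol, angles=(4.0, 18.0))[:, None]
        t1, m0, status, _ = fit_despot1(s, (4.0, 18.0), protocol.spgr_tr, 1.0)
        assert t1[0] == pytest.approx(1000.0, rel=1e-9)
        assert m0[0] == pytest.approx(500.0, rel=1e-9)

    def test_zero_input_flagged_degenerate(self, protocol):
        s = np.zeros((len(protocol.spgr_flip_angles), 3))
        _, _, status, _ = fit_despot1(s, protocol.spgr_flip_angles, protocol.spgr_tr, 1.0)
        assert np.all(status == STATUS_DEGENERATE)

    def test_unbiased_under_gaussian_noise(self, protocol):
        """DESPOT1 T1 is unbiased within Monte-Carlo error at SNR ~200."""
        rng = np.random.default_rng(11)
        n = 10_000
        clean = self._signals(protocol)  # peak signal ~ 25 for M0=500
        sigma = clean.max() / 200.0
        noisy = clean[:, None] + rng.normal(0.0, sigma, size=(clean.size, n))
        t1, _, status, _ = fit_despot1(noisy, protocol.spgr_flip_angles,
                                       protocol.spgr_tr, 1.0)
        ok = status == STATUS_OK
        assert ok.mean() > 0.99
        mc_se = t1[ok].std(ddof=1) / np.sqrt(ok.sum())
        assert abs(t1[ok].mean() - 1000.0) < 4 * mc_se + 1.0


class TestDespot2:
    def _signals(self, protocol, t1=1000.0, t2=80.0, m0=500.0, kappa=1.0, df=0.0):
        p = TissueParameters(m0=m0, t1_single=t1, t2_single=t2,
                             off_resonance=df, b1_scale=kappa)
        return np.stack([
            np.array([float(bssfp_signal(p, a, dphi, protocol.bssfp_te_tr))
                      for a in protocol.bssfp_flip_angles])
            for dphi in protocol.bssfp_phase_increments
        ])

    @pytest.mark.parametrize("path", ["joint", "linearized"])
    def test_on_resonance_round_trip(self, protocol, path):
        s = self._signals(protocol)
        t2, m0, df, status, _ = fit_despot2(
            s, protocol.bssfp_flip_angles, protocol.bssfp_phase_increments,
            protocol.bssfp_te_tr, 1.0, 1000.0, path=path,
        )
        assert status == STATUS_OK
        assert t2 == pytest.approx(80.0, rel=1e-4)

    def test_off_resonance_joint_recovers_linearized_biased(self, protocol):
        s = self._signals(protocol, df=20.0)
        t2_j, _, df_j, st_j, _ = fit_despot2(
            s, protocol.bssfp_flip_angles, protocol.bssfp_phase_increments,
            protocol.bssfp_te_tr, 1.0, 1000.0, path="joint",
        )
        assert st_j == STATUS_OK
        assert t2_j == pytest.approx(80.0, rel=1e-3)
        assert abs(df_j) == pytest.approx(20.0, rel=1e-3)
        t2_l, _, _, st_l, _ = fit_despot2(
            s, protocol.bssfp_flip_angles, protocol.bssfp_phase_increments,
            protocol.bssfp_te_tr, 1.0, 1000.0, path="linearized",
        )
        # single-cycle linearized estimator ignores off-resonance: biased
        assert st_l != STATUS_OK or abs(t2_l - 80.0) / 80.0 > 1e-3

    def test_t2_equals_t1_gives_zero_linearized_slope(self, protocol):
        # E2 = E1 -> the pi-cycle regression slope (E1-E2)/(1-E1E2) is 0,
        # so the recovered T2 equals the supplied T1
        s = self._signals(protocol, t1=800.0, t2=800.0)
        t2, _, _, status, _ = fit_despot2(
            s, protocol.bssfp_flip_angles, protocol.bssfp_phase_increments,
            protocol.bssfp_te_tr, 1.0, 800.0, path="linearized",
        )
        assert status == STATUS_FAILED or t2 == pytest.approx(800.0, rel=1e-6)

    def test_round_trip_grid(self, protocol):
        """Noiseless inversion is exact across a (T1, T2, kappa) grid."""
        for t1 in (600.0, 1200.0, 2400.0):
            for t2 in (40.0, 90.0, 180.0):
                for kappa in (0.85, 1.0, 1.15):
                    s = self._signals(protocol, t1=t1, t2=t2, kappa=kappa)
                    est, _, _, status, _ = fit_despot2(
                        s, protocol.bssfp_flip_angles, protocol.bssfp_phase_increments,
                        protocol.bssfp_te_tr, kappa, t1,
                    )
                    assert status == STATUS_OK
                    assert est == pytest.approx(t2, rel=1e-4)


class TestFitVolume:
    def test_noiseless_phantom_round_trip(self, protocol, tiny_phantom_spec):
        params, mask = generate_phantom(tiny_phantom_spec)
        stacks = simulate_acquisition(params, protocol, seed=0)
        from lc_relaxo.fitting import fit_dam_b1

        b1 = fit_dam_b1(stacks.dam, protocol.dam_flip_angles[0])
        maps = fit_volume(stacks, protocol, b1)
        sel = np.isfinite(maps.r1)
        assert maps.ok_mask().all()
        np.testing.assert_allclose(1000.0 / maps.r1, params.t1_single, rtol=1e-3)
        np.testing.assert_allclose(1000.0 / maps.r2, params.t2_single, rtol=1e-3)

    def test_all_zero_volume_fails_cleanly(self, protocol):
        from lc_relaxo.phantom import SignalStackSet
        from lc_relaxo.topography import LcMask, slice_profile

        grid = (3, 3, 3)
        stacks = SignalStackSet(
            spgr=np.zeros((10, *grid)), bssfp=np.zeros((2, 10, *grid)),
            dam=np.zeros((2, *grid)), protocol=protocol, voxel_size=1.0,
        )
        b1 = B1Map(kappa=np.ones(grid))
        maps = fit_volume(stacks, protocol, b1)
        assert not maps.ok_mask().any()
        # downstream ROI means refuse to average zero usable voxels
        mask = LcMask(data=np.ones(grid, dtype=bool), voxel_size=1.0)
        profile = slice_profile(maps, mask)
        assert profile.table["r1"].isna().all()
        assert profile.missing_slices == [0, 1, 2]

    def test_masked_fit_matches_full_fit(self, protocol, tiny_phantom_spec):
        """Voxel independence: a 10-voxel mask reproduces the full run."""
        params, mask = generate_phantom(tiny_phantom_spec)
        stacks = simulate_acquisition(params, protocol.with_noise(0.3), seed=9)
        b1 = B1Map(kappa=np.ones(tiny_phantom_spec.grid_shape))
        full = fit_volume(stacks, protocol, b1, mask=mask.data)
        small = np.zeros_like(mask.data)
        idx = np.argwhere(mask.data)[:10]
        small[tuple(idx.T)] = True
        sub = fit_volume(stacks, protocol, b1, mask=small)
        np.testing.assert_array_equal(sub.r1[small], full.r1[small])
        np.testing.assert_array_equal(sub.r2[small], full.r2[small])

    def test_grid_mismatch_rejected(self, protocol, tiny_phantom_spec):
        params, _ = generate_phantom(tiny_phantom_spec)
        stacks = simulate_acquisition(params, protocol, seed=0)
        with pytest.raises(ValueError, match="grid"):
            fit_volume(stacks, protocol, B1Map(kappa=np.ones((2, 2, 2))))
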