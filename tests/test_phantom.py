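"""Bolus physics, dilution theory, relaxation regimes, and phantom assembly."""

import math

import numpy as np
import pytest

from icaperf.phantom import (
    BolusParams,
    KiselevParams,
    PhantomSpec,
    bolus_concentration,
    build_phantom,
    concentration_to_signal,
    relaxation_shift,
    tissue_concentration,
)


class TestBolus:
    def test_zero_at_injection(self):
        assert bolus_concentration(0.0, BolusParams()) == 0.0

    def test_peak_value_and_location(self):
        p = BolusParams(c_max=3.0, t0=7.0)
        assert bolus_concentration(7.0, p) == pytest.approx(3.0, abs=1e-14)
        t = np.linspace(0, 60, 6001)
        c = bolus_concentration(t, p)
        assert t[np.argmax(c)] == pytest.approx(7.0, abs=0.02)

    def test_value_at_twice_t0(self):
        # c_max * 2 * e^-1 = 6/e
        p = BolusParams(c_max=3.0, t0=7.0)
        assert bolus_concentration(14.0, p) == pytest.approx(6.0 / math.e, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            bolus_concentration(-0.1, BolusParams())

    @pytest.mark.parametrize("cmax,t0", [(0.0, 7.0), (3.0, -1.0)])
    def test_invalid_params(self, cmax, t0):
        with pytest.raises(ValueError):
            BolusParams(c_max=cmax, t0=t0)


class TestDilution:
    def test_zero_input_gives_zero(self):
        out = tissue_concentration(np.zeros(40), mtt=2.6, zeta=0.02, dt=1.5)
        assert np.all(out == 0)

    def test_mass_balance_constant_input(self):
        # constant input c approaches zeta*c; exact bin-integrated kernel,
        # evaluated after 20 transit times
        mtt, zeta, c, dt = 2.6, 0.02, 2.0, 0.05
        n = int(20 * mtt / dt)
        out = tissue_concentration(np.full(n, c), mtt, zeta, dt)
        assert out[-1] == pytest.approx(zeta * c, rel=1e-6)

    @pytest.mark.parametrize("kernel", ["exact", "riemann"])
    def test_matches_bruteforce_convolution(self, kernel):
        # independent O(n^2) double-loop oracle
        rng = np.random.default_rng(3)
        aif = rng.random(150)
        mtt, zeta, dt = 2.6, 0.5, 1.5
        out = tissue_concentration(aif, mtt, zeta, dt, kernel=kernel)
        k = np.arange(150)
        if kernel == "exact":
            h = (1 - math.exp(-dt / mtt)) * np.exp(-k * dt / mtt)
        else:
            h = (dt / mtt) * np.exp(-k * dt / mtt)
        expected = np.zeros(150)
        for i in range(150):
            for j in range(i + 1):
                expected[i] += aif[j] * h[i - j]
        np.testing.assert_allclose(out, zeta * expected, atol=1e-12)

    def test_impulse_response_riemann_form(self):
        # unit impulse at index 0 -> zeta/mtt * exp(-t/mtt) * dt elementwise
        mtt, zeta, dt, n = 2.6, 0.3, 1.5, 60
        imp = np.zeros(n)
        imp[0] = 1.0
        out = tissue_concentration(imp, mtt, zeta, dt, kernel="riemann")
        t = np.arange(n) * dt
        np.testing.assert_allclose(out, zeta / mtt * np.exp(-t / mtt) * dt, rtol=1e-12)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            tissue_concentration(np.array([]), 2.6, 0.02, 1.5)


class TestRelaxation:
    def setup_method(self):
        self.p = KiselevParams()
        self.c = np.array([0.0, 0.5, 1.0, 2.0, 3.0])

    def test_zero_concentration_zero_shift(self):
        for regime in ("SDR", "DNR"):
            out = relaxation_shift(np.zeros(5), regime, 0.02, self.p)
            assert np.all(out == 0)

    def test_sdr_linear(self):
        r1 = relaxation_shift(self.c, "SDR", 0.02, self.p)
        r2 = relaxation_shift(2 * self.c, "SDR", 0.02, self.p)
        np.testing.assert_allclose(r2, 2 * r1, rtol=1e-12)

    def test_dnr_quadratic(self):
        r1 = relaxation_shift(self.c, "DNR", 0.02, self.p)
        r2 = relaxation_shift(2 * self.c, "DNR", 0.02, self.p)
        np.testing.assert_allclose(r2, 4 * r1, rtol=1e-12)

    def test_unknown_regime(self):
        with pytest.raises(ValueError, match="regime"):
            relaxation_shift(self.c, "XYZ", 0.02, self.p)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            relaxation_shift(np.array([-1.0]), "SDR", 0.02, self.p)


class TestSignalModel:
    def test_baseline_only(self):
        s = concentration_to_signal(np.zeros(10), s0=1000, te=0.045, r2_baseline=6.21)
        np.testing.assert_allclose(s, 1000 * math.exp(-0.045 * 6.21))

    def test_large_relaxation_drives_signal_to_zero(self):
        s = concentration_to_signal(np.array([1e3]), 1000, 0.045, 6.21)
        assert 0 < s[0] < 1e-10

    def test_algebraic_roundtrip(self):
        rng = np.random.default_rng(0)
        dr2 = rng.random(50) * 40
        s = concentration_to_signal(dr2, s0=1234.5, te=0.045, r2_baseline=6.21)
        recovered = -np.log(s / 1234.5) / 0.045 - 6.21
        np.testing.assert_allclose(recovered, dr2, rtol=1e-10, atol=1e-10)


class TestBuildPhantom:
    def test_deterministic(self):
        spec = PhantomSpec(cnr=40.0, seed=11)
        s1, _ = build_phantom(spec)
        s2, _ = build_phantom(spec)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_seed_changes_noise(self):
        s1, _ = build_phantom(PhantomSpec(cnr=40.0, seed=1))
        s2, _ = build_phantom(PhantomSpec(cnr=40.0, seed=2))
        assert not np.array_equal(s1.data, s2.data)

    def test_pure_artery_voxels_noise_free(self, noiseless_phantom):
        spec, series, truth = noiseless_phantom
        X = series.as_matrix()
        for vox in truth.mask_artery:
            np.testing.assert_array_equal(X[:, vox], truth.pure_signals["artery"])

    def test_overlap_is_half_mixture(self, noiseless_phantom):
        spec, series, truth = noiseless_phantom
        X = series.as_matrix()
        expected = 0.5 * truth.pure_signals["artery"] + 0.5 * truth.pure_signals["surround"]
        for vox in truth.mask_overlap_12:
            np.testing.assert_allclose(X[:, vox], expected, rtol=1e-12)

    def test_masks_disjoint_and_sized(self, noiseless_phantom):
        _, _, truth = noiseless_phantom
        masks = [truth.mask_artery, truth.mask_surround, truth.mask_tissue,
                 truth.mask_overlap_12, truth.mask_overlap_23]
        all_ids = np.concatenate(masks)
        assert len(all_ids) == len(set(all_ids.tolist()))
        assert len(truth.mask_artery) == 54
        assert len(truth.mask_surround) == 27
        assert len(truth.mask_overlap_12) == 27
        # each block is 9x9 = 81 voxels including its strips
        assert len(truth.region_mask("artery", True)) == 81
        assert len(truth.region_mask("surround", True)) == 81

    def test_empirical_cnr(self):
        spec = PhantomSpec(cnr=50.0, seed=5)
        series, truth = build_phantom(spec)
        X = series.as_matrix()
        art = truth.pure_signals["artery"]
        drop = art[series.baseline_slice].mean() - art.min()
        baseline_noise = X[series.baseline_slice][:, truth.mask_artery]
        sigma_hat = (baseline_noise - art[series.baseline_slice][:, None]).std(ddof=1)
        assert drop / sigma_hat == pytest.approx(50.0, rel=0.05)

    def test_surround_drop_smaller_and_later(self, noiseless_phantom):
        _, series, truth = noiseless_phantom
        art = truth.pure_signals["artery"]
        sur = truth.pure_signals["surround"]
        bsl = series.baseline_slice
        assert art[bsl].mean() - art.min() > sur[bsl].mean() - sur.min()
        assert np.argmin(sur) > np.argmin(art)

    def test_bad_overlap_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(overlap_cols=9, block_edge=9)
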