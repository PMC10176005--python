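"""Map estimation: ESTATICS fit, closed-form R1/A, MTsat, PD calibration."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from qmritrack.mpm import (
    MultiEchoSeries,
    calibrate_pd,
    compute_mtsat,
    compute_r1_amplitude,
    estimate_parameter_maps,
    fit_estatics,
)
from qmritrack.phantom import simulate_flash_series
from qmritrack.protocol import AcquisitionProtocol, mt_spgr_signal_te0


def _series(contrast, s0, r2s, te, shape=(1, 1, 1)):
    te = np.asarray(te, dtype=float)
    data = np.broadcast_to(
        np.asarray(s0)[..., None] * np.exp(-te * np.asarray(r2s)[..., None]),
        shape + (te.size,),
    ).copy()
    return MultiEchoSeries(contrast=contrast, data=data, te=tuple(te))


class TestEstatics:
    def test_two_point_log_linear_solution(self):
        data = np.array([[[[100.0, 81.873]]]])
        fit = fit_estatics([MultiEchoSeries("PDw", data, (0.002, 0.010))])
        # slope = ln(100/81.873)/0.008 = 25/s; S0 = 100 e^{0.05}
        assert fit.r2s[0, 0, 0] == pytest.approx(25.0, abs=1e-3)
        assert fit.intercepts["PDw"][0, 0, 0] == pytest.approx(105.127, abs=1e-2)

    def test_shared_decay_recovered_exactly(self):
        te = (0.002, 0.008, 0.014, 0.020)
        series = [
            _series(c, s0, 30.0, te)
            for c, s0 in (("MTw", 50.0), ("PDw", 80.0), ("T1w", 65.0))
        ]
        fit = fit_estatics(series)
        assert fit.r2s[0, 0, 0] == pytest.approx(30.0, rel=1e-12)
        for c, s0 in (("MTw", 50.0), ("PDw", 80.0), ("T1w", 65.0)):
            assert fit.intercepts[c][0, 0, 0] == pytest.approx(s0, rel=1e-12)

    def test_matches_single_contrast_fit_when_alone(self, rng):
        te = (0.003, 0.009, 0.015)
        s0 = rng.uniform(50, 100, size=(4, 1, 1))
        data = s0[..., None] * np.exp(-np.asarray(te) * 22.0)
        joint = fit_estatics([MultiEchoSeries("T1w", data, te)])
        slopes = np.polyfit(te, np.log(data[0, 0, 0]), 1)[0]
        assert joint.r2s[0, 0, 0] == pytest.approx(-slopes, rel=1e-10)

    def test_nonpositive_voxels_flagged_not_raised(self):
        data = np.ones((2, 1, 1, 2))
        data[1, 0, 0, 1] = 0.0
        fit = fit_estatics([MultiEchoSeries("PDw", data, (0.002, 0.01))])
        assert fit.valid[0, 0, 0] and not fit.valid[1, 0, 0]
        assert np.isnan(fit.r2s[1, 0, 0])

    def test_grid_mismatch_raises(self):
        a = _series("PDw", 10.0, 20.0, (0.002, 0.01), shape=(2, 1, 1))
        b = _series("T1w", 10.0, 20.0, (0.002, 0.01), shape=(3, 1, 1))
        with pytest.raises(ValueError):
            fit_estatics([a, b])

    def test_unbiased_against_nonlinear_oracle(self, rng):
        """Noisy log-linear fit agrees with exponential-domain NLS on average."""
        te = np.array([0.002, 0.006, 0.010, 0.014, 0.018, 0.022])
        r2s_true, s0_true, n_vox = 25.0, 100.0, 200
        clean = s0_true * np.exp(-te * r2s_true)
        data = clean + rng.normal(0, 1.0, size=(n_vox, 1, 1, te.size))
        fit = fit_estatics([MultiEchoSeries("PDw", data, tuple(te))], weighted=True)
        est_lin = fit.r2s[fit.valid]

        def model(t, s0, r):
            return s0 * np.exp(-t * r)

        est_nls = []
        for v in range(50):  # independent oracle on a subset
            popt, _ = curve_fit(model, te, data[v, 0, 0], p0=(90.0, 20.0))
            est_nls.append(popt[1])
        mc_err = 3 * np.std(est_nls, ddof=1) / np.sqrt(len(est_nls))
        assert abs(np.mean(est_nls) - r2s_true) < mc_err + 0.05
        assert abs(np.mean(est_lin) - r2s_true) < mc_err + 0.05


class TestR1Amplitude:
    def test_exact_inversion_of_small_angle_model(self, small_angle_protocol):
        prot = small_angle_protocol
        a_true, r1_true = 1000.0, 1.0

        def small(cp):
            u = cp.tr * r1_true
            return a_true * cp.flip_angle_rad * u / (cp.flip_angle_rad**2 / 2 + u)

        r1, a, valid = compute_r1_amplitude(
            np.array([small(prot.t1w)]), np.array([small(prot.pdw)]), prot
        )
        assert valid[0]
        assert r1[0] == pytest.approx(r1_true, rel=1e-12)
        assert a[0] == pytest.approx(a_true, rel=1e-12)

    def test_full_flash_signals_within_one_percent(self, small_angle_protocol):
        from qmritrack.protocol import spgr_signal

        prot = small_angle_protocol
        a_true, r1_true = 1000.0, 1.0
        s_t1 = spgr_signal(a_true, r1_true, 0.0, prot.t1w.flip_angle_rad, prot.t1w.tr, 0.0)
        s_pd = spgr_signal(a_true, r1_true, 0.0, prot.pdw.flip_angle_rad, prot.pdw.tr, 0.0)
        r1, a, valid = compute_r1_amplitude(np.atleast_1d(s_t1), np.atleast_1d(s_pd), prot)
        assert valid[0]
        assert r1[0] == pytest.approx(r1_true, rel=0.01)
        assert a[0] == pytest.approx(a_true, rel=0.01)

    def test_infeasible_voxel_flagged(self, small_angle_protocol):
        # an intercept ratio above the flip-angle ratio admits no positive R1
        # (S_T1/S_PD = 4 > a_T1/a_PD = 2.5 makes the closed form negative)
        r1, a, valid = compute_r1_amplitude(
            np.array([200.0]), np.array([50.0]), small_angle_protocol
        )
        assert not valid[0]
        assert np.isnan(r1[0]) and np.isnan(a[0])

    def test_degenerate_protocol_raises(self, small_angle_protocol):
        from qmritrack.protocol import AcquisitionProtocol

        prot = AcquisitionProtocol(
            mtw=small_angle_protocol.mtw,
            pdw=small_angle_protocol.pdw,
            t1w=small_angle_protocol.pdw,
        )
        with pytest.raises(ValueError, match="degenerate"):
            compute_r1_amplitude(np.array([1.0]), np.array([1.0]), prot)


class TestMtsat:
    def test_zero_saturation_identity(self, small_angle_protocol):
        prot = small_angle_protocol
        a, r1 = np.array([800.0]), np.array([0.9])
        s_mt0 = mt_spgr_signal_te0(a, r1, 0.0, prot.mtw.flip_angle_rad, prot.mtw.tr)
        mtsat, valid = compute_mtsat(s_mt0, a, r1, prot)
        assert valid[0]
        assert mtsat[0] == pytest.approx(0.0, abs=1e-10)

    def test_round_trip_two_pu(self, small_angle_protocol):
        prot = small_angle_protocol
        a, r1 = np.array([800.0]), np.array([0.9])
        s_mt0 = mt_spgr_signal_te0(a, r1, 2.0, prot.mtw.flip_angle_rad, prot.mtw.tr)
        mtsat, _ = compute_mtsat(s_mt0, a, r1, prot)
        assert mtsat[0] == pytest.approx(2.0, rel=1e-10)

    def test_strictly_increasing_in_amplitude(self, small_angle_protocol):
        prot = small_angle_protocol
        s, r1 = np.array([40.0]), np.array([1.0])
        lo, _ = compute_mtsat(s, np.array([800.0]), r1, prot)
        hi, _ = compute_mtsat(s, np.array([1600.0]), r1, prot)
        assert hi[0] > lo[0]

    def test_nonpositive_intercept_invalid(self, small_angle_protocol):
        mtsat, valid = compute_mtsat(
            np.array([0.0]), np.array([800.0]), np.array([1.0]), small_angle_protocol
        )
        assert not valid[0] and np.isnan(mtsat[0])


class TestCalibratePd:
    def test_constant_map_hits_target(self):
        a = np.full((3, 3, 3), 5.0)
        mask = np.zeros_like(a, dtype=bool)
        mask[1] = True
        assert np.allclose(calibrate_pd(a, mask, target_pu=69.0), 69.0)

    def test_global_scale_invariance(self, rng):
        a = rng.uniform(1, 10, size=(4, 4, 4))
        mask = a > 3
        np.testing.assert_allclose(
            calibrate_pd(a, mask), calibrate_pd(7.3 * a, mask), rtol=1e-12
        )

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            calibrate_pd(np.ones((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


class TestRoundTrip:
    def test_noiseless_cohort_round_trip(self, clean_phantom, small_angle_protocol):
        """simulate -> ESTATICS -> R1/A -> MTsat recovers the truth maps."""
        tp = clean_phantom.subjects[0].timepoints["T0"]
        series = simulate_flash_series(tp.maps, small_angle_protocol, noise_sd=0.0)
        est = estimate_parameter_maps(series.values(), small_angle_protocol)
        mask = tp.maps.valid & est.valid
        assert mask.sum() > 1000
        np.testing.assert_allclose(est.r2s[mask], tp.maps.r2s[mask], rtol=1e-9)
        for p in ("R1", "A", "MTsat"):
            err = np.abs(est[p][mask] - tp.maps[p][mask]) / np.abs(tp.maps[p][mask])
            assert np.nanmax(err) < 0.01, p

    def test_pd_calibration_recovers_truth_field(self, clean_phantom, small_angle_protocol):
        tp = clean_phantom.subjects[0].timepoints["T0"]
        nawm = tp.posteriors["NAWM"] > 0.5
        series = simulate_flash_series(tp.maps, small_angle_protocol, noise_sd=0.0)
        est = estimate_parameter_maps(
            series.values(), small_angle_protocol, pd_reference_mask=nawm
        )
        mask = tp.maps.valid & est.valid
        corr = np.corrcoef(est.pd[mask], tp.maps.pd[mask])[0, 1]
        assert corr > 0.9999

    def test_voxelwise_independence(self, rng, small_angle_protocol):
        """Permuting voxel order permutes every output identically."""
        n = 40
        from qmritrack.mpm import ParameterMaps

        shape = (n, 1, 1)
        truth = ParameterMaps(
            mtsat=rng.uniform(0.5, 3, shape), pd=rng.uniform(60, 90, shape),
            r1=rng.uniform(0.3, 1.2, shape), r2s=rng.uniform(5, 30, shape),
            a=rng.uniform(60, 90, shape),
        )
        series = simulate_flash_series(truth, small_angle_protocol, noise_sd=0.0)
        est = estimate_parameter_maps(series.values(), small_angle_protocol)
        perm = rng.permutation(n)
        series_p = {
            c: MultiEchoSeries(c, s.data[perm], s.te) for c, s in series.items()
        }
        est_p = estimate_parameter_maps(series_p.values(), small_angle_protocol)
        for p in ("MTsat", "R1", "R2s", "A"):
            np.testing.assert_allclose(est_p[p], est[p][perm], rtol=1e-12)
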