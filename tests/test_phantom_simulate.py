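"""Digital phantom geometry and the k-space forward model."""

import numpy as np
import pytest

from natsc import (AcquisitionProtocol, CohortSpec, HeadGeometry,
                   TissueProperties, build_head_phantom, cohort_truths,
                   default_tissues, generate_cohort, signal_weight,
                   simulate_kspace)
from natsc.phantom import Ellipsoid, scene_fourier


class TestTissueProperties:
    def test_defaults_follow_brain_relaxation(self):
        t = default_tissues()
        assert t["csf"].t1_ms == 47.0 and t["wm"].t1_ms == 22.0
        assert t["tube20"].tsc_mM == 20.0 and t["tube80"].tsc_mM == 80.0

    @pytest.mark.parametrize("kwargs", [
        {"tsc_mM": -1.0}, {"t1_ms": 0.0}, {"frac_short": 1.2},
        {"t2s_short_ms": 30.0, "t2s_long_ms": 10.0},
    ])
    def test_invalid_properties_rejected(self, kwargs):
        base = {"name": "x", "tsc_mM": 50.0, "t1_ms": 30.0,
                "t2s_short_ms": 3.0, "t2s_long_ms": 20.0, "frac_short": 0.5}
        base.update(kwargs)
        with pytest.raises(ValueError):
            TissueProperties(**base)


class TestHeadPhantom:
    def test_pv_fractions_partition(self, head_phantom):
        total = sum(head_phantom.pv_maps.values())
        assert total.max() <= 1.0 + 1e-9
        # pure cores are exactly 1
        for t in ("wm", "gm"):
            m = head_phantom.pv_maps[t] > 0.95
            assert m.any()
            assert head_phantom.pv_maps[t][m].max() == pytest.approx(1.0)

    def test_tube_raster_extent_matches_physical_size(self, head_phantom):
        """24.5 mm x 89 mm tubes at 4 mm: ~6-voxel diameter, ~22 slices."""
        masks = head_phantom.tube_masks_truth()
        for m in masks.values():
            slices = np.where(m.any(axis=(0, 1)))[0]
            assert 20 <= len(slices) <= 23
            mid = m[:, :, slices[len(slices) // 2]]
            xs = np.where(mid.any(axis=1))[0]
            assert 5 <= np.ptp(xs) + 1 <= 7

    def test_tube_intersecting_head_rejected(self):
        with pytest.raises(ValueError, match="intersects the head"):
            build_head_phantom(geometry=HeadGeometry(tube_offset_mm=60.0),
                               rasterize=False)

    def test_overlapping_ventricles_rejected(self):
        bad = HeadGeometry(ventricle_semi_mm=(20, 30, 15),
                           ventricle_offset_mm=10.0)
        with pytest.raises(ValueError, match="overlap"):
            build_head_phantom(geometry=bad, rasterize=False)


class TestSignalWeight:
    def test_full_recovery_limit(self):
        t = TissueProperties("x", 50, 4.0, 3, 20, 0.5)
        assert signal_weight(t, tr_ms=100.0, t_ms=0.0) == pytest.approx(1.0 - np.exp(-25),
                                                                        abs=1e-8)

    def test_csf_saturation_closed_form(self):
        csf = default_tissues()["csf"]
        # t = 0 isolates the T1 term
        assert signal_weight(csf, 100.0, 0.0) == pytest.approx(
            1.0 - np.exp(-100.0 / 47.0), rel=1e-12)

    def test_biexponential_decay_closed_form(self):
        t = TissueProperties("x", 50, 1e9, 3.0, 20.0, 0.6)
        at5 = signal_weight(t, 1e12, 5.0)
        assert at5 == pytest.approx(0.6 * np.exp(-5 / 3) + 0.4 * np.exp(-5 / 20),
                                    rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            signal_weight(default_tissues()["wm"], 100.0, -1.0)


class TestSimulateKspace:
    def test_zero_concentration_gives_pure_noise_with_averaging(
            self, head_phantom, ci_raw_traj, ci_protocol):
        """With 3 averages the per-channel SD is noise_sd / sqrt(3)."""
        zero = {k: TissueProperties(k, 0.0, v.t1_ms, v.t2s_short_ms,
                                    v.t2s_long_ms, v.frac_short)
                for k, v in head_phantom.tissues.items()}
        ph = head_phantom.with_tissues(zero)
        kd = simulate_kspace(ph, ci_raw_traj, ci_protocol, noise_sd=1.0, seed=4)
        expected = 1.0 / np.sqrt(3.0)
        assert kd.samples.real.std() == pytest.approx(expected, rel=0.05)
        assert kd.samples.imag.std() == pytest.approx(expected, rel=0.05)

    def test_uniform_sphere_matches_closed_form(self, ci_protocol, ci_raw_traj):
        """Analytic-mode samples of a sphere equal the sin(x) - x cos(x) form."""
        R, amp = 0.05, 42.0
        sphere = Ellipsoid((0, 0, 0), (R, R, R))
        phantom = build_head_phantom(voxel_mm=4.0, grid_size=60,
                                     rasterize=False)
        phantom.solids = [(sphere, "wm", None)]
        phantom.tissues = {"wm": TissueProperties("wm", amp, 22, 3, 20, 0.6)}
        kd = simulate_kspace(phantom, ci_raw_traj, ci_protocol,
                             noise_sd=0.0, relaxation=False)
        kr = np.linalg.norm(ci_raw_traj.k, axis=2)
        x = 2 * np.pi * kr * R
        with np.errstate(invalid="ignore"):
            expected = amp * np.where(
                x < 1e-8, 4 / 3 * np.pi * R ** 3,
                (np.sin(x) - x * np.cos(x)) / (2 * np.pi ** 2 * np.maximum(kr, 1e-30) ** 3))
        np.testing.assert_allclose(kd.samples.real, expected, rtol=1e-6,
                                   atol=1e-12)
        np.testing.assert_allclose(kd.samples.imag, 0.0, atol=1e-12)

    def test_linearity_in_concentration(self, head_phantom, ci_raw_traj,
                                        ci_protocol):
        doubled = {k: TissueProperties(k, 2 * v.tsc_mM, v.t1_ms,
                                       v.t2s_short_ms, v.t2s_long_ms,
                                       v.frac_short)
                   for k, v in head_phantom.tissues.items()}
        kd1 = simulate_kspace(head_phantom, ci_raw_traj, ci_protocol, 0.0)
        kd2 = simulate_kspace(head_phantom.with_tissues(doubled),
                              ci_raw_traj, ci_protocol, 0.0)
        np.testing.assert_allclose(kd2.samples, 2.0 * kd1.samples, rtol=1e-12)

    def test_raster_mode_agrees_with_analytic(self, ci_protocol):
        """NUFFT of the rasterised phantom tracks the analytic transform."""
        phantom = build_head_phantom(voxel_mm=ci_protocol.voxel_mm,
                                     grid_size=ci_protocol.grid_size,
                                     supersample=3)
        proto = AcquisitionProtocol(n_readouts=24, readout_ms=2.0,
                                    bw_full_khz=25.0, tr_ms=20.0)
        from natsc import design_cones
        traj = design_cones(proto)
        ka = simulate_kspace(phantom, traj, proto, 0.0, mode="analytic")
        kr = simulate_kspace(phantom, traj, proto, 0.0, mode="raster")
        err = np.linalg.norm(ka.samples - kr.samples) / np.linalg.norm(ka.samples)
        assert err < 0.05

    def test_reproducible_for_fixed_seed(self, head_phantom, ci_raw_traj,
                                         ci_protocol):
        a = simulate_kspace(head_phantom, ci_raw_traj, ci_protocol, 0.5, seed=9)
        b = simulate_kspace(head_phantom, ci_raw_traj, ci_protocol, 0.5, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestCohort:
    def test_default_cohort_structure(self):
        spec = CohortSpec()
        assert spec.n_subjects == 11
        assert spec.scans_per_site["A"] == [2] * 11
        assert spec.scans_per_site["B"] == [2] * 7 + [1] * 4
        assert spec.tsc_mean_mM == {"wm": 41.8, "gm": 52.1, "csf": 85.8}
        assert spec.tsc_sd_mM == {"wm": 6.7, "gm": 7.1, "csf": 14.3}

    def test_zero_spread_gives_identical_truths(self):
        spec = CohortSpec(n_subjects=5, tsc_sd_mM={"wm": 0, "gm": 0, "csf": 0})
        truths = cohort_truths(spec)
        for tissue, mean in spec.tsc_mean_mM.items():
            vals = truths[truths.tissue == tissue].true_tsc_mM
            assert (vals == mean).all()

    def test_truth_draws_match_configured_distribution(self):
        """Monte-Carlo: 200-subject WM mean within 3 SE of the target."""
        spec = CohortSpec(n_subjects=200, seed=21)
        truths = cohort_truths(spec)
        wm = truths[truths.tissue == "wm"].true_tsc_mM.to_numpy()
        se = spec.tsc_sd_mM["wm"] / np.sqrt(len(wm))
        assert abs(wm.mean() - spec.tsc_mean_mM["wm"]) < 3 * se
        assert (wm >= 0).all()

    def test_truths_stable_under_cohort_growth(self):
        small = cohort_truths(CohortSpec(n_subjects=3, seed=5))
        large = cohort_truths(CohortSpec(n_subjects=6, seed=5))
        merged = small.merge(large, on=["subject", "tissue"])
        np.testing.assert_allclose(merged.true_tsc_mM_x, merged.true_tsc_mM_y)

    def test_scan_stream_matches_design(self, ci_protocol, ci_raw_traj):
        spec = CohortSpec(n_subjects=2, seed=1,
                          scans_per_site={"A": [2, 2], "B": [2, 1]})
        scans, truths = generate_cohort(spec, ci_protocol, ci_raw_traj)
        infos = [info for info, _, _ in scans]
        assert len(infos) == 7  # 4 at site A, 3 at site B
        assert sum(1 for i in infos if i["site"] == "B" and i["scan"] == 2) == 1
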