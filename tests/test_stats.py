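"""Statistics layer against closed-form and ANOVA oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from natsc import (bland_altman, build_report, icc, place_observer_rois,
                   region_means, repeatability_stats, reproducibility_stats,
                   tissue_masks)
from natsc.pipeline import make_fixtures


class TestTissueMasks:
    def test_strict_threshold_and_default(self):
        pv = {"wm": np.array([[[0.94, 0.95, 0.951, 1.0]]]),
              "gm": np.zeros((1, 1, 4)), "csf": np.ones((1, 1, 4))}
        with pytest.warns(UserWarning, match="empty"):
            masks = tissue_masks(pv)
        np.testing.assert_array_equal(masks["wm"][0, 0],
                                      [False, False, True, True])
        assert masks["csf"].all()

    def test_binary_maps_unchanged_at_any_threshold(self):
        rng = np.random.default_rng(0)
        binary = (rng.random((4, 4, 4)) > 0.5).astype(float)
        pv = {"wm": binary, "gm": binary, "csf": binary}
        for thr in (0.1, 0.5, 0.9):
            masks = tissue_masks(pv, threshold=thr)
            np.testing.assert_array_equal(masks["wm"], binary.astype(bool))

    def test_cardinality_matches_direct_count(self):
        rng = np.random.default_rng(3)
        pv = rng.random((6, 6, 6))
        masks = tissue_masks({"wm": pv, "gm": pv, "csf": pv})
        assert masks["wm"].sum() == int((pv > 0.95).sum())

    def test_out_of_range_pv_rejected(self):
        with pytest.raises(ValueError):
            tissue_masks({"wm": np.full((2, 2, 2), 1.5),
                          "gm": np.zeros((2, 2, 2)),
                          "csf": np.zeros((2, 2, 2))})


class TestObserverRois:
    def test_zero_jitter_observers_identical(self, head_phantom):
        a = place_observer_rois(head_phantom, observer_jitter_mm=0.0, seed=1)
        b = place_observer_rois(head_phantom, observer_jitter_mm=0.0, seed=2)
        for region in a:
            np.testing.assert_array_equal(a[region], b[region])

    def test_rois_bilateral(self, head_phantom):
        from scipy import ndimage
        rois = place_observer_rois(head_phantom, 0.0, seed=0)
        for region, mask in rois.items():
            _, n_comp = ndimage.label(mask)
            assert n_comp == 2, region

    def test_dice_decreases_as_jitter_doubles(self, head_phantom):
        """Observer agreement degrades monotonically with hand jitter."""
        def mean_dice(jitter):
            vals = []
            for pair in range(10):
                a = place_observer_rois(head_phantom, jitter, seed=(pair, 0))
                b = place_observer_rois(head_phantom, jitter, seed=(pair, 1))
                for r in a:
                    inter = (a[r] & b[r]).sum()
                    vals.append(2 * inter / (a[r].sum() + b[r].sum()))
            return np.mean(vals)
        d1, d2, d4 = (mean_dice(j) for j in (1.0, 2.0, 4.0))
        assert d1 > d2 > d4


class TestRegionMeans:
    def test_constant_field(self):
        vals = np.full((4, 4, 4), 50.0)
        masks = {"wm": np.ones((4, 4, 4), bool)}
        df = region_means(vals, masks)
        assert df.mean_tsc_mM.iloc[0] == pytest.approx(50.0)
        assert df.n_voxels.iloc[0] == 64

    def test_checkerboard_against_direct_sum(self):
        vals = np.indices((4, 4, 4)).sum(0) % 2
        vals = np.where(vals == 0, 40.0, 60.0)
        mask = np.ones((4, 4, 4), bool)
        df = region_means(vals, {"wm": mask})
        assert df.mean_tsc_mM.iloc[0] == pytest.approx(vals.sum() / 64) == 50.0

    def test_empty_mask_flagged_not_dropped(self):
        with pytest.warns(UserWarning, match="empty mask"):
            df = region_means(np.ones((2, 2, 2)),
                              {"wm": np.zeros((2, 2, 2), bool)})
        assert df.flag_empty.iloc[0]
        assert len(df) == 1


class TestRepeatability:
    def test_identical_pairs_give_zero(self):
        st_ = repeatability_stats([(40.0, 40.0), (55.0, 55.0), (70.0, 70.0)])
        assert st_["cov_pct"] == 0.0 and st_["rc_mM"] == 0.0

    def test_single_pair_closed_form(self):
        """(40, 42): wsd = sqrt(2), CoV = 100*sqrt(2)/41 = 3.449%."""
        st_ = repeatability_stats([(40.0, 42.0), (40.0, 42.0)])
        assert st_["wsd_mM"] == pytest.approx(np.sqrt(2.0), rel=1e-12)
        assert st_["cov_pct"] == pytest.approx(100 * np.sqrt(2) / 41, rel=1e-12)

    def test_rc_is_2772_times_wsd(self):
        """Pooled wsd of 1 mM gives RC = 1.96*sqrt(2) = 2.772 mM."""
        x = 50.0
        d = np.sqrt(2.0)  # |x1-x2| = sqrt(2) -> wsd_i = 1
        st_ = repeatability_stats([(x, x + d), (x, x - d), (x + d, x)])
        assert st_["wsd_mM"] == pytest.approx(1.0, rel=1e-12)
        assert st_["rc_mM"] == pytest.approx(1.96 * np.sqrt(2.0), rel=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            repeatability_stats([(40.0, 42.0)])

    def test_reproducibility_is_same_estimator(self):
        pairs = [(40.0, 43.0), (50.0, 49.0), (60.0, 58.0)]
        assert reproducibility_stats(pairs) == repeatability_stats(pairs)

    def test_estimator_consistency_against_injected_sd(self):
        """CoV converges to 100*sigma_m/mu over a 200-repeat oracle."""
        rng = np.random.default_rng(42)
        mu, sigma_m, n = 50.0, 1.5, 11
        covs = []
        for _ in range(200):
            subj = rng.normal(mu, 7.0, size=n)
            pairs = np.stack([subj + rng.normal(0, sigma_m, n),
                              subj + rng.normal(0, sigma_m, n)], axis=1)
            covs.append(repeatability_stats(pairs)["cov_pct"])
        target = 100.0 * sigma_m / mu
        se = np.std(covs) / np.sqrt(len(covs))
        assert abs(np.mean(covs) - target) < 3 * se + 0.02 * target

    def test_cov_monotone_in_noise(self):
        """Repeatability CoV non-decreasing across 4 noise levels, 5 seeds."""
        mu, n = 50.0, 11
        for seed in range(5):
            rng = np.random.default_rng(seed)
            subj = rng.normal(mu, 7.0, size=n)
            covs = []
            for sigma in (0.5, 1.0, 2.0, 4.0):
                rng2 = np.random.default_rng((seed, int(sigma * 10)))
                pairs = np.stack([subj + rng2.normal(0, sigma, n),
                                  subj + rng2.normal(0, sigma, n)], axis=1)
                covs.append(np.mean([repeatability_stats(pairs)["cov_pct"]
                                     for _ in range(1)]))
            assert all(b > a for a, b in zip(covs, covs[1:]))


class TestBlandAltman:
    def test_equal_pairs(self):
        ba = bland_altman([(40.0, 40.0), (50.0, 50.0)])
        assert (ba["mean_diff_mM"], ba["loa_low_mM"], ba["loa_high_mM"]) == \
            (0.0, 0.0, 0.0)

    def test_closed_form_differences(self):
        """d = {2, -2, 0}: mean 0, SD 2, LoA -/+ 3.92."""
        ba = bland_altman([(0.0, 2.0), (0.0, -2.0), (0.0, 0.0)])
        assert ba["mean_diff_mM"] == 0.0
        assert ba["loa_high_mM"] == pytest.approx(3.92, rel=1e-12)
        assert ba["loa_low_mM"] == pytest.approx(-3.92, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
                    min_size=2, max_size=20))
    def test_loa_bracket_mean(self, pairs):
        ba = bland_altman(pairs)
        assert ba["loa_low_mM"] <= ba["mean_diff_mM"] <= ba["loa_high_mM"]


class TestIcc:
    def test_perfect_agreement(self):
        x = np.tile(np.array([40.0, 50, 60, 45, 55])[:, None], (1, 2))
        assert icc(x)["icc"] == pytest.approx(1.0)

    def test_fixture_matrix_against_anova_oracle(self):
        """6x2 matrix: ICC(2,1) from hand-computed mean squares to 1e-10."""
        x = make_fixtures("unit")["icc_matrix"]
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(1, keepdims=True) - x.mean(0, keepdims=True)
                + grand) ** 2).sum() / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(x)["icc"] == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_absolute_agreement(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        x = rng.normal(50, 7, (9, 1)) + rng.normal(0, 2, (9, 2)) + [[0, 0.8]]
        df = pd.DataFrame({"s": np.repeat(np.arange(9), 2),
                           "r": np.tile([0, 1], 9), "y": x.ravel()})
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        ref_row = ref[ref.Type == "ICC2"] if (ref.Type == "ICC2").any() \
            else ref.iloc[[1]]
        mine = icc(x)
        assert mine["icc"] == pytest.approx(float(ref_row.ICC.iloc[0]),
                                            abs=1e-10)
        lo, hi = ref_row.CI95.iloc[0]
        assert mine["ci_low"] == pytest.approx(lo, abs=0.01)
        assert mine["ci_high"] == pytest.approx(hi, abs=0.01)

    def test_zero_variance_flagged(self):
        flat = np.full((5, 2), 42.0)
        out = icc(flat)
        assert out["undefined"] and np.isnan(out["icc"])

    def test_point_estimate_bounded(self):
        rng = np.random.default_rng(0)
        out = icc(rng.normal(size=(6, 2)))
        assert -1.0 <= out["icc"] <= 1.0
        assert out["ci_low"] <= out["icc"] <= out["ci_high"]


def _measurement_rows(values):
    rows = []
    for (subj, site, scan, region, obs), v in values.items():
        rows.append({"subject": subj, "site": site, "scan": scan,
                     "region": region, "observer": obs, "mean_tsc_mM": v,
                     "n_voxels": 10})
    return pd.DataFrame(rows)


class TestBuildReport:
    def test_unpaired_scans_never_contaminate_paired_stats(self):
        """A poisoned single-scan value enters per-scan means only."""
        vals = {}
        for s in range(4):
            vals[(s, "A", 1, "wm", "auto")] = 40.0 + s
            vals[(s, "A", 2, "wm", "auto")] = 40.5 + s
        # subject 4 has only scan 1, with an absurd value
        vals[(4, "A", 1, "wm", "auto")] = 1e6
        df = _measurement_rows(vals)
        rep = build_report(df)
        r = rep.repeatability
        assert r.n_pairs.iloc[0] == 4
        assert r.cov_pct.iloc[0] < 1.0  # poisoned value excluded
        scan1 = rep.per_scan_means.query("scan == 1")
        assert scan1.n.iloc[0] == 5  # but it does count in per-scan means

    def test_single_scan_subjects_excluded_from_pairing(self):
        vals = {}
        for s in range(7):
            vals[(s, "B", 1, "wm", "auto")] = 40.0 + s
            vals[(s, "B", 2, "wm", "auto")] = 41.0 + s
        for s in range(7, 11):
            vals[(s, "B", 1, "wm", "auto")] = 40.0 + s
        rep = build_report(_measurement_rows(vals))
        scan2 = rep.per_scan_means.query("site == 'B' and scan == 2")
        assert scan2.n.iloc[0] == 7
        assert rep.repeatability.query("site == 'B'").n_pairs.iloc[0] == 7

    def test_noiseless_cohort_collapses_to_zero_variability(self):
        vals = {}
        for s in range(5):
            for site in ("A", "B"):
                for scan in (1, 2):
                    for obs in ("auto", "obs1", "obs2"):
                        vals[(s, site, scan, "wm", obs)] = 40.0 + 3 * s
        rep = build_report(_measurement_rows(vals))
        assert (rep.repeatability.cov_pct == 0).all()
        assert rep.bland_altman_repro["mean_diff_mM"] == 0.0
        assert (rep.icc_interobserver.icc == 1.0).all()
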