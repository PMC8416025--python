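import math
import warnings

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from mtquant import filaments
from mtquant.filaments import (
    FilamentSegment,
    SegmentBorderError,
    detect_segments,
    estimate_crosstalk,
    filter_singles,
    fit_single_intensity,
    measure_segment,
    segments_from_rois,
    select_substack,
)
from mtquant.rois import PolylineRoi
from mtquant.simgen import simulate_segment_intensities
from mtquant.stack import ChannelStack


# ---------------------------------------------------------------------------
# brute-force oracle for the dual-width measurement (pure python loops,
# same pixel-centre distance rule as the implementation)


def oracle_measure(img, vertices, w_mid, w_wide):
    def point_seg_dist(px, py, a, b):
        ax, ay = a
        bx, by = b
        abx, aby = bx - ax, by - ay
        denom = abx * abx + aby * aby
        if denom == 0:
            return math.hypot(px - ax, py - ay)
        t = max(0.0, min(1.0, ((px - ax) * abx + (py - ay) * aby) / denom))
        return math.hypot(px - (ax + t * abx), py - (ay + t * aby))

    def in_tube(px, py, width):
        d = min(
            point_seg_dist(px, py, vertices[i], vertices[i + 1])
            for i in range(len(vertices) - 1)
        )
        return d <= width / 2.0

    i_mid = i_wide = 0.0
    s_mid = s_wide = 0
    ny, nx = img.shape
    for y in range(ny):
        for x in range(nx):
            if in_tube(x, y, w_wide):
                i_wide += img[y, x]
                s_wide += 1
                if in_tube(x, y, w_mid):
                    i_mid += img[y, x]
                    s_mid += 1
    i_bg = (i_wide - i_mid) / (s_wide - s_mid)
    return i_mid / s_mid - i_bg


def render_filament(shape, p0, p1, amplitude=2000.0, sigma=1.0,
                    background=0.0):
    """2D line rendered by dense point deposition then Gaussian blur."""
    img = np.zeros(shape)
    n = 400
    t = np.linspace(0, 1, n)
    xs = p0[0] + t * (p1[0] - p0[0])
    ys = p0[1] + t * (p1[1] - p0[1])
    length = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
    w = amplitude * length / n
    for x, y in zip(xs, ys):
        ix, iy = int(np.floor(x)), int(np.floor(y))
        fx, fy = x - ix, y - iy
        for dy in (0, 1):
            for dx in (0, 1):
                wy = fy if dy else 1 - fy
                wx = fx if dx else 1 - fx
                img[iy + dy, ix + dx] += w * wx * wy
    return gaussian_filter(img, sigma) + background


class TestSelectSubstack:
    def make_stack(self, vals):
        vox = np.stack([vals, vals * 2, vals * 3])
        return ChannelStack(vox, ("total", "tyr", "ac"), (0.04, 0.04, 0.15))

    def test_single_slice_mip_equals_sum(self, rng):
        vals = rng.poisson(20, (4, 8, 8)).astype(float)
        stack = self.make_stack(vals)
        mips, sums = select_substack(stack, (2, 3))
        np.testing.assert_array_equal(mips["total"], vals[2])
        np.testing.assert_array_equal(sums["total"], vals[2])

    def test_constant_stack(self):
        vals = np.full((4, 6, 6), 3.0)
        stack = self.make_stack(vals)
        mips, sums = select_substack(stack, (0, 4))
        assert np.all(mips["total"] == 3.0)
        assert np.all(sums["total"] == 12.0)

    def test_empty_range_rejected(self, rng):
        stack = self.make_stack(rng.poisson(5, (4, 6, 6)).astype(float))
        with pytest.raises(ValueError):
            select_substack(stack, (2, 2))
        with pytest.raises(ValueError):
            select_substack(stack, (0, 9))


class TestDetectSegments:
    def test_blank_image(self):
        assert detect_segments(np.zeros((64, 64)), pixel_size=0.04) == []

    def test_single_filament_recovered(self, rng):
        # 3 um filament at 0.04 um pixels = 75 px, SNR ~ 20
        img = render_filament((100, 120), (20.0, 50.0), (95.0, 50.0),
                              amplitude=400.0, background=10.0)
        img = rng.poisson(img).astype(float)
        segs = detect_segments(img, pixel_size=0.04)
        assert len(segs) == 1
        seg = segs[0]
        true_len = 75 * 0.04
        assert abs(seg.length_um - true_len) / true_len < 0.15
        ends = seg.vertices[[0, -1]]
        d0 = min(np.linalg.norm(ends - np.array([20.0, 50.0]), axis=1))
        d1 = min(np.linalg.norm(ends - np.array([95.0, 50.0]), axis=1))
        assert max(d0, d1) <= 4  # endpoints shrink slightly at mask tips

    def test_two_parallel_filaments_not_merged(self, rng):
        img = (
            render_filament((100, 120), (20.0, 45.0), (95.0, 45.0),
                            amplitude=400.0)
            + render_filament((100, 120), (20.0, 55.0), (95.0, 55.0),
                              amplitude=400.0)
            + 10.0
        )
        img = rng.poisson(img).astype(float)
        segs = detect_segments(img, pixel_size=0.04)
        assert len(segs) == 2

    def test_min_length_filter(self, rng):
        img = render_filament((64, 64), (28.0, 32.0), (36.0, 32.0),
                              amplitude=400.0) + 5.0
        segs = detect_segments(rng.poisson(img).astype(float),
                               pixel_size=0.04, min_length_um=0.6)
        assert segs == []

    def test_polygon_mask_limits_detection(self, rng):
        img = render_filament((100, 120), (20.0, 50.0), (95.0, 50.0),
                              amplitude=400.0) + 5.0
        img = rng.poisson(img).astype(float)
        far_mask = PolylineRoi.rectangle(0, 0, 20, 20)
        assert detect_segments(img, pixel_size=0.04, mask=far_mask) == []

    def test_imported_rois_bypass_detection(self):
        rois = [PolylineRoi(np.array([[0.0, 0.0], [30.0, 0.0]])),
                PolylineRoi(np.array([[0.0, 5.0], [5.0, 5.0]]))]
        segs = segments_from_rois(rois, pixel_size=0.04,
                                  detection_channel="tyr")
        assert len(segs) == 1  # second is below min length
        assert segs[0].source == "imported_roi"
        assert segs[0].detection_channel == "tyr"


class TestMeasureSegment:
    def straight_segment(self):
        return FilamentSegment(
            "total", np.array([[15.0, 25.0], [45.0, 25.0]]), 1.2
        )

    def test_flat_field_null(self):
        img = np.full((50, 60), 7.5)
        m = measure_segment({"total": img}, self.straight_segment())
        ci = m.channels["total"]
        assert ci.I_BG == pytest.approx(7.5)
        assert ci.I_segm == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        img = render_filament((50, 60), (15.0, 25.0), (45.0, 25.0),
                              amplitude=300.0, background=5.0)
        img = rng.poisson(img).astype(float)
        seg = FilamentSegment(
            "total", np.array([[15.0, 25.3], [30.0, 24.6], [45.0, 25.1]]),
            1.2,
        )
        m = measure_segment({"total": img}, seg)
        expected = oracle_measure(img, seg.vertices, 6.0, 13.0)
        assert abs(m.channels["total"].I_segm - expected) <= (
            1e-9 * abs(expected)
        )

    def test_background_invariance(self, rng):
        clean = render_filament((50, 60), (15.0, 25.0), (45.0, 25.0),
                                amplitude=300.0)
        seg = self.straight_segment()
        base = measure_segment({"total": clean}, seg).channels["total"].I_segm
        lifted = measure_segment(
            {"total": clean + 40.0}, seg
        ).channels["total"].I_segm
        assert abs(lifted - base) / base < 0.02

    def test_border_segment_flagged(self):
        img = np.ones((50, 60))
        seg = FilamentSegment(
            "total", np.array([[2.0, 3.0], [30.0, 3.0]]), 1.1
        )
        with pytest.raises(SegmentBorderError):
            measure_segment({"total": img}, seg)

    def test_measured_in_all_channels(self):
        imgs = {"total": np.full((50, 60), 5.0),
                "tyr": np.full((50, 60), 2.0),
                "ac": np.full((50, 60), 9.0)}
        m = measure_segment(imgs, self.straight_segment())
        assert set(m.channels) == {"total", "tyr", "ac"}
        for ci in m.channels.values():
            assert ci.S_wide > ci.S_mid > 0


class TestFitSingleIntensity:
    @pytest.mark.parametrize("doublet_fraction", [0.1, 0.3, 0.5])
    @pytest.mark.parametrize("cv", [0.1, 0.15, 0.2])
    def test_identifiability_grid(self, cv, doublet_fraction):
        vals = simulate_segment_intensities(
            2000, mean_single=100.0, cv=cv,
            doublet_fraction=doublet_fraction, seed=17,
        )
        fit = fit_single_intensity(vals)
        assert abs(fit.i_single - 100.0) / 100.0 < 0.05

    def test_reference_case(self):
        vals = simulate_segment_intensities(
            2000, mean_single=100.0, cv=0.15, doublet_fraction=0.3, seed=42
        )
        fit = fit_single_intensity(vals)
        assert 95.0 <= fit.i_single <= 105.0
        assert fit.single_threshold == pytest.approx(
            fit.i_single + fit.sigma_single
        )

    def test_no_doublets_small_second_amplitude(self):
        vals = simulate_segment_intensities(
            2000, mean_single=100.0, cv=0.12, doublet_fraction=0.0, seed=5
        )
        fit = fit_single_intensity(vals)
        assert fit.a2 / fit.a1 < 0.05
        assert abs(fit.i_single - 100.0) / 100.0 < 0.02

    def test_identical_intensities_rejected(self):
        with pytest.raises(filaments.FitError, match="variance"):
            fit_single_intensity(np.full(500, 42.0))

    def test_small_sample_warns(self):
        vals = simulate_segment_intensities(
            60, mean_single=100.0, cv=0.15, doublet_fraction=0.2, seed=9
        )
        with pytest.warns(UserWarning, match="n=60"):
            fit_single_intensity(vals)


def _fake_measurement(total, tyr=0.0, ac=0.0, channel="total"):
    seg = FilamentSegment(channel, np.array([[0.0, 0.0], [10.0, 0.0]]), 1.0)
    chans = {
        name: filaments.ChannelIntensity(v, v, 10, 20, 0.0, v)
        for name, v in (("total", total), ("tyr", tyr), ("ac", ac))
    }
    return filaments.SegmentIntensity(seg, chans)


class TestFilterSingles:
    def fit(self):
        return filaments.SingleIntensityFit(
            a1=1, a2=0.1, i_single=100.0, sigma_single=15.0,
            residual_norm=0.0, n=500, bin_width=5.0,
        )

    def test_boundary_is_strictly_below(self):
        at_threshold = _fake_measurement(115.0)
        below = _fake_measurement(114.999)
        kept, report = filter_singles([at_threshold, below], self.fit())
        assert kept == [below]
        assert report == {"kept": 1, "discarded": 1}

    def test_empty_input(self):
        kept, report = filter_singles([], self.fit())
        assert kept == []
        assert report == {"kept": 0, "discarded": 0}

    def test_doublet_removal_rates(self):
        rng = np.random.default_rng(3)
        singles = [
            _fake_measurement(v)
            for v in rng.normal(100, 15, 400)
        ]
        doublets = [
            _fake_measurement(v)
            for v in rng.normal(200, 15 * np.sqrt(2), 200)
        ]
        kept, _ = filter_singles(singles + doublets, self.fit())
        kept_ids = {id(m) for m in kept}
        singles_kept = sum(1 for m in singles if id(m) in kept_ids)
        doublets_kept = sum(1 for m in doublets if id(m) in kept_ids)
        assert doublets_kept / len(doublets) < 0.2  # >= 80% removed
        assert singles_kept / len(singles) > 0.8  # <= 20% removed


class TestEstimateCrosstalk:
    def test_basic_estimates(self):
        tyr_singles = [
            _fake_measurement(100, tyr=50.0, ac=9.0, channel="tyr")
            for _ in range(25)
        ]
        ac_singles = [
            _fake_measurement(100, tyr=25.0, ac=20.0, channel="ac")
            for _ in range(25)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            ct = estimate_crosstalk({"tyr": tyr_singles, "ac": ac_singles})
        assert ct.i_tyr == pytest.approx(50.0)
        assert ct.i_ac == pytest.approx(20.0)
        assert ct.alpha == pytest.approx(25.0 / 50.0)
        assert ct.beta == pytest.approx(9.0 / 20.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        tyr_singles = [
            _fake_measurement(100, tyr=t, ac=a, channel="tyr")
            for t, a in zip(rng.normal(50, 5, 30), rng.normal(9, 1, 30))
        ]
        ac_singles = [
            _fake_measurement(100, tyr=t, ac=a, channel="ac")
            for t, a in zip(rng.normal(25, 3, 30), rng.normal(20, 2, 30))
        ]
        ct = estimate_crosstalk({"tyr": tyr_singles, "ac": ac_singles})
        # multiply the tyr channel everywhere by a constant
        c = 3.7
        tyr_scaled = [
            _fake_measurement(
                100, tyr=m.i_segm("tyr") * c, ac=m.i_segm("ac"),
                channel="tyr",
            )
            for m in tyr_singles
        ]
        ac_scaled = [
            _fake_measurement(
                100, tyr=m.i_segm("tyr") * c, ac=m.i_segm("ac"),
                channel="ac",
            )
            for m in ac_singles
        ]
        ct2 = estimate_crosstalk({"tyr": tyr_scaled, "ac": ac_scaled})
        assert ct2.alpha == pytest.approx(ct.alpha, rel=1e-12)
        assert ct2.beta == pytest.approx(ct.beta, rel=1e-12)

    def test_identical_sets_alpha_beta_product_one(self):
        rng = np.random.default_rng(4)
        shared = [
            _fake_measurement(100, tyr=t, ac=a)
            for t, a in zip(rng.normal(40, 4, 30), rng.normal(40, 4, 30))
        ]
        ct = estimate_crosstalk({"tyr": shared, "ac": shared})
        assert ct.alpha * ct.beta == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_single_intensity_rejected(self):
        bad = [_fake_measurement(100, tyr=0.0, ac=5.0, channel="tyr")
               for _ in range(25)]
        good = [_fake_measurement(100, tyr=5.0, ac=5.0, channel="ac")
                for _ in range(25)]
        with pytest.raises(ValueError, match="non-positive"):
            estimate_crosstalk({"tyr": bad, "ac": good})

    def test_few_singles_warns(self):
        few = [_fake_measurement(100, tyr=5.0, ac=5.0, channel="tyr")
               for _ in range(3)]
        with pytest.warns(UserWarning, match="unstable"):
            estimate_crosstalk({"tyr": few, "ac": few})


class TestSomaPipelineRecovery:
    def test_crosstalk_recovery_on_scene(self, soma_calibration_result):
        cal = soma_calibration_result
        assert abs(cal.crosstalk.alpha - 0.53) <= 0.10
        assert abs(cal.crosstalk.beta - 0.45) <= 0.10

    def test_zero_crosstalk_scene(self):
        from mtquant.pipeline import soma_calibration
        from mtquant.simgen import SceneSpec, simulate_scene

        from conftest import STED

        spec = SceneSpec(
            scene_kind="soma_sheet", n_microtubules=150, sheet_size=22.0,
            bundle_fraction=0.15, true_alpha=0.0, true_beta=0.0,
            fraction_acetylated=0.5, fraction_tyrosinated=0.5,
            fraction_other=0.0, noise_model="poisson", seed=19, **STED,
        )
        stack, _ = simulate_scene(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cal = soma_calibration(stack)
        assert cal.crosstalk.alpha <= 0.05
        assert cal.crosstalk.beta <= 0.05
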