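import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt, gaussian_filter

from conftest import circle_contour, disk_image
from mtquant.radial import (
    BoundaryParams,
    DecompositionResult,
    RadialProfile,
    average_profiles,
    convex_hull_contour,
    decompose_total,
    fit_contour,
    initial_rectangle,
    radial_profile,
    track_rectangle,
)


# ---------------------------------------------------------------------------
# independent oracle: per-pixel distance-map binning


def oracle_profile(img, contour):
    mask = contour.mask(img.shape)
    dist = distance_transform_edt(mask)
    k_max = int(np.floor(dist.max()))
    mi = []
    r_mid = []
    areas_above = [np.sum(dist > k) for k in range(k_max + 2)]
    radii = np.sqrt(np.asarray(areas_above, float) / np.pi)
    radii_n = radii / radii[0]
    for k in range(1, k_max + 2):
        ring = (dist > k - 1) & (dist <= k)
        if not ring.any():
            continue
        mi.append(img[ring].mean())
        r_mid.append(0.5 * (radii_n[k - 1] + radii_n[k]))
    mi = np.clip(np.asarray(mi), 0, None)
    r_mid = np.asarray(r_mid)
    order = np.argsort(r_mid)
    mi, r_mid = mi[order], r_mid[order]
    widths = np.empty_like(r_mid)
    edges = np.concatenate([[0.0], 0.5 * (r_mid[1:] + r_mid[:-1]), [1.0]])
    widths = np.diff(edges)
    rho = mi / np.sum(mi * widths)
    return r_mid, rho


class TestBoundaryParams:
    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            BoundaryParams(i_thr=0.0)
        with pytest.raises(ValueError):
            BoundaryParams(tracking_thresholds=(0.3, 0.1))


class TestInitialRectangle:
    def test_centered_disk(self):
        img = disk_image(101, radius=30.0)
        rect = initial_rectangle(img, BoundaryParams())
        assert abs(rect.x_lb - 20) <= 2
        assert abs(rect.x_rb - 80) <= 2
        assert abs(rect.y_tb - 20) <= 2
        assert abs(rect.y_bb - 80) <= 2

    def test_uniform_slice_is_an_error(self):
        with pytest.raises(ValueError, match="edge|zero"):
            initial_rectangle(np.full((50, 50), 3.0), BoundaryParams())

    def test_all_zero_slice(self):
        with pytest.raises(ValueError, match="all-zero"):
            initial_rectangle(np.zeros((50, 50)), BoundaryParams())

    def test_corner_distractor_outside_scan_range_ignored(self):
        # off-centre disk: the maximal centred rectangle (half-width ~30)
        # never scans the far corner where the distractor sits
        img = disk_image(101, radius=20.0, center=(30, 30))
        img[88:92, 88:92] = 500.0
        rect = initial_rectangle(img, BoundaryParams())
        assert abs(rect.x_lb - 10) <= 3
        assert abs(rect.x_rb - 50) <= 3
        assert abs(rect.y_tb - 10) <= 3


class TestTrackRectangle:
    def test_fixed_point_on_identical_slices(self):
        img = disk_image(101, radius=25.0)
        params = BoundaryParams()
        r0 = initial_rectangle(img, params)
        r1 = track_rectangle(img, r0, params)
        assert (r1.x_lb, r1.x_rb, r1.y_tb, r1.y_bb) == (
            r0.x_lb, r0.x_rb, r0.y_tb, r0.y_bb,
        )

    def test_drifting_disk_tracked(self):
        params = BoundaryParams()
        rect = initial_rectangle(
            disk_image(121, radius=20.0, center=(40, 40)), params
        )
        centers = []
        for s in range(1, 21):
            img = disk_image(121, radius=20.0, center=(40 + s, 40 + s))
            rect = track_rectangle(img, rect, params)
            centers.append(((rect.x_lb + rect.x_rb) / 2,
                            (rect.y_tb + rect.y_bb) / 2))
        drift = np.diff([c[0] for c in centers])
        assert np.all(np.abs(drift - 1.0) <= 1.5)
        assert abs(centers[-1][0] - 60) <= 2

    def test_adjacent_blob_does_not_capture_edge(self):
        params = BoundaryParams()
        base = disk_image(121, radius=20.0, center=(60, 60))
        rect0 = initial_rectangle(base, params)
        # axon-like second blob appears to the right of the dendrite
        axon = disk_image(121, radius=6.0, center=(95, 60), value=80.0)
        rect1 = track_rectangle(base + axon, rect0, params)
        assert abs(rect1.x_rb - rect0.x_rb) <= 3

    def test_no_candidates_inherits_with_flag(self):
        params = BoundaryParams()
        img = disk_image(101, radius=25.0)
        rect = initial_rectangle(img, params)
        flat = np.full_like(img, 5.0)
        flat[45:56, 45:56] = 5.0  # still uniform
        with pytest.raises(ValueError):
            track_rectangle(np.zeros_like(img), rect, params)


class TestFitContour:
    def test_disk_contour_radius_uniform(self):
        img = gaussian_filter(disk_image(101, radius=30.0), 1.0)
        params = BoundaryParams()
        rect = initial_rectangle(img, params)
        contour = fit_contour(img, rect, params)
        d = np.linalg.norm(contour.polygon - [50, 50], axis=1)
        assert np.ptp(d) / d.mean() < 2 * 0.10

    def test_ellipse_axis_ratio(self):
        ys, xs = np.mgrid[0:121, 0:121]
        img = (((xs - 60) / 40.0) ** 2 + ((ys - 60) / 20.0) ** 2 <= 1.0
               ) * 100.0
        img = gaussian_filter(img, 1.0)
        params = BoundaryParams()
        rect = initial_rectangle(img, params)
        contour = fit_contour(img, rect, params)
        poly = contour.polygon
        rx = np.ptp(poly[:, 0]) / 2
        ry = np.ptp(poly[:, 1]) / 2
        assert rx / ry == pytest.approx(2.0, abs=0.3)

    def test_degenerate_rectangle_rejected(self):
        from mtquant.radial import BoundingRect

        img = disk_image(51, radius=15.0)
        rect = BoundingRect(x_lb=24, x_rb=27, y_tb=10, y_bb=40,
                            x_c=25.0, y_c=25.0)
        with pytest.raises(ValueError, match="small"):
            fit_contour(img, rect, BoundaryParams())


class TestConvexHullContour:
    @staticmethod
    def puncta_ring(n_pts=12, radius=25.0, size=101):
        img = np.zeros((size, size))
        t = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
        for a in t:
            x = int(round(size / 2 + radius * np.cos(a)))
            y = int(round(size / 2 + radius * np.sin(a)))
            img[y, x] = 100.0
        return gaussian_filter(img, 1.5)

    def test_ring_of_puncta(self):
        img = self.puncta_ring()
        contour = convex_hull_contour(img)
        d = np.linalg.norm(contour.polygon - [50, 50], axis=1)
        assert abs(d.mean() - 25.0) <= 1.5

    def test_too_few_maxima(self):
        img = np.zeros((60, 60))
        img[30, 30] = 100.0
        img = gaussian_filter(img, 1.5)
        with pytest.raises(ValueError, match="maxima"):
            convex_hull_contour(img)

    def test_methods_agree_on_clean_disk(self):
        # a disk rendered as dense puncta: both contour routes exist
        img = gaussian_filter(disk_image(101, radius=30.0), 1.0)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, size=(600, 2))
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= 1.0] * 29.0 + 50.0
        punct = np.zeros_like(img)
        for x, y in pts:
            punct[int(round(y)), int(round(x))] += 100.0
        punct = gaussian_filter(punct, 1.2)
        params = BoundaryParams()
        rect = initial_rectangle(punct, params)
        spline = fit_contour(punct, rect, params)
        hull = convex_hull_contour(punct, threshold_rel=0.1)
        assert abs(spline.area - hull.area) / hull.area < 0.15


class TestRadialProfile:
    def test_uniform_disk_flat_density(self):
        img = disk_image(121, radius=35.0, value=50.0)
        contour = circle_contour(35.0, (60.0, 60.0))
        prof = radial_profile(img, contour)
        sel = (prof.r >= 0.1) & (prof.r <= 0.9)
        assert np.all(np.abs(prof.rho[sel] - 1.0) < 0.05)

    def test_unit_area_normalization(self):
        rng = np.random.default_rng(2)
        img = rng.poisson(40, (121, 121)).astype(float)
        contour = circle_contour(30.0, (60.0, 60.0))
        prof = radial_profile(img, contour)
        assert np.sum(prof.rho * prof.dr) == pytest.approx(1.0, abs=1e-6)

    def test_annulus_peak_position(self):
        n = 121
        ys, xs = np.mgrid[0:n, 0:n]
        r = np.hypot(xs - 60, ys - 60)
        img = (((r >= 26) & (r <= 30)) * 100.0 + (r <= 35) * 1.0)
        contour = circle_contour(35.0, (60.0, 60.0))
        prof = radial_profile(img, contour)
        peak_r = prof.r[np.argmax(prof.rho)]
        assert 0.7 <= peak_r <= 0.9

    def test_matches_distance_map_oracle(self):
        rng = np.random.default_rng(5)
        img = gaussian_filter(
            rng.poisson(30, (121, 121)).astype(float), 1.0
        )
        img += disk_image(121, radius=20.0, value=25.0)
        contour = circle_contour(32.0, (60.0, 60.0))
        prof = radial_profile(img, contour)
        r_o, rho_o = oracle_profile(img, contour)
        rho_interp = np.interp(r_o, prof.r, prof.rho)
        assert np.mean(np.abs(rho_interp - rho_o)) < 0.05

    def test_erosion_series_monotone(self):
        img = disk_image(101, radius=25.0)
        contour = circle_contour(25.0, (50.0, 50.0))
        from mtquant.radial import distance_transform_edt as edt

        mask = contour.mask(img.shape)
        dist = distance_transform_edt(mask)
        areas = [np.sum(dist > k) for k in range(int(dist.max()) + 1)]
        assert all(a > b for a, b in zip(areas, areas[1:]))

    def test_tiny_contour_rejected(self):
        img = disk_image(51, radius=10.0)
        contour = circle_contour(0.8, (25.0, 25.0))
        with pytest.raises(ValueError, match="area"):
            radial_profile(img, contour)

    def test_negative_rings_clipped_and_flagged(self):
        img = disk_image(121, radius=35.0, value=10.0)
        img[55:66, 55:66] = 0.0  # hole forces a low-intensity core ring
        rng = np.random.default_rng(1)
        img += rng.normal(0, 0.5, img.shape)
        img = np.clip(img, 0, None)
        contour = circle_contour(35.0, (60.0, 60.0))
        prof = radial_profile(img, contour)
        assert np.all(prof.rho >= 0)


class TestAverageProfiles:
    @staticmethod
    def flat_profile(level):
        r = np.linspace(0.05, 0.95, 20)
        return RadialProfile(r=r, rho=np.full_like(r, level),
                             mi=np.full_like(r, level))

    def test_identical_profiles_zero_sd(self):
        p = self.flat_profile(1.0)
        out = average_profiles([[p, p, p]])
        assert np.allclose(out["sd"], 0.0)

    def test_two_constant_profiles(self):
        out = average_profiles(
            [[self.flat_profile(0.8)], [self.flat_profile(1.2)]]
        )
        assert np.allclose(out["mean"], 1.0)
        assert np.allclose(out["sd"], 0.2, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_profiles([])


class TestDecomposition:
    @staticmethod
    def gaussians():
        r = np.linspace(0, 1, 50)
        a = np.exp(-((r - 0.3) ** 2) / 0.02)
        b = np.exp(-((r - 0.8) ** 2) / 0.02)
        a /= np.trapezoid(a, r)
        b /= np.trapezoid(b, r)
        return r, a, b

    def test_exact_mixture_recovered(self):
        _, core, shell = self.gaussians()
        total = 0.65 * core + 0.35 * shell
        res = decompose_total(total, shell, core)
        assert res.w_tyr == pytest.approx(0.35, abs=1e-9)
        assert res.w_ac == pytest.approx(0.65, abs=1e-9)
        assert res.mse < 1e-18

    def test_collinear_rejected(self):
        _, core, _ = self.gaussians()
        with pytest.raises(ValueError, match="collinear"):
            decompose_total(core, core, core)

    def test_noisy_mixture_weight_sum(self):
        r, core, shell = self.gaussians()
        rng = np.random.default_rng(12)
        total = 0.6 * core + 0.4 * shell
        noisy = total * (1 + 0.05 * rng.standard_normal(len(r)))
        noisy = np.clip(noisy, 0, None)
        noisy /= np.trapezoid(noisy, r)
        res = decompose_total(noisy, shell, core)
        assert 0.95 <= res.weight_sum <= 1.05

    def test_brute_force_optimality(self):
        r, core, shell = self.gaussians()
        rng = np.random.default_rng(3)
        total = 0.55 * core + 0.45 * shell + 0.02 * rng.standard_normal(
            len(r))
        res = decompose_total(total, shell, core)
        grid = np.linspace(0, 2, 50)
        best = np.inf
        for wt in grid:
            for wa in grid:
                mse = np.mean((total - wt * shell - wa * core) ** 2)
                best = min(best, mse)
        assert res.mse <= best + 1e-15

    def test_shape_mismatch(self):
        _, core, shell = self.gaussians()
        with pytest.raises(ValueError, match="grid"):
            decompose_total(core[:-1], shell, core)


class TestCoreShellScene:
    def test_ac_peaks_inward_of_tyr(self):
        """End-to-end: biased dendrite -> reslice -> profiles -> ordering."""
        import warnings

        from mtquant.pipeline import radial_workflow, yz_slice_series
        from mtquant.simgen import SceneSpec, simulate_scene

        spec = SceneSpec(
            scene_kind="dendrite", dendrite_diameter=1.2,
            dendrite_length=4.0, n_microtubules=60,
            fraction_acetylated=0.5, fraction_tyrosinated=0.5,
            fraction_other=0.0, radial_bias=1.0, orientation="flipped",
            noise_model="poisson", background_level=5.0,
            filament_photons=40000.0, psf_sigma_lateral=0.10,
            psf_sigma_axial=0.30, voxel_size=(0.06, 0.06, 0.06),
            expansion_factor=4.15, seed=3,
        )
        stack, _ = simulate_scene(spec)
        resliced = yz_slice_series(stack, trim=12, step=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = radial_workflow(
                resliced,
                BoundaryParams(i_thr=0.3, reference_channel="total"),
            )
        av = out["averaged"]
        r = av["ac"]["r"]
        ac_peak = r[np.argmax(av["ac"]["mean"])]
        tyr_peak = r[np.argmax(av["tyr"]["mean"])]
        assert ac_peak < tyr_peak
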