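"""Radial intensity distribution in dendrite cross-sections.

Per YZ slice: a bounding rectangle is found by scanning normalized edge
intensity derivatives inward from each side; subsequent slices track the
rectangle against the previous slice using a multi-threshold candidate
search.  Two diagonal boundary points per diagonal complete an ordered set
of eight anchors through which a periodic cubic spline is drawn (a convex
hull of local maxima is the low-background alternative).  The contour is
then shrunk iteratively via the Euclidean distance map; ring mean
intensities

    MI_k = (IC_k - IC_{k-1}) / (S_k - S_{k-1})

against the normalized equivalent-circle radius ``R_k = sqrt(S_k / pi)``
give the radial density rho(R) after unit-area normalization.  The total
density decomposes into tyrosinated and acetylated components by
closed-form least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import splev, splprep
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import polygon2mask
from skimage.feature import peak_local_max


@dataclass
class BoundaryParams:
    i_thr: float = 0.3  # first-slice normalized edge threshold
    tracking_thresholds: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    diagonal_fraction: float = 0.175
    diagonal_width: float = 20.0  # pixels, width of the diagonal profile band
    reference_channel: str = "tyr"

    def __post_init__(self) -> None:
        ts = tuple(self.tracking_thresholds)
        if any(not 0 < t < 1 for t in (self.i_thr, *ts)):
            raise ValueError("thresholds must lie in (0, 1)")
        if list(ts) != sorted(ts):
            raise ValueError("tracking thresholds must be sorted ascending")
        self.tracking_thresholds = ts


@dataclass
class BoundingRect:
    x_lb: int
    x_rb: int
    y_tb: int
    y_bb: int
    x_c: float
    y_c: float
    flags: list[str] = field(default_factory=list)
    edge_profiles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.x_lb < self.x_c < self.x_rb
                and self.y_tb < self.y_c < self.y_bb):
            raise ValueError(
                f"degenerate rectangle ({self.x_lb},{self.x_rb},"
                f"{self.y_tb},{self.y_bb}) around ({self.x_c},{self.y_c})"
            )

    @property
    def width(self) -> int:
        return self.x_rb - self.x_lb

    @property
    def height(self) -> int:
        return self.y_bb - self.y_tb


@dataclass
class ClosedContour:
    anchors: np.ndarray  # (8, 2) ordered (x, y)
    polygon: np.ndarray  # densely sampled periodic spline, (M, 2)
    flags: list[str] = field(default_factory=list)

    @property
    def area(self) -> float:
        """Shoelace area of the spline polygon (sub-pixel)."""
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return float(
            0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        )

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        return polygon2mask(shape, self.polygon[:, ::-1])


@dataclass
class RadialProfile:
    r: np.ndarray  # ascending normalized radius (ring midpoints)
    rho: np.ndarray  # unit-area density on r
    mi: np.ndarray  # raw ring mean intensities
    dr: np.ndarray = None  # ring widths; sum(rho * dr) == 1
    channel: str = ""
    clipped: bool = False  # negative ring intensities were clipped to 0


@dataclass
class DecompositionResult:
    w_tyr: float
    w_ac: float
    mse: float

    @property
    def weight_sum(self) -> float:
        return self.w_tyr + self.w_ac


# ---------------------------------------------------------------------------
# bounding rectangle


def _strip_sums(img: np.ndarray, x_c: float, y_c: float, axis: int,
                direction: int) -> np.ndarray:
    """Sum of single-pixel strips from the centre toward one rect edge.

    The scan is confined to the maximal rectangle centred on
    ``(x_c, y_c)`` that fits inside the image, in both dimensions.
    ``axis=1`` scans columns (left/right edges), ``axis=0`` rows;
    ``direction`` is +1 toward the high-index edge, -1 toward zero.
    """
    ny, nx = img.shape
    hw_x = min(x_c, nx - 1 - x_c)
    hw_y = min(y_c, ny - 1 - y_c)
    x0, x1 = int(np.ceil(x_c - hw_x)), int(np.floor(x_c + hw_x))
    y0, y1 = int(np.ceil(y_c - hw_y)), int(np.floor(y_c + hw_y))
    sub = img[y0:y1 + 1, x0:x1 + 1]
    sums = sub.sum(axis=1 - axis)
    c = int(round((x_c - x0) if axis == 1 else (y_c - y0)))
    if direction > 0:
        return sums[c:]
    return sums[c::-1]


def _normalize(p: np.ndarray) -> np.ndarray:
    lo, hi = p.min(), p.max()
    if hi <= lo:
        return np.zeros_like(p)
    return (p - lo) / (hi - lo)


def _first_edge(p_norm: np.ndarray, thr: float) -> int | None:
    """Scanning inward from the border, the first strip above threshold."""
    for j in range(len(p_norm) - 1, -1, -1):
        if p_norm[j] > thr:
            return j
    return None


def _edge_candidates(p_norm: np.ndarray,
                     thresholds: tuple[float, ...]) -> list[int]:
    """All threshold-crossing positions, scanning in both directions."""
    cands: set[int] = set()
    for thr in thresholds:
        above = p_norm >= thr
        for j in range(len(above) - 1):
            if above[j] != above[j + 1]:
                cands.add(j + 1 if above[j + 1] else j)
        j_in = _first_edge(p_norm, thr)
        if j_in is not None:
            cands.add(j_in)
    return sorted(cands)


def initial_rectangle(slice2d: np.ndarray,
                      params: BoundaryParams) -> BoundingRect:
    """First-slice bounding rectangle from normalized edge derivatives."""
    img = np.asarray(slice2d, dtype=float)
    total = img.sum()
    if total <= 0:
        raise ValueError("all-zero slice; no rectangle can be found")
    ny, nx = img.shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    x_c = float((img * xs).sum() / total)
    y_c = float((img * ys).sum() / total)

    edges = {}
    profiles = {}
    for name, axis, direction, center in (
        ("right", 1, +1, x_c),
        ("left", 1, -1, x_c),
        ("bottom", 0, +1, y_c),
        ("top", 0, -1, y_c),
    ):
        p = _normalize(_strip_sums(img, x_c, y_c, axis, direction))
        profiles[name] = p
        j = _first_edge(p, params.i_thr)
        if j is None or j == 0:
            raise ValueError(
                f"no {name} edge found above I_thr={params.i_thr}; "
                "try lowering the threshold"
            )
        edges[name] = int(round(center)) + direction * j
    rect = BoundingRect(
        x_lb=edges["left"], x_rb=edges["right"],
        y_tb=edges["top"], y_bb=edges["bottom"],
        x_c=x_c, y_c=y_c, edge_profiles=profiles,
    )
    return rect


def track_rectangle(slice2d: np.ndarray, previous: BoundingRect,
                    params: BoundaryParams) -> BoundingRect:
    """Rectangle for a subsequent slice, anchored to the previous one.

    Candidate edges are collected at every tracking threshold while
    scanning in both directions; the candidate closest to the previous
    slice's edge wins, ties broken toward the larger rectangle.  An edge
    with no candidates inherits the previous position and is flagged.
    """
    img = np.asarray(slice2d, dtype=float)
    total = img.sum()
    if total <= 0:
        raise ValueError("all-zero slice")
    ny, nx = img.shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    x_c = float((img * xs).sum() / total)
    y_c = float((img * ys).sum() / total)

    prev_edges = {
        "right": previous.x_rb, "left": previous.x_lb,
        "bottom": previous.y_bb, "top": previous.y_tb,
    }
    flags = []
    edges = {}
    for name, axis, direction, center in (
        ("right", 1, +1, x_c),
        ("left", 1, -1, x_c),
        ("bottom", 0, +1, y_c),
        ("top", 0, -1, y_c),
    ):
        p = _normalize(_strip_sums(img, x_c, y_c, axis, direction))
        cands = _edge_candidates(p, params.tracking_thresholds)
        positions = [int(round(center)) + direction * j for j in cands if j > 0]
        if not positions:
            edges[name] = prev_edges[name]
            flags.append(f"inherited_{name}")
            continue
        prev = prev_edges[name]
        dist = np.abs(np.asarray(positions) - prev)
        best = dist.min()
        # tie-break toward the larger rectangle (outermost position)
        tied = [pos for pos, d in zip(positions, dist) if d == best]
        edges[name] = max(tied, key=lambda pos: direction * pos)
    return BoundingRect(
        x_lb=edges["left"], x_rb=edges["right"],
        y_tb=edges["top"], y_bb=edges["bottom"],
        x_c=x_c, y_c=y_c, flags=flags,
    )


# ---------------------------------------------------------------------------
# closed contour


def _diagonal_points(img: np.ndarray, p_from: np.ndarray, p_to: np.ndarray,
                     fraction: float, band_width: float
                     ) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Boundary points on both halves of a wide diagonal profile.

    The band intensity profile is min-max normalized; on each half the
    sample closest to ``fraction`` of the maximum marks the boundary.
    """
    from scipy.ndimage import map_coordinates

    length = np.linalg.norm(p_to - p_from)
    n = max(int(np.ceil(length)), 8)
    t = np.linspace(0, 1, n)
    line = p_from[None] + t[:, None] * (p_to - p_from)[None]
    d = (p_to - p_from) / length
    normal = np.array([-d[1], d[0]])
    half = band_width / 2.0
    offsets = np.arange(-np.floor(half), np.floor(half) + 1)
    xs = line[:, 0][:, None] + offsets[None] * normal[0]
    ys = line[:, 1][:, None] + offsets[None] * normal[1]
    vals = map_coordinates(img, [ys.ravel(), xs.ravel()], order=1,
                           mode="nearest").reshape(xs.shape)
    profile = _normalize(vals.mean(axis=1))
    mid = n // 2
    halves = []
    for idx in (np.arange(0, mid), np.arange(mid, n)):
        seg = profile[idx]
        if seg.max() < fraction:  # never reaches the level
            halves.append(None)
            continue
        j = idx[int(np.argmin(np.abs(seg - fraction)))]
        halves.append(line[j])
    return halves[0], halves[1]


def _periodic_spline(anchors: np.ndarray, n_samples: int = 256) -> np.ndarray:
    pts = np.asarray(anchors, float)
    closed = np.vstack([pts, pts[:1]])
    tck, _ = splprep(closed.T, s=0, per=True, k=3)
    u = np.linspace(0, 1, n_samples, endpoint=False)
    return np.column_stack(splev(u, tck))


def fit_contour(slice2d: np.ndarray, rect: BoundingRect,
                params: BoundaryParams) -> ClosedContour:
    """8-anchor periodic spline through rectangle and diagonal boundaries."""
    if rect.width < 4 or rect.height < 4:
        raise ValueError(f"rectangle too small ({rect.width}x{rect.height})")
    img = np.asarray(slice2d, dtype=float)
    x_c, y_c = rect.x_c, rect.y_c
    lt = np.array([rect.x_lb, rect.y_tb], float)
    rb = np.array([rect.x_rb, rect.y_bb], float)
    lb = np.array([rect.x_lb, rect.y_bb], float)
    rt = np.array([rect.x_rb, rect.y_tb], float)
    width = min(params.diagonal_width, rect.width / 2, rect.height / 2)
    flags = []
    ld1, ld2 = _diagonal_points(img, lt, rb, params.diagonal_fraction, width)
    rd2, rd1 = _diagonal_points(img, lb, rt, params.diagonal_fraction, width)
    if ld1 is None:
        ld1 = (lt + np.array([x_c, y_c])) / 2
        flags.append("diagonal_fallback_ld1")
    if ld2 is None:
        ld2 = (rb + np.array([x_c, y_c])) / 2
        flags.append("diagonal_fallback_ld2")
    if rd2 is None:
        rd2 = (lb + np.array([x_c, y_c])) / 2
        flags.append("diagonal_fallback_rd2")
    if rd1 is None:
        rd1 = (rt + np.array([x_c, y_c])) / 2
        flags.append("diagonal_fallback_rd1")
    anchors = np.array([
        [rect.x_lb, y_c],
        ld1,
        [x_c, rect.y_tb],
        rd1,
        [rect.x_rb, y_c],
        ld2,
        [x_c, rect.y_bb],
        rd2,
    ], dtype=float)
    polygon = _periodic_spline(anchors)
    return ClosedContour(anchors=anchors, polygon=polygon, flags=flags)


def convex_hull_contour(
    slice2d: np.ndarray,
    min_distance: int = 3,
    threshold_rel: float = 0.2,
    smooth_sigma: float = 1.0,
) -> ClosedContour:
    """Spline through the convex hull of local intensity maxima.

    Fast alternative for low-background data where microtubule
    cross-sections appear as distinct puncta.
    """
    img = gaussian_filter(np.asarray(slice2d, float), smooth_sigma)
    peaks = peak_local_max(
        img, min_distance=min_distance, threshold_rel=threshold_rel
    )
    if len(peaks) < 3:
        raise ValueError(
            f"need >= 3 local maxima for a hull, found {len(peaks)}"
        )
    pts_xy = peaks[:, ::-1].astype(float)
    try:
        hull = ConvexHull(pts_xy)
    except QhullError as exc:
        raise ValueError(f"degenerate (collinear) hull: {exc}") from exc
    anchors = pts_xy[hull.vertices]
    polygon = _periodic_spline(anchors)
    return ClosedContour(anchors=anchors, polygon=polygon)


# ---------------------------------------------------------------------------
# radial profile by contour erosion


def radial_profile(
    slice2d: np.ndarray,
    contour: ClosedContour,
    channel: str = "",
    min_area: int = 4,
) -> RadialProfile:
    """Shrink the contour via the Euclidean distance map; density vs radius.

    Step ``k`` keeps pixels deeper than ``k`` from the boundary; ring mean
    intensities are mapped to the normalized equivalent-circle radius and
    normalized to unit discrete area.  Negative ring means (noise) are
    clipped to zero and flagged.
    """
    img = np.asarray(slice2d, dtype=float)
    mask0 = contour.mask(img.shape)
    if int(mask0.sum()) < min_area:
        raise ValueError(f"contour area {int(mask0.sum())} px < {min_area}")
    dist = distance_transform_edt(mask0)
    s_list = []
    ic_list = []
    k = 0
    while True:
        mk = dist > k
        s = int(mk.sum())
        if s == 0:
            break
        s_list.append(s)
        ic_list.append(float(img[mk].sum()))
        k += 1
    s_arr = np.asarray(s_list, dtype=float)
    ic_arr = np.asarray(ic_list, dtype=float)
    radii = np.sqrt(s_arr / np.pi)
    r_norm = radii / radii[0]

    # ring k lies between contours k-1 and k
    d_ic = ic_arr[:-1] - ic_arr[1:]
    d_s = s_arr[:-1] - s_arr[1:]
    valid = d_s > 0
    mi = d_ic[valid] / d_s[valid]
    r_outer = r_norm[:-1][valid]
    r_inner = r_norm[1:][valid]
    r_mid = 0.5 * (r_outer + r_inner)
    # innermost disk (below the last contour) forms the final "ring"
    if s_arr[-1] > 0:
        mi = np.append(mi, ic_arr[-1] / s_arr[-1])
        r_mid = np.append(r_mid, 0.5 * r_norm[-1])
        r_outer = np.append(r_outer, r_norm[-1])
        r_inner = np.append(r_inner, 0.0)

    clipped = bool(np.any(mi < 0))
    mi = np.clip(mi, 0, None)
    widths = r_outer - r_inner
    norm = float(np.sum(mi * widths))
    if norm <= 0:
        raise ValueError("profile has zero integrated intensity")
    rho = mi / norm

    order = np.argsort(r_mid)
    return RadialProfile(
        r=r_mid[order], rho=rho[order], mi=mi[order], dr=widths[order],
        channel=channel, clipped=clipped,
    )


def average_profiles(
    profiles_by_dendrite: list[list[RadialProfile]],
    n_grid: int = 50,
) -> dict[str, np.ndarray]:
    """Average profiles per dendrite first, then across dendrites.

    Returns the common R grid, the grand mean, the within-dendrite SD and
    the across-dendrite SEM.
    """
    if not profiles_by_dendrite or not any(profiles_by_dendrite):
        raise ValueError("no profiles to average")
    grid = np.linspace(0.0, 1.0, n_grid)
    dendrite_means = []
    all_interp = []
    for profiles in profiles_by_dendrite:
        if not profiles:
            continue
        interp = np.stack([
            np.interp(grid, p.r, p.rho) for p in profiles
        ])
        all_interp.append(interp)
        dendrite_means.append(interp.mean(axis=0))
    dm = np.stack(dendrite_means)
    pooled = np.concatenate(all_interp, axis=0)
    mean = dm.mean(axis=0)
    sd = pooled.std(axis=0, ddof=0)
    sem = (
        dm.std(axis=0, ddof=1) / np.sqrt(len(dm))
        if len(dm) > 1
        else np.zeros_like(mean)
    )
    return {"r": grid, "mean": mean, "sd": sd, "sem": sem}


# ---------------------------------------------------------------------------
# two-component decomposition


def decompose_total(
    rho_tot: np.ndarray,
    rho_tyr: np.ndarray,
    rho_ac: np.ndarray,
) -> DecompositionResult:
    """Closed-form least-squares weights of the two-component mixture.

    Solves the normal equations of
    ``sum_R (rho_tot - w_tyr rho_tyr - w_ac rho_ac)^2`` with no constraint
    on the weights; angle brackets below are means over the R grid::

        w_ac  = (<tot*ac><tyr^2> - <tot*tyr><tyr*ac>)
                / (<tyr^2><ac^2> - <tyr*ac>^2)
        w_tyr = (<tot*tyr> - w_ac <tyr*ac>) / <tyr^2>
    """
    t = np.asarray(rho_tot, float)
    y = np.asarray(rho_tyr, float)
    a = np.asarray(rho_ac, float)
    if not t.shape == y.shape == a.shape:
        raise ValueError("profiles must share the same R grid")
    m = lambda u: float(np.mean(u))  # noqa: E731
    denom = m(y * y) * m(a * a) - m(y * a) ** 2
    scale = m(y * y) * m(a * a)
    if abs(denom) < 1e-12 * max(scale, 1e-300):
        raise ValueError(
            "tyr and ac profiles are collinear; weights are not identifiable"
        )
    w_ac = (m(t * a) * m(y * y) - m(t * y) * m(y * a)) / denom
    w_tyr = (m(t * y) - w_ac * m(y * a)) / m(y * y)
    resid = t - w_tyr * y - w_ac * a
    return DecompositionResult(
        w_tyr=float(w_tyr), w_ac=float(w_ac), mse=float(np.mean(resid**2))
    )
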