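"""Soma-stage single-filament analysis.

Detects curvilinear microtubule segments on per-channel maximum-intensity
projections, quantifies dual-width background-corrected intensities on the
matching sum projections, fits the two-Gaussian single-filament intensity
model, filters out bundles, and estimates the modification crosstalk
coefficients alpha and beta.

Background correction: for a polyline tube of width ``w_microtubule``
(integrated intensity ``I_mid`` over ``S_mid`` pixels) and a wider tube of
width ``w_wide`` (``I_wide`` over ``S_wide``),

    I_BG   = (I_wide - I_mid) / (S_wide - S_mid)
    I_segm = I_mid / S_mid - I_BG

``I_segm`` is the background-corrected mean intensity along the filament
and does not depend on segment length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit
from skimage.draw import polygon2mask
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import skeletonize

from mtquant.rois import PolylineRoi
from mtquant.stack import ChannelStack

QUANT_CHANNELS = ("total", "tyr", "ac")


class SegmentBorderError(ValueError):
    """Segment's wide tube leaves the image; the segment must be excluded."""


class FitError(RuntimeError):
    """Histogram fit failed; carries diagnostics in ``args``."""


@dataclass
class FilamentSegment:
    detection_channel: str
    vertices: np.ndarray  # ordered (x, y) pixel coordinates
    length_um: float
    source: str = "internal_detector"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if len(self.vertices) < 2:
            raise ValueError("segment needs >= 2 vertices")


@dataclass
class ChannelIntensity:
    I_mid: float
    I_wide: float
    S_mid: int
    S_wide: int
    I_BG: float
    I_segm: float


@dataclass
class SegmentIntensity:
    """Dual-width intensities of one segment in every quantification channel."""

    segment: FilamentSegment
    channels: dict[str, ChannelIntensity]

    def i_segm(self, channel: str) -> float:
        return self.channels[channel].I_segm


@dataclass
class SingleIntensityFit:
    """Two-Gaussian model of the pooled segment-intensity histogram.

    The second component is the self-convolution of the first: mean
    ``2 * i_single`` and variance ``2 * sigma_single**2``.
    """

    a1: float
    a2: float
    i_single: float
    sigma_single: float
    residual_norm: float
    n: int
    bin_width: float

    @property
    def single_threshold(self) -> float:
        return self.i_single + self.sigma_single


@dataclass
class CrosstalkCoefficients:
    i_tyr: float
    i_ac: float
    alpha: float
    beta: float
    n_segments: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# projections


def select_substack(
    stack: ChannelStack, z_range: tuple[int, int]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Return (MIP images, sum images) per channel over ``z_range``.

    ``z_range`` is a half-open slice ``(z0, z1)``; detection uses the
    maximum projection, quantification the sum projection of the same
    slices.
    """
    z0, z1 = z_range
    nz = stack.shape[0]
    z0, z1 = int(z0), int(z1)
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"empty or out-of-range z_range {z_range} for nz={nz}")
    mips = {}
    sums = {}
    for name in stack.channel_names:
        sub = stack.channel(name)[z0:z1]
        mips[name] = sub.max(axis=0)
        sums[name] = sub.sum(axis=0)
    return mips, sums


# ---------------------------------------------------------------------------
# detection


def _skeleton_arcs(skel: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Split a skeleton into simple arcs.

    Returns ordered (row, col) paths and the junction-pixel positions at
    which the skeleton was broken.
    """
    from scipy.ndimage import convolve, label

    nb = convolve(skel.astype(int), np.ones((3, 3)), mode="constant") - skel
    junctions = np.argwhere(skel & (nb > 2))
    arcs_mask = skel & (nb <= 2)
    lbl, n = label(arcs_mask, structure=np.ones((3, 3)))
    paths = []
    for i in range(1, n + 1):
        pts = np.argwhere(lbl == i)
        if len(pts) < 2:
            continue
        paths.append(_order_path(pts))
    return paths, junctions


def _trim_junction_ends(path: np.ndarray, junctions: np.ndarray,
                        trim: int, reach: float = 3.0) -> np.ndarray:
    """Drop `trim` pixels from arc ends that abut a junction.

    Pixels around filament crossings carry summed intensity from both
    filaments; excluding them keeps per-segment intensities single-like.
    """
    if len(junctions) == 0 or trim <= 0:
        return path
    out = path
    for end in (0, -1):
        d = np.min(np.linalg.norm(junctions - out[end], axis=1))
        if d <= reach:
            out = out[trim:] if end == 0 else out[:-trim]
            if len(out) < 2:
                return out
    return out


def _order_path(pts: np.ndarray) -> np.ndarray:
    """Greedy nearest-neighbour ordering of arc pixels from an endpoint."""
    pts_set = {tuple(p) for p in pts}
    # endpoint: pixel with exactly one 8-neighbour in the set
    start = None
    for p in map(tuple, pts):
        nn = sum(
            (p[0] + dr, p[1] + dc) in pts_set
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        )
        if nn == 1:
            start = p
            break
    if start is None:  # small loop; pick any
        start = tuple(pts[0])
    ordered = [start]
    pts_set.discard(start)
    while pts_set:
        r, c = ordered[-1]
        candidates = [
            (r + dr, c + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0) and (r + dr, c + dc) in pts_set
        ]
        if not candidates:
            break
        nxt = min(candidates, key=lambda q: abs(q[0] - r) + abs(q[1] - c))
        ordered.append(nxt)
        pts_set.discard(nxt)
    return np.asarray(ordered)


def _smooth_vertices(verts: np.ndarray, window: int = 9) -> np.ndarray:
    """Sub-pixel smoothing of an ordered pixel chain (clipped moving mean)."""
    n = len(verts)
    if n <= 2:
        return verts
    half = window // 2
    out = np.empty_like(verts)
    for i in range(n):
        lo = max(i - half, 0)
        hi = min(i + half + 1, n)
        out[i] = verts[lo:hi].mean(axis=0)
    return out


def detect_segments(
    mip_image: np.ndarray,
    pixel_size: float,
    line_width: float = 2.5,
    min_length_um: float = 0.6,
    mask: PolylineRoi | None = None,
    detection_channel: str = "total",
    threshold: float | None = None,
    threshold_method: str = "otsu",
    junction_trim: int = 4,
) -> list[FilamentSegment]:
    """Trace ridge-like curvilinear segments on a 2D detection image.

    A deliberately simple stand-in for a full curvilinear detector: the
    image is smoothed at the expected line width, thresholded
    (Otsu by default; ``multiotsu`` takes the upper of two thresholds,
    useful when a channel shows background, crosstalk-dim and native-bright
    filament populations), skeletonized, split at junctions and traced into
    ordered polylines.  Segments shorter than ``min_length_um`` are dropped.
    Externally produced ROIs can bypass this entirely via
    :func:`segments_from_rois`.
    """
    img = np.asarray(mip_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detection image must be 2D")
    smoothed = gaussian_filter(img, line_width / 2.0)
    if threshold is None:
        if smoothed.max() <= smoothed.min():
            return []
        if threshold_method == "multiotsu":
            threshold = float(threshold_multiotsu(smoothed, classes=3)[-1])
        elif threshold_method == "otsu":
            threshold = float(threshold_otsu(smoothed))
        elif threshold_method == "foreground_otsu":
            # two-stage: split background/foreground, then split the
            # foreground again — separates crosstalk-dim foreign filaments
            # from the channel's native bright population.
            t1 = float(threshold_otsu(smoothed))
            fg_vals = smoothed[smoothed > t1]
            if fg_vals.size < 2 or fg_vals.max() <= fg_vals.min():
                threshold = t1
            else:
                threshold = float(threshold_otsu(fg_vals))
        else:
            raise ValueError(f"unknown threshold_method {threshold_method!r}")
    fg = smoothed > threshold
    if mask is not None:
        poly_rc = mask.vertices[:, ::-1]  # (x, y) -> (row, col)
        fg &= polygon2mask(img.shape, poly_rc)
    if not fg.any():
        return []
    skel = skeletonize(fg)
    segments = []
    paths, junctions = _skeleton_arcs(skel)
    for path_rc in paths:
        path_rc = _trim_junction_ends(path_rc, junctions, trim=junction_trim)
        if len(path_rc) < 2:
            continue
        verts = path_rc[:, ::-1].astype(float)  # (row, col) -> (x, y)
        # pixel chains staircase at +-0.5 px; smoothing the chain keeps the
        # measurement tube straight instead of inflating it along the jags
        verts = _smooth_vertices(verts)
        length = float(
            np.sum(np.linalg.norm(np.diff(verts, axis=0), axis=1))
        ) * pixel_size
        if length < min_length_um:
            continue
        segments.append(
            FilamentSegment(detection_channel, verts, length)
        )
    return segments


def segments_from_rois(
    rois: list[PolylineRoi],
    pixel_size: float,
    detection_channel: str,
    min_length_um: float = 0.6,
) -> list[FilamentSegment]:
    """Wrap imported (e.g. ImageJ) polyline ROIs as first-class segments."""
    out = []
    for roi in rois:
        length = roi.length * pixel_size
        if length < min_length_um:
            continue
        out.append(
            FilamentSegment(
                detection_channel, roi.vertices, length, source="imported_roi"
            )
        )
    return out


# ---------------------------------------------------------------------------
# intensity measurement


def tube_mask(shape: tuple[int, int], vertices: np.ndarray,
              width: float) -> np.ndarray:
    """Pixels whose centre lies within ``width/2`` of the polyline.

    Deterministic rasterization matching ImageJ line-ROI semantics closely;
    the same rule is used by the brute-force oracle in the tests.
    """
    verts = np.asarray(vertices, dtype=float)
    half = width / 2.0
    ny, nx = shape
    x0 = max(int(np.floor(verts[:, 0].min() - half - 1)), 0)
    x1 = min(int(np.ceil(verts[:, 0].max() + half + 1)) + 1, nx)
    y0 = max(int(np.floor(verts[:, 1].min() - half - 1)), 0)
    y1 = min(int(np.ceil(verts[:, 1].max() + half + 1)) + 1, ny)
    if x0 >= x1 or y0 >= y1:
        return np.zeros(shape, dtype=bool)
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    px = xs.astype(float)
    py = ys.astype(float)
    dmin = np.full(px.shape, np.inf)
    for a, b in zip(verts[:-1], verts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            dx, dy = px - a[0], py - a[1]
            d2 = dx * dx + dy * dy
        else:
            t = ((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom
            t = np.clip(t, 0.0, 1.0)
            dx = px - (a[0] + t * ab[0])
            dy = py - (a[1] + t * ab[1])
            d2 = dx * dx + dy * dy
        dmin = np.minimum(dmin, d2)
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = dmin <= half * half
    return out


def _tube_touches_border(shape: tuple[int, int], vertices: np.ndarray,
                         width: float) -> bool:
    half = width / 2.0
    verts = np.asarray(vertices, dtype=float)
    ny, nx = shape
    return bool(
        verts[:, 0].min() - half < 0
        or verts[:, 0].max() + half > nx - 1
        or verts[:, 1].min() - half < 0
        or verts[:, 1].max() + half > ny - 1
    )


def measure_segment(
    sum_images: dict[str, np.ndarray],
    segment: FilamentSegment,
    w_microtubule: float = 6.0,
    w_wide: float = 13.0,
) -> SegmentIntensity:
    """Dual-width background-corrected intensities in every channel.

    Raises :class:`SegmentBorderError` when the wide tube leaves the image,
    so border segments are excluded rather than measured with truncated
    background.
    """
    shape = next(iter(sum_images.values())).shape
    if _tube_touches_border(shape, segment.vertices, w_wide):
        raise SegmentBorderError(
            "segment tube touches the image border; excluded"
        )
    mid = tube_mask(shape, segment.vertices, w_microtubule)
    wide = tube_mask(shape, segment.vertices, w_wide)
    s_mid = int(mid.sum())
    s_wide = int(wide.sum())
    if not s_wide > s_mid > 0:
        raise SegmentBorderError(
            f"degenerate tube areas S_mid={s_mid}, S_wide={s_wide}"
        )
    channels = {}
    for name, img in sum_images.items():
        i_mid = float(img[mid].sum())
        i_wide = float(img[wide].sum())
        i_bg = (i_wide - i_mid) / (s_wide - s_mid)
        i_segm = i_mid / s_mid - i_bg
        channels[name] = ChannelIntensity(
            I_mid=i_mid, I_wide=i_wide, S_mid=s_mid, S_wide=s_wide,
            I_BG=i_bg, I_segm=i_segm,
        )
    return SegmentIntensity(segment=segment, channels=channels)


def measure_segments(
    sum_images: dict[str, np.ndarray],
    segments: list[FilamentSegment],
    w_microtubule: float = 6.0,
    w_wide: float = 13.0,
) -> tuple[list[SegmentIntensity], int]:
    """Measure many segments, silently skipping border-flagged ones.

    Returns the measurements and the number excluded.
    """
    out = []
    excluded = 0
    for seg in segments:
        try:
            out.append(measure_segment(sum_images, seg, w_microtubule, w_wide))
        except SegmentBorderError:
            excluded += 1
    return out, excluded


# ---------------------------------------------------------------------------
# two-Gaussian intensity model


def _two_gaussian(i, a1, a2, i1, sigma):
    g1 = a1 * np.exp(-((i - i1) ** 2) / (2 * sigma**2))
    g2 = a2 * np.exp(-((i - 2 * i1) ** 2) / (4 * sigma**2))
    return g1 + g2


def fit_single_intensity(
    intensities: np.ndarray | list[float],
    bins: str | int = "fd",
) -> SingleIntensityFit:
    """Fit the binned intensity histogram with a singles+doublets model.

    The doublet component is the analytic self-convolution of the singles
    Gaussian (mean doubled, variance doubled).  Initial guesses: histogram
    mode for the singles mean, half the interquartile range for sigma, the
    mass above 1.5x the mode for the doublet amplitude.
    """
    values = np.asarray(intensities, dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    if n < 3:
        raise FitError(f"too few intensities to fit (n={n})")
    if n < 100:
        warnings.warn(
            f"fitting a two-Gaussian model to only n={n} intensities",
            stacklevel=2,
        )
    if np.ptp(values) == 0 or np.std(values) == 0:
        raise FitError("zero-variance intensities; sigma would degenerate")

    base_edges = np.histogram_bin_edges(values, bins=bins)
    bin_width = float(base_edges[1] - base_edges[0])
    counts0, _ = np.histogram(values, bins=base_edges)
    mode = float(
        0.5 * (base_edges[:-1] + base_edges[1:])[np.argmax(counts0)]
    )
    # extend the binning past twice the singles peak so that an absent
    # doublet population pins a2 to ~0 instead of leaving it unconstrained
    hi_edge = max(float(values.max()), 2.4 * mode) + bin_width
    edges = np.arange(float(values.min()), hi_edge, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if mode <= 0:
        mode = float(np.median(values))
    q75, q25 = np.percentile(values, [75, 25])
    sigma0 = max((q75 - q25) / 2.0, bin_width)
    a1_0 = float(counts.max())
    frac_high = float(np.mean(values > 1.5 * mode))
    a2_0 = max(a1_0 * frac_high, 1e-3)
    p0 = (a1_0, a2_0, mode, sigma0)
    # anchor the singles mean near the histogram mode; otherwise the
    # optimizer can park the doublet component on the singles peak
    # (i1 = mode/2), which fits equally well but is meaningless
    lo = (0.0, 0.0, 0.6 * mode, 1e-12)
    hi = (np.inf, np.inf, 1.5 * mode, np.inf)
    try:
        popt, _ = curve_fit(
            _two_gaussian, centers, counts, p0=p0, bounds=(lo, hi),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            f"two-Gaussian fit failed: {exc}; n={n}, p0={p0}"
        ) from exc
    a1, a2, i1, sigma = (float(v) for v in popt)
    resid = counts - _two_gaussian(centers, *popt)
    if i1 <= 0 or sigma <= 0:
        raise FitError(f"non-positive fitted parameters: I={i1}, sigma={sigma}")
    return SingleIntensityFit(
        a1=a1, a2=a2, i_single=i1, sigma_single=sigma,
        residual_norm=float(np.linalg.norm(resid)), n=n, bin_width=bin_width,
    )


def filter_singles(
    measurements: list[SegmentIntensity],
    fit: SingleIntensityFit,
    total_channel: str = "total",
) -> tuple[list[SegmentIntensity], dict[str, int]]:
    """Keep segments whose total-channel intensity is strictly below
    ``i_single + sigma_single`` (bundles are discarded)."""
    thr = fit.single_threshold
    kept = [m for m in measurements if m.i_segm(total_channel) < thr]
    report = {"kept": len(kept), "discarded": len(measurements) - len(kept)}
    return kept, report


def select_native_singles(
    singles: list[SegmentIntensity],
    channel: str,
    min_split: int = 6,
) -> list[SegmentIntensity]:
    """Keep the segments natively bright in their detection channel.

    A permissive detection threshold in the tyr/ac channels also picks up
    the other subset's crosstalk-dim filaments (emitting only a fraction
    of the native level).  Segment-level intensities cluster at the
    native and crosstalk levels, so an Otsu split of the detection-channel
    intensities separates them; the upper class is returned.  With fewer
    than ``min_split`` segments, or a degenerate distribution, the input
    is returned unchanged.
    """
    if len(singles) < min_split:
        return singles
    values = np.array([m.i_segm(channel) for m in singles])
    if np.ptp(values) <= 0:
        return singles
    try:
        thr = float(threshold_otsu(values))
    except ValueError:
        return singles
    kept = [m for m, v in zip(singles, values) if v > thr]
    return kept if len(kept) >= 2 else singles


def estimate_crosstalk(
    singles_by_channel: dict[str, list[SegmentIntensity]],
    min_singles: int = 20,
) -> CrosstalkCoefficients:
    """Estimate alpha and beta from threshold-filtered single segments.

    ``i_tyr``/``i_ac`` are the mean same-channel intensities of singles
    detected in the tyr/ac channel; alpha is the mean tyr-channel intensity
    of ac-detected singles normalized by ``i_tyr`` (beta symmetrically).
    """
    for ch in ("tyr", "ac"):
        n = len(singles_by_channel.get(ch, []))
        if n < min_singles:
            warnings.warn(
                f"only {n} singles detected in {ch!r} channel "
                f"(< {min_singles}); crosstalk estimate may be unstable",
                stacklevel=2,
            )
    tyr_singles = singles_by_channel.get("tyr", [])
    ac_singles = singles_by_channel.get("ac", [])
    if not tyr_singles or not ac_singles:
        raise ValueError("need singles in both tyr and ac detection channels")
    i_tyr = float(np.mean([m.i_segm("tyr") for m in tyr_singles]))
    i_ac = float(np.mean([m.i_segm("ac") for m in ac_singles]))
    if i_tyr <= 0 or i_ac <= 0:
        raise ValueError(
            f"non-positive single-filament intensity: I_Tyr={i_tyr}, "
            f"I_Ac={i_ac}"
        )
    alpha = float(np.mean([m.i_segm("tyr") for m in ac_singles])) / i_tyr
    beta = float(np.mean([m.i_segm("ac") for m in tyr_singles])) / i_ac
    return CrosstalkCoefficients(
        i_tyr=i_tyr,
        i_ac=i_ac,
        alpha=alpha,
        beta=beta,
        n_segments={"tyr": len(tyr_singles), "ac": len(ac_singles)},
    )
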