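"""Microtubule cross-section counting in flipped-gel YZ stacks.

In the flipped orientation the poor axial PSF lies along the dendrite, so
each YZ slice shows microtubules as compact fluorescent spots.  The stage
detects spots per channel, removes merged doublets with a roundness filter
(theta = w*h / max(w, h)^2 >= 0.8), fits a normal law to the surviving
areas and keeps spots inside [max(Q1, mean - sd), mean + sd], calibrates
the single-cross-section intensity with the two-Gaussian histogram model,
estimates crosstalk by three methods, and counts microtubules per slice by
normalized integrated intensity and linear unmixing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, label
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from mtquant.counting import classify_counts, unmix_counts
from mtquant.filaments import SingleIntensityFit, fit_single_intensity
from mtquant.stack import DEFAULT_CHANNELS

CROSSTALK_METHODS = ("pooled_mean", "trimmed_mean", "two_gaussian_peak")


@dataclass
class Spot:
    slice_index: int
    detection_channel: str
    centroid: tuple[float, float]  # (row, col)
    w_spot: float  # column extent at half maximum, pixels
    h_spot: float  # row extent at half maximum, pixels
    area: float  # detected component area, pixels²
    intensities: dict[str, float]  # background-corrected integrated, per channel

    @property
    def roundness(self) -> float:
        long = max(self.w_spot, self.h_spot)
        return self.w_spot * self.h_spot / long**2

    def area_pre_expansion(self, expansion_factor: float) -> float:
        return self.area / expansion_factor**2


@dataclass
class AreaFilterParams:
    s_mean: float
    sigma_area: float
    q1: float

    @property
    def lower(self) -> float:
        return max(self.q1, self.s_mean - self.sigma_area)

    @property
    def upper(self) -> float:
        return self.s_mean + self.sigma_area


# ---------------------------------------------------------------------------
# detection


def detect_spots(
    slice_images: dict[str, np.ndarray],
    detection_channel: str,
    slice_index: int = 0,
    smooth_sigma: float = 1.5,
    snr: float = 5.0,
    min_pixels: int = 3,
) -> list[Spot]:
    """Blob detection on one YZ slice of the given channel.

    Smoothed local thresholding at ``median + snr * MAD``; each connected
    component becomes one spot.  Width/height are the component's half-max
    box extents; the integrated intensity is quantified in every channel,
    background-corrected by the median of a 2-pixel annulus around the
    spot box.
    """
    img = np.asarray(slice_images[detection_channel], dtype=float)
    if img.ndim != 2:
        raise ValueError("spot detection expects a 2D slice")
    sm = gaussian_filter(img, smooth_sigma)
    bg = float(np.median(sm))
    mad = float(np.median(np.abs(sm - bg))) * 1.4826
    thr = bg + snr * max(mad, 1e-12)
    mask = sm > thr
    if not mask.any():
        return []
    # watershed from local maxima splits touching cross-sections that a
    # plain connected-component pass would merge into one blob
    peaks = peak_local_max(
        sm, min_distance=max(int(round(2 * smooth_sigma)), 2),
        threshold_abs=thr, exclude_border=False,
    )
    markers = np.zeros(sm.shape, dtype=np.int32)
    for j, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = j
    if len(peaks) == 0:
        lbl, n = label(mask, structure=np.ones((3, 3)))
    else:
        lbl = watershed(-sm, markers=markers, mask=mask)
        n = len(peaks)
    spots: list[Spot] = []
    for i in range(1, n + 1):
        comp = lbl == i
        if int(comp.sum()) < min_pixels:
            continue
        rows, cols = np.nonzero(comp)
        vals = sm[comp]
        peak = float(vals.max())
        half_level = bg + 0.5 * (peak - bg)
        half = comp & (sm >= half_level)
        hr, hc = np.nonzero(half)
        h_spot = float(hr.max() - hr.min() + 1)
        w_spot = float(hc.max() - hc.min() + 1)
        weights = np.clip(img[comp] - bg, 0, None) + 1e-12
        cy = float(np.average(rows, weights=weights))
        cx = float(np.average(cols, weights=weights))
        intensities = {
            name: _integrated_intensity(np.asarray(ch, float), comp)
            for name, ch in slice_images.items()
        }
        spots.append(
            Spot(
                slice_index=slice_index,
                detection_channel=detection_channel,
                centroid=(cy, cx),
                w_spot=w_spot,
                h_spot=h_spot,
                area=float(comp.sum()),
                intensities=intensities,
            )
        )
    return spots


def _integrated_intensity(img: np.ndarray, comp: np.ndarray,
                          ring: int = 2) -> float:
    """Sum over the component minus the annulus-median background."""
    rows, cols = np.nonzero(comp)
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    rr0 = max(r0 - ring, 0)
    rr1 = min(r1 + ring + 1, img.shape[0])
    cc0 = max(c0 - ring, 0)
    cc1 = min(c1 + ring + 1, img.shape[1])
    box = np.zeros(img.shape, dtype=bool)
    box[rr0:rr1, cc0:cc1] = True
    inner = np.zeros(img.shape, dtype=bool)
    inner[r0:r1 + 1, c0:c1 + 1] = True
    annulus = box & ~inner
    bg = float(np.median(img[annulus])) if annulus.any() else 0.0
    return float(img[comp].sum() - bg * comp.sum())


def detect_spots_stack(
    slices: np.ndarray,
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS,
    **kwargs,
) -> list[Spot]:
    """Run per-channel detection over every slice of a (C, S, H, W) array."""
    out: list[Spot] = []
    n_slices = slices.shape[1]
    for s in range(n_slices):
        imgs = {name: slices[c, s] for c, name in enumerate(channel_names)}
        for name in channel_names:
            out.extend(
                detect_spots(imgs, name, slice_index=s, **kwargs)
            )
    return out


# ---------------------------------------------------------------------------
# geometric filters


def roundness_filter(spots: list[Spot], threshold: float = 0.8) -> list[Spot]:
    """Keep spots with roundness >= threshold (drop merged doublets)."""
    return [s for s in spots if s.roundness >= threshold]


def area_filter(
    spots: list[Spot], min_spots: int = 10
) -> tuple[list[Spot], AreaFilterParams]:
    """MLE normal fit to areas; keep spots inside the inclusion range.

    The MLE estimates are the sample mean and the population standard
    deviation; Q1 is the linear-interpolation 25th percentile, raising the
    lower bound against tiny false-positive spots.
    """
    if not spots:
        raise ValueError("no spots to filter")
    if len(spots) < min_spots:
        warnings.warn(
            f"area filter fitted on only {len(spots)} spots", stacklevel=2
        )
    areas = np.array([s.area for s in spots], dtype=float)
    s_mean = float(areas.mean())
    sigma = float(areas.std(ddof=0))
    q1 = float(np.percentile(areas, 25))
    params = AreaFilterParams(s_mean=s_mean, sigma_area=sigma, q1=q1)
    kept = [s for s in spots if params.lower <= s.area <= params.upper]
    return kept, params


def select_native_spots(
    spots: list[Spot], channel: str, min_split: int = 6
) -> list[Spot]:
    """Keep spots natively bright in their detection channel.

    Mirrors :func:`mtquant.filaments.select_native_singles`: an Otsu split
    of the detection-channel intensities separates the native population
    from crosstalk-dim detections of the other subset.
    """
    from skimage.filters import threshold_otsu

    if len(spots) < min_split:
        return spots
    values = np.array([s.intensities[channel] for s in spots])
    if np.ptp(values) <= 0:
        return spots
    thr = float(threshold_otsu(values))
    kept = [s for s, v in zip(spots, values) if v > thr]
    return kept if len(kept) >= 2 else spots


def fit_single_crosssection(
    spots: list[Spot], channel: str, bins: str | int = "fd"
) -> SingleIntensityFit:
    """Two-Gaussian calibration of filtered spot intensities in one channel."""
    values = np.array([s.intensities[channel] for s in spots], dtype=float)
    return fit_single_intensity(values, bins=bins)


# ---------------------------------------------------------------------------
# crosstalk


def crosstalk_levels(
    spots_by_channel: dict[str, list[Spot]],
    fits: dict[str, SingleIntensityFit],
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized crosstalk per single spot.

    alpha levels: tyr-channel intensity of ac-detected singles divided by
    the single intensity in the tyr channel; beta levels symmetrically.
    """
    i_tyr = fits["tyr"].i_single
    i_ac = fits["ac"].i_single
    alpha_levels = np.array(
        [s.intensities["tyr"] / i_tyr for s in spots_by_channel["ac"]]
    )
    beta_levels = np.array(
        [s.intensities["ac"] / i_ac for s in spots_by_channel["tyr"]]
    )
    return alpha_levels, beta_levels


def _peak_of_two_free_gaussians(values: np.ndarray) -> float:
    """Dominant-component mean of an unconstrained two-Gaussian fit."""
    counts, edges = np.histogram(values, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(x, a1, m1, s1, a2, m2, s2):
        return a1 * np.exp(-((x - m1) ** 2) / (2 * s1**2)) + a2 * np.exp(
            -((x - m2) ** 2) / (2 * s2**2)
        )

    spread = max(values.std(), 1e-6)
    p0 = (
        counts.max(), float(np.median(values)), spread / 2,
        counts.max() / 4, float(np.percentile(values, 90)), spread,
    )
    lo = (0, values.min() - spread, 1e-9, 0, values.min() - spread, 1e-9)
    hi = (np.inf, values.max() + spread, np.inf,
          np.inf, values.max() + spread, np.inf)
    popt, _ = curve_fit(model, centers, counts, p0=p0, bounds=(lo, hi),
                        maxfev=20000)
    a1, m1, _, a2, m2, _ = popt
    return float(m1 if a1 >= a2 else m2)


def estimate_crosstalk_flipexm(
    alpha_levels: np.ndarray,
    beta_levels: np.ndarray,
    method: str = "pooled_mean",
) -> tuple[float, float, list[str]]:
    """alpha/beta by one of three estimators.

    ``pooled_mean`` averages all levels; ``trimmed_mean`` first drops
    values above mean + SD of the same sample (robust to the long
    crosstalk tails); ``two_gaussian_peak`` takes the dominant peak
    position of an unconstrained two-Gaussian histogram fit, falling back
    (flagged) to the trimmed mean when the fit fails.
    """
    if method not in CROSSTALK_METHODS:
        raise ValueError(f"unknown method {method!r}")
    flags: list[str] = []

    def _one(values: np.ndarray) -> float:
        values = np.asarray(values, dtype=float)
        if len(values) == 0:
            raise ValueError("no crosstalk levels available")
        if method == "pooled_mean":
            return float(values.mean())
        if method == "trimmed_mean":
            cut = values.mean() + values.std(ddof=0)
            trimmed = values[values <= cut]
            return float(trimmed.mean()) if len(trimmed) else float(values.mean())
        try:
            return _peak_of_two_free_gaussians(values)
        except (RuntimeError, ValueError):
            flags.append("two_gaussian_fallback_trimmed")
            cut = values.mean() + values.std(ddof=0)
            trimmed = values[values <= cut]
            return float(trimmed.mean()) if len(trimmed) else float(values.mean())

    return _one(alpha_levels), _one(beta_levels), flags


# ---------------------------------------------------------------------------
# counting


def count_per_slice(
    spots: list[Spot],
    fits: dict[str, SingleIntensityFit],
    alpha: float,
    beta: float,
    n_slices: int | None = None,
):
    """Per-slice and per-dendrite microtubule counts.

    The normalized integrated intensity of a slice in a channel is the sum
    of that channel's detected spot intensities divided by the fitted
    single-cross-section intensity; the crosstalk system is solved per
    slice and counts averaged over slices for the dendrite value.
    """
    if n_slices is None:
        n_slices = max((s.slice_index for s in spots), default=-1) + 1
    per_slice = []
    for s_idx in range(n_slices):
        theta = {}
        for ch in ("total", "tyr", "ac"):
            tot = sum(
                sp.intensities[ch]
                for sp in spots
                if sp.slice_index == s_idx and sp.detection_channel == ch
            )
            theta[ch] = tot / fits[ch].i_single
        n_tyr, n_ac = unmix_counts(theta["tyr"], theta["ac"], alpha, beta)
        counts = classify_counts(theta["total"], n_tyr, n_ac)
        if not any(
            sp.slice_index == s_idx for sp in spots
        ):
            counts.flags.append("zero_spots")
        per_slice.append(counts)
    if not per_slice:
        raise ValueError("no slices to count")
    dendrite = classify_counts(
        float(np.mean([c.n_tot for c in per_slice])),
        float(np.mean([c.n_tyr for c in per_slice])),
        float(np.mean([c.n_ac for c in per_slice])),
    )
    return per_slice, dendrite
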