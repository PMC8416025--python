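"""Intensity analysis along a single dendrite.

At equidistant points of a spline-fitted path, the perpendicular intensity
profile of each channel is fitted with a Gaussian plus offset; the local
intensity is amplitude x sigma.  Profiles are normalized by the mean of
the first 5 µm, points above 1.25 (crossing neurites) are excluded, and
the remainder is smoothed with a 2 µm moving average.  The total-channel
sigma yields the FWHM series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit

from mtquant.rois import PolylineRoi
from mtquant.stackio import _smooth_path

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


@dataclass
class LongitudinalProfile:
    positions: np.ndarray  # arc positions, µm, strictly increasing
    amplitude: dict[str, np.ndarray]
    sigma_perp: dict[str, np.ndarray]  # µm
    offset: dict[str, np.ndarray]
    intensity: dict[str, np.ndarray]  # amplitude * sigma
    normalized: dict[str, np.ndarray] = field(default_factory=dict)
    excluded: dict[str, np.ndarray] = field(default_factory=dict)  # bool masks
    smoothed: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def channels(self) -> list[str]:
        return list(self.intensity)


def _gauss_offset(t, a, t0, sigma, off):
    return a * np.exp(-((t - t0) ** 2) / (2 * sigma**2)) + off


def trace_profile(
    sum_images: dict[str, np.ndarray],
    path: PolylineRoi,
    pixel_size: float,
    step_um: float = 0.25,
    profile_half_width_um: float = 2.0,
) -> LongitudinalProfile:
    """Perpendicular Gaussian fits at equidistant points along the path.

    A failed fit at a point is masked (NaN), not fatal.
    """
    shape = next(iter(sum_images.values())).shape
    step_px = step_um / pixel_size
    samples, tangents = _smooth_path(path, step_px=step_px)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    half_px = profile_half_width_um / pixel_size
    offsets = np.arange(-np.floor(half_px), np.floor(half_px) + 1)
    t_um = offsets * pixel_size

    n = len(samples)
    positions = np.arange(n) * step_um
    amplitude = {c: np.full(n, np.nan) for c in sum_images}
    sigma_perp = {c: np.full(n, np.nan) for c in sum_images}
    offset_arr = {c: np.full(n, np.nan) for c in sum_images}

    for i in range(n):
        xs = samples[i, 0] + offsets * normals[i, 0]
        ys = samples[i, 1] + offsets * normals[i, 1]
        inside = (
            (xs >= 0) & (xs <= shape[1] - 1)
            & (ys >= 0) & (ys <= shape[0] - 1)
        )
        if inside.sum() < 5:
            continue
        for c, img in sum_images.items():
            prof = map_coordinates(
                np.asarray(img, float), [ys[inside], xs[inside]], order=1
            )
            tt = t_um[inside]
            a0 = float(prof.max() - prof.min())
            if a0 <= 0:
                continue
            p0 = (a0, float(tt[np.argmax(prof)]),
                  profile_half_width_um / 4, float(prof.min()))
            try:
                popt, _ = curve_fit(
                    _gauss_offset, tt, prof, p0=p0,
                    bounds=(
                        (0, tt.min(), 1e-6, -np.inf),
                        (np.inf, tt.max(), np.inf, np.inf),
                    ),
                    maxfev=5000,
                )
            except (RuntimeError, ValueError):
                continue
            amplitude[c][i] = popt[0]
            sigma_perp[c][i] = popt[2]
            offset_arr[c][i] = popt[3]

    intensity = {
        c: amplitude[c] * sigma_perp[c] for c in sum_images
    }
    return LongitudinalProfile(
        positions=positions,
        amplitude=amplitude,
        sigma_perp=sigma_perp,
        offset=offset_arr,
        intensity=intensity,
    )


def normalize_and_smooth(
    profile: LongitudinalProfile,
    norm_length_um: float = 5.0,
    smooth_window_um: float = 2.0,
    spike_threshold: float = 1.25,
) -> LongitudinalProfile:
    """Normalize by the first-5-µm mean, exclude spikes, then smooth.

    Exclusion happens before smoothing, and excluded points are removed
    from the smoothing window (not zero-filled) so spikes do not bleed
    into their neighbours.
    """
    pos = profile.positions
    if pos[-1] <= norm_length_um:
        raise ValueError(
            f"profile covers only {pos[-1]:.2f} µm; need > {norm_length_um}"
        )
    head = pos <= norm_length_um
    for c in profile.channels:
        raw = profile.intensity[c]
        head_vals = raw[head]
        head_vals = head_vals[np.isfinite(head_vals)]
        if len(head_vals) == 0 or np.mean(head_vals) <= 0:
            raise ValueError(
                f"cannot normalize channel {c!r}: empty or non-positive head"
            )
        norm = raw / np.mean(head_vals)
        excluded = ~np.isfinite(norm) | (norm > spike_threshold)
        smoothed = np.full_like(norm, np.nan)
        half = smooth_window_um / 2.0
        for i, p in enumerate(pos):
            window = (np.abs(pos - p) <= half) & ~excluded
            if window.any():
                smoothed[i] = np.mean(norm[window])
        profile.normalized[c] = norm
        profile.excluded[c] = excluded
        profile.smoothed[c] = smoothed
    return profile


def fwhm(profile: LongitudinalProfile, channel: str = "total") -> np.ndarray:
    """FWHM series from the fitted perpendicular sigma (2*sqrt(2 ln 2) * sigma).

    Masked (NaN) fit points propagate as NaN.
    """
    return FWHM_FACTOR * profile.sigma_perp[channel]
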