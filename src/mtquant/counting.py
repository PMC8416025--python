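"""Dendrite-stage microtubule counting.

Measures background-corrected dendrite band intensities on sum projections,
converts the total-channel intensity into a microtubule count via the
single-filament calibration, and unmixes tyrosinated/acetylated counts with
the crosstalk coefficients:

    I_tyr_dendrite = (n_tyr + alpha * n_ac) * I_tyr
    I_ac_dendrite  = (beta * n_tyr + n_ac) * I_ac

whose inverse (valid for alpha*beta != 1) is

    n_tyr = (theta_tyr - alpha * theta_ac) / (1 - alpha * beta)
    n_ac  = theta_ac - beta * n_tyr

with theta_c = I_c_dendrite / I_c.  The dendrite intensity is normalized by
(L_dendrite * w_microtubule) in pixel units, which makes it directly
commensurate with the per-segment single-filament intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from mtquant.filaments import (
    CrosstalkCoefficients,
    SingleIntensityFit,
    _tube_touches_border,
)
from mtquant.rois import PolylineRoi

SINGULARITY_TOL = 1e-6


class UnmixSingularityError(ValueError):
    """alpha * beta is too close to 1 for the unmixing system to be solved."""


@dataclass
class DendriteMeasurement:
    """Band intensities of a straight dendrite segment in all channels."""

    channels: dict[str, dict[str, float]]  # per channel: I_mid, I_wide, ...
    length_um: float
    w_dendrite: float  # pixels
    w_microtubule: float  # pixels used for normalization
    cross_section_area: float | None = None  # µm²

    def i_dendrite(self, channel: str) -> float:
        return self.channels[channel]["I_dendrite"]


@dataclass
class MicrotubuleCounts:
    n_tot: float
    n_tyr: float
    n_ac: float
    n_other: float
    density: float | None = None  # MT / µm²
    fractions: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def band_mask(shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray,
              width: float) -> np.ndarray:
    """Rectangular band of the given width along a straight line.

    Matches ImageJ straight-line-ROI semantics: pixels whose centre
    projects onto the segment (no end caps) and lies within ``width/2``
    of it perpendicular to the line.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    length = float(np.linalg.norm(d))
    if length == 0:
        raise ValueError("degenerate line")
    u = d / length
    n = np.array([-u[1], u[0]])
    ny, nx = shape
    xs, ys = np.meshgrid(np.arange(nx, dtype=float),
                         np.arange(ny, dtype=float))
    rel_x = xs - p0[0]
    rel_y = ys - p0[1]
    t = rel_x * u[0] + rel_y * u[1]
    s = rel_x * n[0] + rel_y * n[1]
    return (t >= 0) & (t <= length) & (np.abs(s) <= width / 2.0)


def measure_dendrite(
    sum_images: dict[str, np.ndarray],
    line: PolylineRoi,
    w_dendrite: float,
    pixel_size: float,
    w_microtubule: float = 6.0,
    widen_by: float = 10.0,
    cross_section_area: float | None = None,
) -> DendriteMeasurement:
    """Dual-width band measurement along a straight dendrite line ROI.

    ``I_dendrite = (I_mid - I_BG * S_mid) / (L_px * w_microtubule)`` so that
    dividing by the single-filament intensity yields a count directly.
    """
    if len(line.vertices) != 2:
        raise ValueError("dendrite line ROI must have exactly 2 vertices")
    length_um = line.length * pixel_size
    if not 2.0 <= length_um <= 3.0:
        warnings.warn(
            f"dendrite line is {length_um:.2f} µm; 2-3 µm is preferred",
            stacklevel=2,
        )
    shape = next(iter(sum_images.values())).shape
    w_wide = w_dendrite + widen_by
    if _tube_touches_border(shape, line.vertices, w_wide):
        raise ValueError("widened dendrite band exits the image")
    mid = band_mask(shape, line.vertices[0], line.vertices[1], w_dendrite)
    wide = band_mask(shape, line.vertices[0], line.vertices[1], w_wide)
    s_mid = int(mid.sum())
    s_wide = int(wide.sum())
    if not s_wide > s_mid > 0:
        raise ValueError(f"degenerate band areas S_mid={s_mid}, S_wide={s_wide}")
    length_px = line.length
    channels = {}
    for name, img in sum_images.items():
        i_mid = float(img[mid].sum())
        i_wide = float(img[wide].sum())
        i_bg = (i_wide - i_mid) / (s_wide - s_mid)
        i_dendrite = (i_mid - i_bg * s_mid) / (length_px * w_microtubule)
        channels[name] = {
            "I_mid": i_mid,
            "I_wide": i_wide,
            "S_mid": float(s_mid),
            "S_wide": float(s_wide),
            "I_BG": i_bg,
            "I_dendrite": i_dendrite,
        }
    return DendriteMeasurement(
        channels=channels,
        length_um=length_um,
        w_dendrite=w_dendrite,
        w_microtubule=w_microtubule,
        cross_section_area=cross_section_area,
    )


def count_total(
    measurement: DendriteMeasurement, fit: SingleIntensityFit
) -> float:
    """n_tot = dendrite total-channel intensity / single-filament intensity."""
    if fit.i_single <= 0:
        raise ValueError("single-filament intensity must be > 0")
    return measurement.i_dendrite("total") / fit.i_single


def unmix_counts(
    theta_tyr: float, theta_ac: float, alpha: float, beta: float
) -> tuple[float, float]:
    """Invert the forward crosstalk model; exact for alpha * beta != 1."""
    det = 1.0 - alpha * beta
    if abs(det) < SINGULARITY_TOL:
        raise UnmixSingularityError(
            f"alpha*beta = {alpha * beta:.9f} is numerically singular"
        )
    n_tyr = (theta_tyr - alpha * theta_ac) / det
    n_ac = theta_ac - beta * n_tyr
    return n_tyr, n_ac


def forward_model(
    n_tyr: float, n_ac: float, alpha: float, beta: float
) -> tuple[float, float]:
    """theta pair produced by given counts (used for round-trip checks)."""
    return n_tyr + alpha * n_ac, beta * n_tyr + n_ac


def classify_counts(
    n_tot: float,
    n_tyr: float,
    n_ac: float,
    area: float | None = None,
) -> MicrotubuleCounts:
    """Derive n_other, density and subtype fractions; flag negatives.

    Negative unmixed counts are legitimate under noise and are reported
    with a flag rather than clamped, so population statistics stay
    unbiased.  Fractions use components clamped at zero so they sum to 1.
    """
    n_other = n_tot - n_tyr - n_ac
    flags = []
    for name, v in (("n_tyr", n_tyr), ("n_ac", n_ac), ("n_other", n_other)):
        if v < 0:
            flags.append(f"negative_{name}")
    clamped = np.clip([n_tyr, n_ac, n_other], 0, None)
    total = clamped.sum()
    if total > 0:
        fractions = {
            "tyr": float(clamped[0] / total),
            "ac": float(clamped[1] / total),
            "other": float(clamped[2] / total),
        }
    else:
        fractions = {"tyr": 0.0, "ac": 0.0, "other": 0.0}
    density = None
    if area is not None:
        if area <= 0:
            raise ValueError("area must be > 0")
        density = n_tot / area
    return MicrotubuleCounts(
        n_tot=n_tot,
        n_tyr=n_tyr,
        n_ac=n_ac,
        n_other=n_other,
        density=density,
        fractions=fractions,
        flags=flags,
    )


def count_dendrite(
    measurement: DendriteMeasurement,
    fit: SingleIntensityFit,
    crosstalk: CrosstalkCoefficients,
) -> MicrotubuleCounts:
    """Full counting chain for one dendrite measurement."""
    n_tot = count_total(measurement, fit)
    theta_tyr = measurement.i_dendrite("tyr") / crosstalk.i_tyr
    theta_ac = measurement.i_dendrite("ac") / crosstalk.i_ac
    n_tyr, n_ac = unmix_counts(
        theta_tyr, theta_ac, crosstalk.alpha, crosstalk.beta
    )
    return classify_counts(
        n_tot, n_tyr, n_ac, area=measurement.cross_section_area
    )


def measure_cross_section_area(
    resliced,
    channel: str = "total",
    i_thr: float = 0.3,
    slice_index: int | None = None,
) -> float:
    """Dendrite cross-section area in biological µm².

    Detects the boundary contour (rectangle scan + 8-point spline from
    :mod:`mtquant.radial`) on one YZ slice (the middle slice by default)
    and converts the enclosed pixel area via the slice pixel size and the
    expansion factor.
    """
    from mtquant.radial import BoundaryParams, fit_contour, initial_rectangle

    slices = resliced.channel(channel)
    idx = slice_index if slice_index is not None else slices.shape[0] // 2
    img = slices[idx]
    if not np.any(img):
        raise ValueError(f"slice {idx} is empty; no contour can be found")
    params = BoundaryParams(i_thr=i_thr)
    rect = initial_rectangle(img, params)
    contour = fit_contour(img, rect, params)
    py, pz = resliced.pixel_size
    area_px = contour.area
    return float(area_px * py * pz / resliced.expansion_factor**2)
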