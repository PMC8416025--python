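"""Ground-truth-labeled synthetic microscopy scenes.

Generates three scene kinds on a common rendering backend:

``soma_sheet``
    A sparse, flat sub-nuclear layer of short filaments, a fraction of which
    are two-filament bundles.  Used to exercise single-filament intensity
    calibration and crosstalk estimation.
``dendrite``
    A cylinder populated with axis-parallel microtubules whose radial
    placement is biased (stable to the core, dynamic to the shell).
``flipexm_dendrite``
    A cylinder with circumferentially placed microtubules on a ring,
    rendered at either PSF orientation to reproduce the flipped-gel
    resolution advantage.

Geometry is generated in biological micrometres, scaled by the expansion
factor, splatted at sub-voxel precision and convolved with an anisotropic
Gaussian PSF.  Background and noise are applied last; the ground truth
records everything pre-noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from mtquant.stack import DEFAULT_CHANNELS, ChannelStack

SCENE_KINDS = ("soma_sheet", "dendrite", "flipexm_dendrite")
ORIENTATIONS = ("regular", "flipped")
NOISE_MODELS = ("none", "poisson", "gaussian", "poisson+gaussian")

#: subtype labels: stable microtubules are detected via acetylation,
#: dynamic via tyrosination, "other" carry neither modification.
SUBTYPES = ("ac", "tyr", "other")


@dataclass
class SceneSpec:
    """Full parameterization of a synthetic scene.

    Lengths are biological micrometres unless stated otherwise; PSF sigmas
    and voxel sizes are in acquired (post-expansion) micrometres.
    """

    scene_kind: str = "soma_sheet"
    dendrite_diameter: float = 2.0
    dendrite_length: float = 8.0
    n_microtubules: int = 100
    fraction_acetylated: float = 0.72
    fraction_tyrosinated: float = 0.26
    fraction_other: float = 0.02
    radial_bias: float = 0.0
    bundle_fraction: float = 0.0
    true_alpha: float = 0.53
    true_beta: float = 0.45
    intensity_cv: float = 0.15
    psf_sigma_lateral: float = 0.05
    psf_sigma_axial: float = 0.20
    orientation: str = "regular"
    background_level: float = 10.0
    read_noise_sd: float = 1.0
    noise_model: str = "poisson"
    voxel_size: tuple[float, float, float] = (0.03, 0.03, 0.15)
    expansion_factor: float = 1.0
    seed: int = 0
    # soma-sheet extras
    sheet_size: float = 15.0
    filament_length: tuple[float, float] = (2.0, 4.0)
    #: emitted photons per biological µm of filament at unit emission level
    filament_photons: float = 4000.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scene_kind not in SCENE_KINDS:
            raise ValueError(f"unknown scene_kind {self.scene_kind!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        fracs = (
            self.fraction_acetylated,
            self.fraction_tyrosinated,
            self.fraction_other,
        )
        for name in (
            "dendrite_diameter",
            "dendrite_length",
            "true_alpha",
            "true_beta",
            "intensity_cv",
            "psf_sigma_lateral",
            "psf_sigma_axial",
            "background_level",
            "read_noise_sd",
            "sheet_size",
            "filament_photons",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.n_microtubules < 0:
            raise ValueError("n_microtubules must be >= 0")
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError(f"subtype fractions must lie in [0, 1]: {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"subtype fractions must sum to 1: {fracs}")
        if not 0 <= self.radial_bias <= 1:
            raise ValueError("radial_bias must lie in [0, 1]")
        if not 0 <= self.bundle_fraction <= 1:
            raise ValueError("bundle_fraction must lie in [0, 1]")
        if self.psf_sigma_axial < self.psf_sigma_lateral:
            raise ValueError("psf_sigma_axial must be >= psf_sigma_lateral")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"invalid voxel_size {self.voxel_size}")

    # -- config round trip ---------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["voxel_size"] = list(self.voxel_size)
        d["filament_length"] = list(self.filament_length)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        if "voxel_size" in d:
            d["voxel_size"] = tuple(d["voxel_size"])
        if "filament_length" in d:
            d["filament_length"] = tuple(d["filament_length"])
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def from_file(cls, path: str | Path) -> "SceneSpec":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


@dataclass
class FilamentTruth:
    """One rendered filament: noiseless geometry and emission."""

    vertices: np.ndarray  # (N, 3) biological µm, columns x, y, z
    subtype: str  # one of SUBTYPES
    bundle: bool
    #: per-channel emitted photons per biological µm of filament
    emission: dict[str, float]
    radius: float | None = None  # radial placement in a dendrite, µm


@dataclass
class GroundTruth:
    """Pre-noise record of everything the generator placed."""

    filaments: list[FilamentTruth]
    n_total: int
    n_tyr: int
    n_ac: int
    n_other: int
    cross_section_area: float | None = None  # µm², dendrite scenes
    density: float | None = None  # MT / µm²

    def __post_init__(self) -> None:
        if self.n_total != self.n_tyr + self.n_ac + self.n_other:
            raise ValueError("subtype counts must sum to n_total")

    def mean_radius(self, subtype: str) -> float:
        radii = [
            f.radius
            for f in self.filaments
            if f.subtype == subtype and f.radius is not None
        ]
        return float(np.mean(radii)) if radii else float("nan")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_total": self.n_total,
            "n_tyr": self.n_tyr,
            "n_ac": self.n_ac,
            "n_other": self.n_other,
            "cross_section_area": self.cross_section_area,
            "density": self.density,
            "filaments": [
                {
                    "subtype": f.subtype,
                    "bundle": f.bundle,
                    "emission": f.emission,
                    "radius": f.radius,
                    "vertices": np.asarray(f.vertices).tolist(),
                }
                for f in self.filaments
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for i, f in enumerate(self.filaments):
            v = np.asarray(f.vertices)
            rows.append(
                {
                    "filament": i,
                    "subtype": f.subtype,
                    "bundle": f.bundle,
                    "radius_um": f.radius,
                    "length_um": float(
                        np.sum(np.linalg.norm(np.diff(v, axis=0), axis=1))
                    ),
                    **{f"emission_{c}": e for c, e in f.emission.items()},
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometry helpers


def _allocate_subtypes(n: int, fractions: tuple[float, float, float],
                       rng: np.random.Generator) -> list[str]:
    """Largest-remainder allocation of subtype labels, order shuffled."""
    target = np.asarray(fractions) * n
    counts = np.floor(target).astype(int)
    rem = target - counts
    for _ in range(n - counts.sum()):
        i = int(np.argmax(rem))
        counts[i] += 1
        rem[i] = -1
    labels = [s for s, c in zip(SUBTYPES, counts) for _ in range(c)]
    rng.shuffle(labels)
    return labels


def _radial_exponent(subtype: str, bias: float) -> float:
    """Exponent p of r = R * u**p; p=0.5 is uniform over the disk.

    Larger p concentrates filaments toward the core.  Stable ("ac")
    microtubules get p growing with bias, dynamic ("tyr") get p shrinking
    with bias, so the mean radius moves strictly inward/outward.
    """
    if subtype == "ac":
        return 0.5 * (1.0 + 3.0 * bias)
    if subtype == "tyr":
        return 0.5 / (1.0 + 3.0 * bias)
    return 0.5


def _emission_levels(subtype: str, spec: SceneSpec) -> dict[str, float]:
    if subtype == "ac":
        return {"total": 1.0, "tyr": spec.true_alpha, "ac": 1.0}
    if subtype == "tyr":
        return {"total": 1.0, "tyr": 1.0, "ac": spec.true_beta}
    return {"total": 1.0, "tyr": 0.0, "ac": 0.0}


def _brightness(rng: np.random.Generator, cv: float) -> float:
    return max(1.0 + cv * rng.standard_normal(), 0.05)


def _place_soma_filaments(spec: SceneSpec, rng: np.random.Generator
                          ) -> list[FilamentTruth]:
    labels = _allocate_subtypes(spec.n_microtubules, (
        spec.fraction_acetylated, spec.fraction_tyrosinated,
        spec.fraction_other), rng)
    out = []
    s = spec.sheet_size
    lo, hi = spec.filament_length
    for subtype in labels:
        length = rng.uniform(lo, hi)
        theta = rng.uniform(0, 2 * np.pi)
        # keep the whole filament inside the sheet
        cx = rng.uniform(length / 2, s - length / 2)
        cy = rng.uniform(length / 2, s - length / 2)
        d = np.array([np.cos(theta), np.sin(theta)])
        p0 = np.array([cx, cy]) - d * length / 2
        p1 = np.array([cx, cy]) + d * length / 2
        # sheet plane z = 0; shifted to the stack centre at render time
        verts = np.array([[p0[0], p0[1], 0.0], [p1[0], p1[1], 0.0]])
        bundle = rng.uniform() < spec.bundle_fraction
        factor = _brightness(rng, spec.intensity_cv)
        if bundle:
            factor += _brightness(rng, spec.intensity_cv)
        levels = _emission_levels(subtype, spec)
        emission = {c: lv * factor * spec.filament_photons
                    for c, lv in levels.items()}
        out.append(FilamentTruth(verts, subtype, bundle, emission))
    return out


def _place_dendrite_filaments(spec: SceneSpec, rng: np.random.Generator
                              ) -> list[FilamentTruth]:
    labels = _allocate_subtypes(spec.n_microtubules, (
        spec.fraction_acetylated, spec.fraction_tyrosinated,
        spec.fraction_other), rng)
    R = spec.dendrite_diameter / 2
    out = []
    if spec.scene_kind == "flipexm_dendrite":
        # circumferential placement: evenly spaced on a ring at 0.8 R
        n = spec.n_microtubules
        angles = 2 * np.pi * (np.arange(n) + rng.uniform()) / max(n, 1)
        radii = np.full(n, 0.8 * R)
    else:
        u = rng.uniform(size=spec.n_microtubules)
        radii = np.array([
            R * u[i] ** _radial_exponent(labels[i], spec.radial_bias)
            for i in range(spec.n_microtubules)
        ])
        angles = rng.uniform(0, 2 * np.pi, size=spec.n_microtubules)
    for subtype, r, a in zip(labels, radii, angles):
        y, z = r * np.cos(a), r * np.sin(a)
        verts = np.array([
            [0.0, y, z],
            [spec.dendrite_length, y, z],
        ])
        factor = _brightness(rng, spec.intensity_cv)
        levels = _emission_levels(subtype, spec)
        emission = {c: lv * factor * spec.filament_photons
                    for c, lv in levels.items()}
        out.append(FilamentTruth(verts, subtype, False, emission,
                                 radius=float(r)))
    return out


# ---------------------------------------------------------------------------
# rendering


def _splat(grid: np.ndarray, pts_vox: np.ndarray, weights: np.ndarray) -> None:
    """Trilinear deposition of point emissions into a (Z, Y, X) grid."""
    zyx = pts_vox[:, ::-1]  # points are (x, y, z) voxel coords
    base = np.floor(zyx).astype(int)
    frac = zyx - base
    nz, ny, nx = grid.shape
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = (
                    weights
                    * (frac[:, 0] if dz else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dx else 1 - frac[:, 2])
                )
                iz = base[:, 0] + dz
                iy = base[:, 1] + dy
                ix = base[:, 2] + dx
                ok = (
                    (iz >= 0) & (iz < nz)
                    & (iy >= 0) & (iy < ny)
                    & (ix >= 0) & (ix < nx)
                )
                np.add.at(grid, (iz[ok], iy[ok], ix[ok]), w[ok])


def _sample_centerline(vertices_um: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at arc steps of `step`; returns (points, seg lengths)."""
    pts = []
    lens = []
    for a, b in zip(vertices_um[:-1], vertices_um[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / step)), 1)
        t = (np.arange(n) + 0.5) / n
        pts.append(a[None] + t[:, None] * (b - a)[None])
        lens.append(np.full(n, seg / n))
    return np.concatenate(pts), np.concatenate(lens)


def psf_sigmas_zyx(spec: SceneSpec) -> tuple[float, float, float]:
    """PSF sigma per (z, y, x) axis in µm; long axis depends on orientation.

    ``regular``: optical axis is z, so the axial (long) sigma lies on z.
    ``flipped``: the gel is rotated 90° about y, so the long axis lies
    along the dendrite (x) and z takes the lateral sigma.
    """
    lat, ax = spec.psf_sigma_lateral, spec.psf_sigma_axial
    if spec.orientation == "flipped":
        return (lat, lat, ax)
    return (ax, lat, lat)


def _stack_shape(spec: SceneSpec) -> tuple[tuple[int, int, int], np.ndarray]:
    """(nz, ny, nx) and the µm offset added to expanded coordinates."""
    dx, dy, dz = spec.voxel_size
    e = spec.expansion_factor
    margin = 4 * spec.psf_sigma_axial + 0.3
    if spec.scene_kind == "soma_sheet":
        ext_x = spec.sheet_size * e + 2 * margin
        ext_y = spec.sheet_size * e + 2 * margin
        ext_z = 2 * margin
        offset = np.array([margin, margin, ext_z / 2])
    else:
        d = spec.dendrite_diameter * e
        ext_x = spec.dendrite_length * e + 2 * margin
        ext_y = d + 2 * margin
        ext_z = d + 2 * margin
        offset = np.array([margin, ext_y / 2, ext_z / 2])
    shape = (
        max(int(np.ceil(ext_z / dz)), 1),
        max(int(np.ceil(ext_y / dy)), 1),
        max(int(np.ceil(ext_x / dx)), 1),
    )
    return shape, offset


def simulate_scene(spec: SceneSpec) -> tuple[ChannelStack, GroundTruth]:
    """Render a scene; returns the noisy stack and its pre-noise truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.scene_kind == "soma_sheet":
        filaments = _place_soma_filaments(spec, rng)
    else:
        filaments = _place_dendrite_filaments(spec, rng)

    shape, offset = _stack_shape(spec)
    dx, dy, dz = spec.voxel_size
    e = spec.expansion_factor
    grids = {c: np.zeros(shape) for c in DEFAULT_CHANNELS}

    step = min(spec.voxel_size) / 4.0  # expanded µm
    for f in filaments:
        verts_exp = np.asarray(f.vertices, dtype=float) * e + offset[None]
        pts, seg = _sample_centerline(verts_exp, step)
        # voxel coordinates, pixel-center convention
        vox = np.empty_like(pts)
        vox[:, 0] = pts[:, 0] / dx - 0.5
        vox[:, 1] = pts[:, 1] / dy - 0.5
        vox[:, 2] = pts[:, 2] / dz - 0.5
        for c in DEFAULT_CHANNELS:
            em = f.emission[c]
            if em <= 0:
                continue
            # emission is per biological µm; seg lengths are expanded µm
            _splat(grids[c], vox, em * seg / e)

    # filament cross-section (0.3 sigma_lat) folded into the PSF kernel:
    # convolving once with the combined Gaussian equals blur-then-PSF.
    core = 0.3 * spec.psf_sigma_lateral
    sz, sy, sx = psf_sigmas_zyx(spec)
    sig_vox = (
        np.sqrt(sz**2 + core**2) / dz,
        np.sqrt(sy**2 + core**2) / dy,
        np.sqrt(sx**2 + core**2) / dx,
    )
    voxels = np.stack([
        gaussian_filter(grids[c], sig_vox, mode="constant")
        for c in DEFAULT_CHANNELS
    ])

    signal = voxels + spec.background_level
    if spec.noise_model == "none":
        noisy = signal
    elif spec.noise_model == "poisson":
        noisy = rng.poisson(signal).astype(float)
    elif spec.noise_model == "gaussian":
        noisy = signal + spec.read_noise_sd * rng.standard_normal(signal.shape)
    else:  # poisson+gaussian
        noisy = (
            rng.poisson(signal).astype(float)
            + spec.read_noise_sd * rng.standard_normal(signal.shape)
        )
    noisy = np.clip(noisy, 0, None)

    n_ac = sum(1 for f in filaments if f.subtype == "ac")
    n_tyr = sum(1 for f in filaments if f.subtype == "tyr")
    n_other = sum(1 for f in filaments if f.subtype == "other")
    area = None
    density = None
    if spec.scene_kind != "soma_sheet":
        area = np.pi * (spec.dendrite_diameter / 2) ** 2
        density = len(filaments) / area if area > 0 else None

    truth = GroundTruth(
        filaments=filaments,
        n_total=len(filaments),
        n_tyr=n_tyr,
        n_ac=n_ac,
        n_other=n_other,
        cross_section_area=area,
        density=density,
    )
    stack = ChannelStack(
        voxels=noisy,
        channel_names=DEFAULT_CHANNELS,
        voxel_size=spec.voxel_size,
        expansion_factor=spec.expansion_factor,
    )
    return stack, truth


def render_noiseless(spec: SceneSpec) -> tuple[ChannelStack, GroundTruth]:
    """Convenience: the same scene with background 0 and no noise."""
    import copy

    clean = copy.deepcopy(spec)
    clean.background_level = 0.0
    clean.noise_model = "none"
    return simulate_scene(clean)


def simulate_segment_intensities(
    n: int,
    mean_single: float,
    cv: float,
    doublet_fraction: float,
    seed: int,
) -> np.ndarray:
    """Draw a singles/doublets intensity mixture for histogram-fit tests.

    Singles follow N(mean_single, (cv*mean_single)^2); a doublet is the sum
    of two independent singles.  Order is randomized.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= doublet_fraction <= 1:
        raise ValueError("doublet_fraction must lie in [0, 1]")
    if cv <= 0:
        raise ValueError("cv must be > 0")
    rng = np.random.default_rng(seed)
    sd = cv * mean_single
    is_doublet = rng.uniform(size=n) < doublet_fraction
    singles = rng.normal(mean_single, sd, size=n)
    partners = rng.normal(mean_single, sd, size=n)
    values = np.where(is_doublet, singles + partners, singles)
    rng.shuffle(values)
    return values
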