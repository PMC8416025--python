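"""Stack I/O, channel registration and geometric transforms.

Reading and writing uses OME-TIFF via :mod:`tifffile`; the voxel size is
stored in the OME ``PhysicalSize*`` attributes and channel names in the OME
``Channel`` elements.  Registration follows the projection-correlation
approach: phase correlation of XY and XZ maximum-intensity projections with
parabolic sub-pixel refinement.  ``straighten_and_reslice`` converts a
polyline-marked dendrite into a series of perpendicular YZ slices.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from scipy.interpolate import splev, splprep
from skimage.registration import phase_cross_correlation

from mtquant.rois import PolylineRoi
from mtquant.stack import ChannelStack


# ---------------------------------------------------------------------------
# TIFF I/O


def write_stack(stack: ChannelStack, path: str | Path) -> None:
    """Write an OME-TIFF with voxel size and channel names in metadata."""
    dx, dy, dz = stack.voxel_size
    tifffile.imwrite(
        str(path),
        stack.voxels.astype(np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
            "Description": f"expansion_factor={stack.expansion_factor}",
        },
    )


def _parse_ome(xml_text: str) -> tuple[tuple | None, tuple | None, float | None]:
    """Extract (voxel_size, channel_names, expansion_factor) from OME XML."""
    root = ET.fromstring(xml_text)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    voxel_size = None
    names = None
    expansion = None
    if pixels is not None:
        try:
            voxel_size = tuple(
                float(pixels.attrib[f"PhysicalSize{ax}"]) for ax in "XYZ"
            )
        except KeyError:
            voxel_size = None
        chans = pixels.findall("ome:Channel", ns)
        if chans and all("Name" in c.attrib for c in chans):
            names = tuple(c.attrib["Name"] for c in chans)
    desc = root.find(".//ome:Image/ome:Description", ns)
    if desc is not None and desc.text and "expansion_factor=" in desc.text:
        try:
            expansion = float(desc.text.split("expansion_factor=")[1].split()[0])
        except ValueError:
            expansion = None
    return voxel_size, names, expansion


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
    channel_names: tuple[str, ...] | None = None,
    expansion_factor: float | None = None,
) -> ChannelStack:
    """Read a multi-channel TIFF/OME-TIFF.

    Metadata missing from the file must be supplied via the keyword
    overrides; a voxel size absent from both is an error, never a silent
    default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta_vs = meta_names = None
        meta_exp = None
        if tf.ome_metadata:
            meta_vs, meta_names, meta_exp = _parse_ome(tf.ome_metadata)

    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[None]
    elif data.ndim != 4:
        raise ValueError(f"cannot interpret TIFF of shape {data.shape}")

    vs = voxel_size or meta_vs
    if vs is None:
        raise ValueError(
            f"{path.name}: no voxel size in metadata and none supplied; "
            "pass voxel_size=(x, y, z) in µm explicitly"
        )
    names = channel_names or meta_names or tuple(
        f"ch{i}" for i in range(data.shape[0])
    )
    exp = expansion_factor if expansion_factor is not None else (meta_exp or 1.0)
    return ChannelStack(
        voxels=np.asarray(data, dtype=np.float64),
        channel_names=names,
        voxel_size=tuple(vs),
        expansion_factor=exp,
    )


# ---------------------------------------------------------------------------
# registration


def _projection_shift(moving: np.ndarray, reference: np.ndarray,
                      upsample: int = 20) -> np.ndarray:
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsample, normalization=None
    )
    return shift


def register_channels(
    stack: ChannelStack,
    reference_channel: str = "total",
    order: int = 1,
) -> tuple[ChannelStack, dict[str, tuple[float, float, float]]]:
    """Align each channel to the reference via projection phase correlation.

    The 3D shift is assembled from the XY maximum-intensity projection
    (y, x components) and the XZ projection (z component).  Returns the
    registered stack and the applied (z, y, x) shift per channel.
    """
    if stack.n_channels < 2:
        raise ValueError("registration needs at least 2 channels")
    ref = stack.channel(reference_channel)
    ref_xy = ref.max(axis=0)
    ref_xz = ref.max(axis=1)
    out = np.empty_like(stack.voxels)
    shifts: dict[str, tuple[float, float, float]] = {}
    for i, name in enumerate(stack.channel_names):
        vol = stack.voxels[i]
        if name == reference_channel:
            out[i] = vol
            shifts[name] = (0.0, 0.0, 0.0)
            continue
        if not np.any(vol):
            warnings.warn(
                f"channel {name!r} is all-zero; applying zero shift",
                stacklevel=2,
            )
            out[i] = vol
            shifts[name] = (0.0, 0.0, 0.0)
            continue
        dy, dx = _projection_shift(vol.max(axis=0), ref_xy)
        dz, dx2 = _projection_shift(vol.max(axis=1), ref_xz)
        shift = (float(dz), float(dy), float((dx + dx2) / 2))
        out[i] = np.clip(ndimage.shift(vol, shift, order=order), 0, None)
        shifts[name] = shift
    return stack.with_voxels(out), shifts


# ---------------------------------------------------------------------------
# straighten + reslice


@dataclass
class ReslicedStack:
    """Series of YZ slices perpendicular to a straightened dendrite axis.

    ``slices`` has shape ``(n_channels, n_slices, nz, width)``; within a
    slice, rows run along z and columns along the in-plane normal (y').
    """

    slices: np.ndarray
    channel_names: tuple[str, ...]
    spacing: float  # µm between consecutive slices (along the axis)
    pixel_size: tuple[float, float]  # (y', z) µm within a slice
    expansion_factor: float = 1.0
    provenance: dict = field(default_factory=dict)

    @property
    def n_slices(self) -> int:
        return self.slices.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.slices[self.channel_names.index(name)]


def _smooth_path(path: PolylineRoi, step_px: float,
                 smoothing: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """B-spline the polyline; return points and unit tangents at arc steps."""
    pts = path.vertices
    if len(pts) == 2:
        # straight segment: no spline needed
        d = pts[1] - pts[0]
        L = np.linalg.norm(d)
        n = max(int(np.round(L / step_px)) + 1, 2)
        t = np.linspace(0, 1, n)
        samples = pts[0][None] + t[:, None] * d[None]
        tangents = np.tile(d / L, (n, 1))
        return samples, tangents
    k = min(3, len(pts) - 1)
    tck, _ = splprep(pts.T, s=smoothing, k=k)
    # densely sample to build an arc-length parameterization
    u = np.linspace(0, 1, max(20 * len(pts), 400))
    dense = np.column_stack(splev(u, tck))
    arc = np.concatenate([[0], np.cumsum(
        np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    L = arc[-1]
    n = max(int(np.round(L / step_px)) + 1, 2)
    targets = np.linspace(0, L, n)
    u_t = np.interp(targets, arc, u)
    samples = np.column_stack(splev(u_t, tck))
    deriv = np.column_stack(splev(u_t, tck, der=1))
    tangents = deriv / np.linalg.norm(deriv, axis=1, keepdims=True)
    return samples, tangents


def straighten_and_reslice(
    stack: ChannelStack,
    path: PolylineRoi,
    half_width: int,
    resample_z: bool = False,
    smoothing: float = 0.0,
) -> ReslicedStack:
    """Straighten a dendrite along `path` and reslice perpendicular to it.

    For each arc-length sample (spacing = in-plane pixel size) the plane
    normal to the path is interpolated (bilinear in-plane, linear between
    z planes) into one YZ slice.  With ``resample_z`` the z axis is
    linearly resampled to the in-plane pixel size, yielding isotropic
    slices.
    """
    nz, ny, nx = stack.shape
    dx, dy, dz = stack.voxel_size
    if abs(dx - dy) > 1e-9:
        raise ValueError("straightening assumes square in-plane pixels")

    samples, tangents = _smooth_path(path, step_px=1.0, smoothing=smoothing)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    offsets = np.arange(-half_width, half_width + 1, dtype=float)

    # bounds check with margin
    for vi, v in enumerate(path.vertices):
        if not (half_width <= v[0] <= nx - 1 - half_width
                and half_width <= v[1] <= ny - 1 - half_width):
            raise ValueError(
                f"path vertex {vi} at ({v[0]:.1f}, {v[1]:.1f}) exits the "
                f"image bounds for half_width={half_width}"
            )

    xs = samples[:, 0][:, None] + offsets[None, :] * normals[:, 0][:, None]
    ys = samples[:, 1][:, None] + offsets[None, :] * normals[:, 1][:, None]
    n_s, w = xs.shape
    zz = np.arange(nz, dtype=float)
    coords = np.stack([
        np.broadcast_to(zz[:, None, None], (nz, n_s, w)),
        np.broadcast_to(ys[None], (nz, n_s, w)),
        np.broadcast_to(xs[None], (nz, n_s, w)),
    ])

    out = []
    for c in range(stack.n_channels):
        vol = ndimage.map_coordinates(
            stack.voxels[c], coords.reshape(3, -1), order=1, mode="constant"
        ).reshape(nz, n_s, w)
        out.append(np.moveaxis(vol, 1, 0))  # (n_slices, nz, width)
    slices = np.stack(out)

    pixel_size = (dx, dz)
    if resample_z and abs(dz - dx) > 1e-9:
        zoom = dz / dx
        slices = ndimage.zoom(slices, (1, 1, zoom, 1), order=1)
        slices = np.clip(slices, 0, None)
        pixel_size = (dx, dx)

    return ReslicedStack(
        slices=slices,
        channel_names=stack.channel_names,
        spacing=dx,
        pixel_size=pixel_size,
        expansion_factor=stack.expansion_factor,
        provenance={"n_path_vertices": len(path.vertices)},
    )
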