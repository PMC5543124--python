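"""Volumetric image containers and IO.

Volumes are 3D scalar fields on an isotropic voxel grid, indexed ``(x, y, z)``
with 0-based voxel indices.  World coordinates are voxel-centre positions in
millimetres: ``world = origin_mm + index * pitch_mm``.  Intensities are kept
in arbitrary units exactly as read — contrast micro-CT attenuation ordering is
relative, so no rescaling happens on IO.

Supported on-disk formats: NIfTI-1 (via nibabel), multi-page TIFF or a
directory of numbered single-page TIFFs (via tifffile), and ASCII VTK XML
ImageData (``.vti``) export for rendering.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "reslice",
    "crop",
    "write_vti",
]

_AXES = ("x", "y", "z")


@dataclass
class Volume:
    """A 3D scalar field with isotropic voxel pitch.

    Parameters
    ----------
    data:
        3D array indexed ``(x, y, z)``.
    voxel_pitch_um:
        Isotropic voxel edge length in micrometres (e.g. 73.0 for the
        whole-heart resolution, 28.0 for a sinus-node block).
    origin_mm:
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    voxel_pitch_um: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_names: tuple[str, str, str] = _AXES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"data must be 3D with positive dims, got shape {self.data.shape}")
        if not self.voxel_pitch_um > 0:
            raise ValueError(f"voxel_pitch_um must be > 0, got {self.voxel_pitch_um}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("intensity values must be finite")
        self.origin_mm = tuple(float(c) for c in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def pitch_mm(self) -> float:
        return self.voxel_pitch_um / 1000.0

    def voxel_to_world(self, index) -> np.ndarray:
        """World coordinates (mm) of voxel-centre(s); affine and invertible."""
        return np.asarray(self.origin_mm) + np.asarray(index, dtype=float) * self.pitch_mm

    def world_to_voxel(self, point_mm) -> np.ndarray:
        """Continuous voxel index of a world point (inverse of voxel_to_world)."""
        return (np.asarray(point_mm, dtype=float) - np.asarray(self.origin_mm)) / self.pitch_mm


@dataclass
class LabelVolume:
    """Integer structure labels on the same grid as a source :class:`Volume`.

    ``legend`` maps each nonzero label to a structure name (0 is background).
    """

    labels: np.ndarray
    legend: dict[int, str]
    voxel_pitch_um: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("labels must be an integer array")
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels present but absent from legend: {sorted(missing)}")
        self.origin_mm = tuple(float(c) for c in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def pitch_mm(self) -> float:
        return self.voxel_pitch_um / 1000.0

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the structure called ``name`` (union over labels)."""
        ids = [k for k, v in self.legend.items() if v == name]
        if not ids:
            raise KeyError(f"no label named {name!r} in legend")
        return np.isin(self.labels, ids)

    def label_of(self, name: str) -> int:
        ids = [k for k, v in self.legend.items() if v == name]
        if len(ids) != 1:
            raise KeyError(f"expected exactly one label named {name!r}, found {ids}")
        return ids[0]


# ---------------------------------------------------------------------------
# Read / write
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")) or path.is_dir():
        return "tiff_stack"
    raise ValueError(f"cannot infer volume format from {path}")


def read_volume(
    path,
    format: str | None = None,
    voxel_pitch_um: float | None = None,
    resample_isotropic: bool = False,
) -> Volume:
    """Read a volume from NIfTI or a TIFF stack.

    The intensity dtype is preserved (or widened during optional resampling),
    never narrowed.  Anisotropic NIfTI headers are rejected unless
    ``resample_isotropic=True``, in which case the volume is resampled to the
    finest pitch with trilinear interpolation.

    Parameters
    ----------
    voxel_pitch_um:
        Required for TIFF stacks (no pitch in the format); overrides the
        header for NIfTI if given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format or _infer_format(path)

    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D NIfTI, got shape {data.shape}")
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)  # mm
        if voxel_pitch_um is not None:
            pitch_mm = voxel_pitch_um / 1000.0
        elif np.allclose(zooms, zooms[0], rtol=1e-4):
            pitch_mm = float(zooms[0])
        elif resample_isotropic:
            target = float(zooms.min())
            data = ndimage.zoom(data.astype(np.float64), zooms / target, order=1)
            pitch_mm = target
        else:
            raise ValueError(
                f"anisotropic voxel pitch {zooms} mm; pass resample_isotropic=True "
                "or an explicit voxel_pitch_um"
            )
        origin = tuple(np.asarray(img.affine[:3, 3], dtype=float))
        return Volume(data, pitch_mm * 1000.0, origin)

    if fmt == "tiff_stack":
        if voxel_pitch_um is None:
            raise ValueError("voxel_pitch_um must be supplied for TIFF stacks")
        if path.is_dir():
            files = sorted(
                (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
                key=lambda p: [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", p.name)],
            )
            if not files:
                raise FileNotFoundError(f"no TIFF slices in {path}")
            pages = [tifffile.imread(str(p)) for p in files]
            stack = np.stack(pages, axis=0)
        else:
            stack = tifffile.imread(str(path))
            if stack.ndim == 2:
                stack = stack[None]
        if stack.ndim != 3:
            raise ValueError(f"TIFF stack must be 3D, got shape {stack.shape}")
        # pages are (z, row=y, col=x) -> (x, y, z)
        data = np.ascontiguousarray(stack.transpose(2, 1, 0))
        return Volume(data, voxel_pitch_um)

    raise ValueError(f"unknown format {fmt!r}")


def write_volume(volume: Volume, path, format: str | None = None) -> None:
    """Write a :class:`Volume` so that :func:`read_volume` restores it exactly."""
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "nifti":
        affine = np.diag([volume.pitch_mm] * 3 + [1.0])
        affine[:3, 3] = volume.origin_mm
        img = nib.Nifti1Image(volume.data, affine)
        img.header.set_zooms((volume.pitch_mm,) * 3)
        nib.save(img, str(path))
    elif fmt == "tiff_stack":
        tifffile.imwrite(str(path),
                         np.ascontiguousarray(volume.data.transpose(2, 1, 0)),
                         photometric="minisblack")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_labels(labels: LabelVolume, path) -> None:
    """Write a label volume (NIfTI) with a JSON legend sidecar."""
    path = Path(path)
    vol = Volume(labels.labels, labels.voxel_pitch_um, labels.origin_mm)
    write_volume(vol, path, format="nifti")
    sidecar = path.parent / (path.name.split(".")[0] + ".legend.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in labels.legend.items()}, indent=1))


def read_labels(path, legend: dict[int, str] | None = None) -> LabelVolume:
    path = Path(path)
    vol = read_volume(path, format="nifti")
    if legend is None:
        sidecar = path.parent / (path.name.split(".")[0] + ".legend.json")
        if sidecar.exists():
            legend = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        else:
            legend = {int(k): f"label_{int(k)}" for k in np.unique(vol.data) if k != 0}
    return LabelVolume(vol.data.astype(np.int32), legend, vol.voxel_pitch_um, vol.origin_mm)


# ---------------------------------------------------------------------------
# Geometry operations
# ---------------------------------------------------------------------------

def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis (u, v) with v = n x u.

    u is the unit axis least aligned with the normal, projected into the
    plane; for axis-aligned normals this reproduces the grid axes exactly.
    """
    n = np.asarray(normal, dtype=float)
    e = np.eye(3)[int(np.argmin(np.abs(n)))]
    u = e - np.dot(e, n) * n
    u /= np.linalg.norm(u)
    return u, np.cross(n, u)


def reslice(
    volume: Volume,
    plane_normal,
    plane_point_mm,
    interpolation: str = "trilinear",
    fill_value: float = 0.0,
) -> Volume:
    """Virtually re-slice a volume along an arbitrary plane.

    Returns a one-voxel-thick :class:`Volume` sampled on a regular 2D grid at
    the source pitch.  Out-of-bounds samples take ``fill_value``.  With an
    axis-aligned normal through a voxel centre the result equals the
    corresponding grid slice exactly.
    """
    n = np.asarray(plane_normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("plane normal must be nonzero")
    n = n / norm
    p0 = np.asarray(plane_point_mm, dtype=float)

    lo = np.asarray(volume.origin_mm)
    hi = lo + (np.asarray(volume.shape) - 1) * volume.pitch_mm
    # plane must intersect the bounding box of voxel centres
    corners = np.array([[lo[i] if b & (1 << i) == 0 else hi[i] for i in range(3)]
                        for b in range(8)])
    signed = (corners - p0) @ n
    if signed.min() > 1e-9 or signed.max() < -1e-9:
        raise ValueError("plane does not intersect the volume")

    u, v = _plane_basis(n)
    pitch = volume.pitch_mm
    su = (corners - p0) @ u
    sv = (corners - p0) @ v
    iu = np.arange(np.floor(su.min() / pitch), np.ceil(su.max() / pitch) + 1)
    iv = np.arange(np.floor(sv.min() / pitch), np.ceil(sv.max() / pitch) + 1)
    UU, VV = np.meshgrid(iu * pitch, iv * pitch, indexing="ij")
    pts = p0[None, None] + UU[..., None] * u + VV[..., None] * v
    idx = (pts - lo) / pitch  # continuous voxel indices

    order = {"nearest": 0, "trilinear": 1}[interpolation]
    samp = ndimage.map_coordinates(
        volume.data.astype(float),
        [idx[..., 0], idx[..., 1], idx[..., 2]],
        order=order,
        mode="constant",
        cval=fill_value,
    )
    origin = tuple(p0 + iu[0] * pitch * u + iv[0] * pitch * v)
    out = samp[..., None]
    if interpolation == "nearest" and np.issubdtype(volume.data.dtype, np.integer):
        out = np.round(out).astype(volume.data.dtype)
    return Volume(out, volume.voxel_pitch_um, origin)


def crop(volume: Volume, bounds) -> Volume:
    """Crop to inclusive voxel-index ranges ``((i0,i1),(j0,j1),(k0,k1))``.

    The origin shifts so world coordinates of retained voxels are unchanged.
    """
    bounds = [(int(a), int(b)) for a, b in bounds]
    for (a, b), dim in zip(bounds, volume.shape):
        if not (0 <= a <= b < dim):
            raise ValueError(f"bounds {bounds} invalid for shape {volume.shape}")
    sl = tuple(slice(a, b + 1) for a, b in bounds)
    lo = np.array([a for a, _ in bounds], dtype=float)
    origin = tuple(np.asarray(volume.origin_mm) + lo * volume.pitch_mm)
    return replace(volume, data=volume.data[sl], origin_mm=origin)


def write_vti(path, scalars: dict[str, np.ndarray], voxel_pitch_um: float,
              origin_mm=(0.0, 0.0, 0.0), vectors: dict[str, np.ndarray] | None = None) -> None:
    """Export point-data fields as ASCII VTK XML ImageData for rendering.

    ``scalars`` maps name -> 3D array; ``vectors`` maps name -> (..., 3)
    array on the same grid.  Arrays are written in VTK's x-fastest order.
    """
    arrays = dict(scalars)
    shape = next(iter(arrays.values())).shape[:3]
    pitch = voxel_pitch_um / 1000.0
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="ImageData" version="0.1" byte_order="LittleEndian">',
        f'  <ImageData WholeExtent="0 {shape[0]-1} 0 {shape[1]-1} 0 {shape[2]-1}"'
        f' Origin="{origin_mm[0]} {origin_mm[1]} {origin_mm[2]}"'
        f' Spacing="{pitch} {pitch} {pitch}">',
        f'    <Piece Extent="0 {shape[0]-1} 0 {shape[1]-1} 0 {shape[2]-1}">',
        "      <PointData>",
    ]
    for name, arr in arrays.items():
        flat = np.asarray(arr).transpose(2, 1, 0).ravel()
        lines.append(f'        <DataArray type="Float32" Name="{name}" format="ascii">')
        lines.append("          " + " ".join(f"{v:.6g}" for v in flat))
        lines.append("        </DataArray>")
    for name, arr in (vectors or {}).items():
        flat = np.asarray(arr).transpose(2, 1, 0, 3).reshape(-1, 3)
        lines.append(f'        <DataArray type="Float32" Name="{name}" '
                     'NumberOfComponents="3" format="ascii">')
        lines.append("          " + " ".join(f"{v:.6g}" for row in flat for v in row))
        lines.append("        </DataArray>")
    lines += ["      </PointData>", "    </Piece>", "  </ImageData>", "</VTKFile>", ""]
    Path(path).write_text("\n".join(lines))
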