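"""Fiber-anisotropic conductivity tensors on the label grid.

Conduction is faster along the myocyte chain than across it, so each
conducting voxel carries D = d_T I + (d_L - d_T) f f^T (mm^2/ms) built from
its fiber direction f and per-tissue (d_L, d_T).  Non-conducting labels
(connective tissue, fat, background) get D = 0; conducting voxels without a
valid fiber fall back to isotropic D = mean(d_L, d_T) I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volumes import LabelVolume

__all__ = ["ConductivityField", "build_conductivity"]

#: symmetric-tensor component order
COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclass
class ConductivityField:
    """Per-voxel symmetric diffusion tensor, packed (xx,yy,zz,xy,xz,yz)."""

    tensors: np.ndarray      # (nx, ny, nz, 6), mm^2/ms
    conducting: np.ndarray   # boolean mask
    pitch_mm: float

    def as_matrix(self) -> np.ndarray:
        """Unpack to (..., 3, 3) symmetric matrices."""
        t = self.tensors
        M = np.zeros(t.shape[:-1] + (3, 3))
        M[..., 0, 0], M[..., 1, 1], M[..., 2, 2] = t[..., 0], t[..., 1], t[..., 2]
        M[..., 0, 1] = M[..., 1, 0] = t[..., 3]
        M[..., 0, 2] = M[..., 2, 0] = t[..., 4]
        M[..., 1, 2] = M[..., 2, 1] = t[..., 5]
        return M

    @property
    def max_trace(self) -> float:
        tr = self.tensors[..., :3].sum(axis=-1)
        return float(tr.max())


def build_conductivity(
    labels: LabelVolume,
    fibers: np.ndarray | None,
    tissue_params: dict[str | int, tuple[float, float]],
) -> ConductivityField:
    """Assemble the conductivity field from labels, fibers and (d_L, d_T).

    ``tissue_params`` maps label ids or legend names to ``(d_L, d_T)`` in
    mm^2/ms; labels not listed are non-conducting.  ``fibers`` is an
    ``(nx,ny,nz,3)`` unit-vector field (NaN where undefined) or None for
    fully isotropic tissue.
    """
    name_to_id = {v: k for k, v in labels.legend.items()}
    params: dict[int, tuple[float, float]] = {}
    for key, dl_dt in tissue_params.items():
        lab = name_to_id[key] if isinstance(key, str) else int(key)
        if lab not in labels.legend:
            raise KeyError(f"label {key!r} not in legend")
        d_l, d_t = map(float, dl_dt)
        if not (d_l >= d_t > 0):
            raise ValueError(f"need d_L >= d_T > 0 for {key!r}, got {dl_dt}")
        params[lab] = (d_l, d_t)

    shape = labels.shape
    tens = np.zeros(shape + (6,))
    conducting = np.isin(labels.labels, list(params))
    if fibers is not None:
        fib_ok = np.all(np.isfinite(fibers), axis=-1)
    else:
        fib_ok = np.zeros(shape, dtype=bool)

    for lab, (d_l, d_t) in params.items():
        m = labels.labels == lab
        aniso = m & fib_ok
        if np.any(aniso):
            f = fibers[aniso]
            delta = d_l - d_t
            tens[aniso, 0] = d_t + delta * f[:, 0] ** 2
            tens[aniso, 1] = d_t + delta * f[:, 1] ** 2
            tens[aniso, 2] = d_t + delta * f[:, 2] ** 2
            tens[aniso, 3] = delta * f[:, 0] * f[:, 1]
            tens[aniso, 4] = delta * f[:, 0] * f[:, 2]
            tens[aniso, 5] = delta * f[:, 1] * f[:, 2]
        iso = m & ~fib_ok
        if np.any(iso):
            d_iso = 0.5 * (d_l + d_t)
            tens[iso, 0] = tens[iso, 1] = tens[iso, 2] = d_iso
    return ConductivityField(tens, conducting, labels.pitch_mm)
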