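"""Parallel-beam projection operator for single-axis tilt geometry.

The beam runs along the z axis of a (z, y, x) volume and the tilt axis is
the vertical y axis, so every y slice is an independent 2-D problem: the
(z, x) plane is rotated by the tilt angle with bilinear interpolation and
summed along z.  The per-angle plane rotation is materialized as a sparse
matrix, which makes the back-projector the *exact* adjoint of the
projector (the transposed matrix) — the property iterative reconstruction
relies on.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["ParallelProjector"]


def _plane_rotation(nz: int, nx: int, angle_deg: float) -> sparse.csr_matrix:
    """Sparse bilinear rotation of the (z, x) plane about its center.

    Row = destination pixel, column = source pixel; out-of-bounds source
    samples are treated as zero (rows just lose weight).
    """
    theta = np.deg2rad(angle_deg)
    cz, cx = (nz - 1) / 2.0, (nx - 1) / 2.0
    z, x = np.meshgrid(np.arange(nz), np.arange(nx), indexing="ij")
    dz, dx = z - cz, x - cx
    # inverse map: sample the source at R(-theta) * dest
    zs = cz + np.cos(theta) * dz + np.sin(theta) * dx
    xs = cx - np.sin(theta) * dz + np.cos(theta) * dx
    z0 = np.floor(zs).astype(np.int64)
    x0 = np.floor(xs).astype(np.int64)
    fz = zs - z0
    fx = xs - x0
    rows, cols, vals = [], [], []
    dest = (z * nx + x).ravel()
    for oz, wz in ((0, 1.0 - fz), (1, fz)):
        for ox, wx in ((0, 1.0 - fx), (1, fx)):
            zi = z0 + oz
            xi = x0 + ox
            w = (wz * wx).ravel()
            ok = ((zi >= 0) & (zi < nz) & (xi >= 0) & (xi < nx)).ravel()
            ok &= w > 0
            rows.append(dest[ok])
            cols.append((zi * nx + xi).ravel()[ok])
            vals.append(w[ok])
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nz * nx, nz * nx),
    )
    return mat.tocsr()


class ParallelProjector:
    """Linear operator A: volume (nz, ny, nx) -> tilt stack (n_angles, ny, nx)."""

    def __init__(self, shape: tuple[int, int, int], angles_deg) -> None:
        if len(shape) != 3:
            raise ValueError("projector requires a 3-D volume shape")
        angles = [float(a) for a in angles_deg]
        if any(abs(a) >= 90.0 for a in angles):
            raise ValueError("tilt angles must lie strictly within (-90, 90) degrees")
        self.shape = tuple(int(s) for s in shape)
        self.angles_deg = angles
        nz, _, nx = self.shape
        self._mats = [_plane_rotation(nz, nx, a) for a in angles]

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    def project(self, volume: np.ndarray) -> np.ndarray:
        """Rotate by each tilt angle and integrate along the beam (z) axis."""
        v = np.asarray(volume, dtype=np.float64)
        if v.shape != self.shape:
            raise ValueError(f"volume shape {v.shape} != projector shape {self.shape}")
        nz, ny, nx = self.shape
        planes = v.transpose(0, 2, 1).reshape(nz * nx, ny)
        stack = np.empty((self.n_angles, ny, nx))
        for i, mat in enumerate(self._mats):
            rot = (mat @ planes).reshape(nz, nx, ny)
            stack[i] = rot.sum(axis=0).T
        return stack

    def backproject(self, stack: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`project`."""
        s = np.asarray(stack, dtype=np.float64)
        nz, ny, nx = self.shape
        if s.shape != (self.n_angles, ny, nx):
            raise ValueError(
                f"stack shape {s.shape} != ({self.n_angles}, {ny}, {nx})")
        acc = np.zeros((nz * nx, ny))
        for i, mat in enumerate(self._mats):
            smeared = np.tile(s[i].T, (nz, 1))  # replicate along z
            acc += mat.T @ smeared
        return acc.reshape(nz, nx, ny).transpose(0, 2, 1)
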