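"""Parallel-beam tomographic reconstruction: WBP and SIRT.

Both reconstructors share the sparse rotate-and-sum projector used to
generate the tilt series, so SIRT's forward/back pair is an exact adjoint
pair.  WBP applies a 1-D ramp filter to each projection row perpendicular
to the tilt axis before back-projection.  SIRT is the simultaneous
additive scheme with row/column-sum normalization (Landweber-SIRT), the
variant common in electron-tomography packages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .projector import ParallelProjector
from .synthetic import TiltSeries

__all__ = ["ReconConfig", "wbp", "sirt"]


@dataclass(frozen=True)
class ReconConfig:
    """Reconstruction method and parameters."""

    method: str = "wbp"
    iterations: int = 15
    relaxation: float = 1.0
    filter: str = "ramp"
    output_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.method not in ("wbp", "sirt"):
            raise ValueError("method must be 'wbp' or 'sirt'")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.relaxation < 2.0:
            raise ValueError("relaxation must lie in (0, 2)")
        if self.filter not in ("ramp", "none"):
            raise ValueError("filter must be 'ramp' or 'none'")


def _resolve_shape(ts: TiltSeries, cfg: ReconConfig) -> tuple[int, int, int]:
    if cfg.output_shape is not None:
        return tuple(int(s) for s in cfg.output_shape)
    _, ny, nx = ts.projections.shape
    return (nx, ny, nx)


def _ramp_filter(stack: np.ndarray) -> np.ndarray:
    """1-D frequency-ramp filtering along x (perpendicular to the tilt axis)."""
    nx = stack.shape[-1]
    ramp = 2.0 * np.abs(np.fft.fftfreq(nx))
    return np.fft.ifft(np.fft.fft(stack, axis=-1) * ramp, axis=-1).real


def wbp(ts: TiltSeries, cfg: ReconConfig | None = None) -> np.ndarray:
    """Weighted (ramp-filtered) back projection.  Linear in the input."""
    if cfg is None:
        cfg = ReconConfig(method="wbp")
    if len(ts) < 2:
        raise ValueError("WBP needs at least 2 projections")
    shape = _resolve_shape(ts, cfg)
    proj = ParallelProjector(shape, ts.angles_deg)
    stack = ts.projections
    if cfg.filter == "ramp":
        stack = _ramp_filter(stack)
    return proj.backproject(stack) * (np.pi / (2.0 * len(ts)))


def sirt(ts: TiltSeries, cfg: ReconConfig | None = None) -> np.ndarray:
    """Simultaneous iterative reconstruction with additive updates.

    x <- x + λ·C·Aᵀ·R·(b - A·x), with R and C the reciprocal row/column
    sums of the projection operator A.  Stops early with a warning if the
    residual norm grows three iterations running.
    """
    if cfg is None:
        cfg = ReconConfig(method="sirt")
    if len(ts) < 2:
        raise ValueError("SIRT needs at least 2 projections")
    shape = _resolve_shape(ts, cfg)
    proj = ParallelProjector(shape, ts.angles_deg)
    b = ts.projections

    row = proj.project(np.ones(shape))
    col = proj.backproject(np.ones_like(b))
    rinv = np.where(row > 1e-9, 1.0 / np.maximum(row, 1e-9), 0.0)
    cinv = np.where(col > 1e-9, 1.0 / np.maximum(col, 1e-9), 0.0)

    x = np.zeros(shape)
    prev_norm = np.inf
    growing = 0
    for _ in range(cfg.iterations):
        resid = b - proj.project(x)
        norm = float(np.linalg.norm(resid))
        if norm > prev_norm:
            growing += 1
            if growing >= 3:
                warnings.warn("SIRT residual grew 3 iterations running; "
                              "stopping early", stacklevel=2)
                break
        else:
            growing = 0
        prev_norm = norm
        x = x + cfg.relaxation * cinv * proj.backproject(rinv * resid)
    return x
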