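"""Simulation inputs: geometric phantom, SNR-calibrated Gaussian noise and
parallel-beam tilt series.

The phantom emulates a multi-primitive density test object spanning coarse
and fine scales — a large ellipsoid body, spheres of decreasing radius and
increasing contrast, a thin cylinder and a small box — so that both smooth
regions and fine detail are available when judging a denoiser.  All
primitives of the default spec sit inside the cylinder inscribed about the
tilt (y) axis, so rotation during projection loses no mass.

Noise is calibrated by the variance-ratio SNR convention: for a target
SNR s the additive white Gaussian noise gets σ = sqrt(Var(signal)/s), with
the signal variance taken within the evaluation mask when one is given.
The default target (0.1) matches the noise level of a real cryo-tomogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import as_array
from .projector import ParallelProjector

__all__ = [
    "Primitive",
    "PhantomSpec",
    "TiltSeries",
    "default_phantom_spec",
    "make_phantom",
    "support_mask",
    "add_noise_to_snr",
    "tilt_angles",
    "project_tilt_series",
    "noisy_tilt_series",
]

KINDS = ("sphere", "ellipsoid", "cylinder", "box")

#: Default simulated acquisition noise level, matching a real cryo-tomogram.
DEFAULT_TARGET_SNR = 0.1


@dataclass(frozen=True)
class Primitive:
    """One solid: ``size`` is radius (sphere), semi-axes (ellipsoid/box)
    or (radius, half_length) for a y-axis cylinder.  Coordinates in voxels,
    (z, y, x) order."""

    kind: str
    center: tuple[float, float, float]
    size: tuple[float, ...]
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")

    def extent(self) -> np.ndarray:
        """Per-axis half-extent, for the inside-the-volume check."""
        if self.kind == "sphere":
            r = self.size[0]
            return np.array([r, r, r])
        if self.kind == "ellipsoid":
            return np.asarray(self.size, dtype=float)
        if self.kind == "box":
            return np.asarray(self.size, dtype=float)
        r, half = self.size
        return np.array([r, half, r])

    def mask(self, grids) -> np.ndarray:
        z, y, x = grids
        cz, cy, cx = self.center
        if self.kind == "sphere":
            r = self.size[0]
            return (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= r ** 2
        if self.kind == "ellipsoid":
            az, ay, ax_ = self.size
            return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax_) ** 2 <= 1.0
        if self.kind == "box":
            hz, hy, hx = self.size
            return ((np.abs(z - cz) <= hz) & (np.abs(y - cy) <= hy)
                    & (np.abs(x - cx) <= hx))
        r, half = self.size
        return ((z - cz) ** 2 + (x - cx) ** 2 <= r ** 2) & (np.abs(y - cy) <= half)


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic phantom description (no randomness involved)."""

    shape: tuple[int, int, int] = (64, 64, 64)
    primitives: tuple[Primitive, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be 3 positive integers")
        bounds = np.asarray(self.shape, dtype=float)
        for p in self.primitives:
            c = np.asarray(p.center, dtype=float)
            ext = p.extent()
            if np.any(c - ext < -0.5) or np.any(c + ext > bounds - 0.5):
                raise ValueError(f"primitive {p.kind} at {p.center} extends "
                                 "outside the volume")


def default_phantom_spec(shape: tuple[int, int, int] = (64, 64, 64)) -> PhantomSpec:
    """Six-primitive density phantom, scaled proportionally to ``shape``."""
    sz, sy, sx = (s / 64.0 for s in shape)

    def c(z, y, x):
        return (z * sz, y * sy, x * sx)

    prims = (
        Primitive("ellipsoid", c(32, 32, 32), (18 * sz, 22 * sy, 14 * sx), 1.0),
        Primitive("sphere", c(22, 40, 24), (6 * min(sz, sy, sx),), 2.0),
        Primitive("sphere", c(40, 22, 40), (4 * min(sz, sy, sx),), 3.0),
        Primitive("sphere", c(32, 48, 20), (2 * min(sz, sy, sx),), 4.0),
        Primitive("cylinder", c(44, 32, 32), (1.5 * min(sz, sx), 14 * sy), 2.5),
        Primitive("box", c(20, 20, 44), (3 * sz, 3 * sy, 3 * sx), 1.5),
    )
    return PhantomSpec(shape=tuple(int(s) for s in shape), primitives=prims)


def make_phantom(spec: PhantomSpec | None = None) -> np.ndarray:
    """Render the phantom: voxel value = sum of intensities covering it."""
    if spec is None:
        spec = default_phantom_spec()
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in spec.shape),
                        indexing="ij")
    vol = np.zeros(spec.shape)
    for p in spec.primitives:
        vol += p.intensity * p.mask(grids)
    return vol


def support_mask(volume, dilate: int = 2) -> np.ndarray:
    """Binary support of the phantom (non-zero voxels) dilated by ``dilate``."""
    v = as_array(volume)
    m = v != 0
    if dilate > 0:
        m = ndimage.binary_dilation(m, iterations=dilate)
    return m


def add_noise_to_snr(image, target_snr: float = DEFAULT_TARGET_SNR,
                     seed: int | None = None, mask=None,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Add white Gaussian noise with σ calibrated to the variance-ratio SNR.

    Deterministic for a given ``seed``.  ``mask`` restricts the signal
    variance used for calibration (not where noise is added).
    """
    x = as_array(image)
    if target_snr <= 0:
        raise ValueError("target_snr must be > 0")
    sig = x[np.asarray(mask, dtype=bool)] if mask is not None else x
    var = float(np.var(sig))
    if var == 0.0:
        raise ValueError("image is constant within the mask; cannot calibrate noise")
    sigma = np.sqrt(var / target_snr)
    if rng is None:
        rng = np.random.default_rng(seed)
    return x + rng.normal(0.0, sigma, size=x.shape)


def tilt_angles(start: float = -70.0, stop: float = 70.0,
                step: float = 1.0) -> np.ndarray:
    """Tilt angles ``start..stop`` inclusive with the given increment."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass
class TiltSeries:
    """Ordered projection stack with matching tilt angles (degrees) about
    the vertical (y) tilt axis."""

    projections: np.ndarray
    angles_deg: np.ndarray
    axis: str = "y"

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.projections.ndim != 3:
            raise ValueError("projections must be a (n_angles, ny, nx) stack")
        if len(self.projections) != len(self.angles_deg):
            raise ValueError("number of projections and angles differ")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")

    def __len__(self) -> int:
        return len(self.angles_deg)


def project_tilt_series(volume, angles_deg) -> TiltSeries:
    """Parallel-beam line integrals of a 3-D volume over the tilt range."""
    v = as_array(volume)
    if v.ndim != 3:
        raise ValueError("project_tilt_series requires a 3-D volume")
    proj = ParallelProjector(v.shape, angles_deg)
    return TiltSeries(projections=proj.project(v),
                      angles_deg=np.asarray(angles_deg, dtype=float))


def noisy_tilt_series(volume, angles_deg,
                      target_snr: float = DEFAULT_TARGET_SNR,
                      seed: int | None = None) -> TiltSeries:
    """Project, then add per-image SNR-calibrated Gaussian noise."""
    ts = project_tilt_series(volume, angles_deg)
    rng = np.random.default_rng(seed)
    noisy = np.stack([add_noise_to_snr(p, target_snr, rng=rng)
                      for p in ts.projections])
    return TiltSeries(projections=noisy, angles_deg=ts.angles_deg, axis=ts.axis)
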