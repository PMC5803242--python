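"""Undecimated (dyadic) spline wavelet transform for 2-D and 3-D images.

The transform is the redundant, translation-invariant filter-bank
decomposition used in multiscale edge analysis: at every level *j* the
current approximation is smoothed with the quadratic-spline low-pass filter
dilated à trous (2**(j-1)-1 zeros between taps), and one detail band per
axis records a first-difference (gradient-like) component.  Nothing is
downsampled, so every band has the shape of the input and circularly
shifting the input shifts every band identically.

Per level the bands are produced axis-by-axis: band ``d`` is the high-pass
response along axis ``d`` of the signal already low-passed along the axes
preceding ``d``.  This telescoped arrangement is what makes the inverse an
exact finite-filter identity: with the per-axis perfect-reconstruction
condition ``H(z)·H̃(z) + G(z)·K(z) = 1`` the multi-dimensional round trip
is exact to machine precision under periodic indexing.

Levels are 1-based (level 1 = finest), matching the usual convention of
multiresolution denoising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .image import as_array

__all__ = [
    "Kernel",
    "FilterBank",
    "WaveletPyramid",
    "default_spline_bank",
    "forward_ddwt",
    "inverse_ddwt",
]

BOUNDARIES = ("periodic", "mirror")


class Kernel(NamedTuple):
    """A 1-D FIR filter: ``taps[i]`` is the coefficient at position ``nmin + i``."""

    taps: tuple[float, ...]
    nmin: int


def _seq_mul(a: Kernel, b: Kernel) -> Kernel:
    return Kernel(tuple(np.convolve(a.taps, b.taps)), a.nmin + b.nmin)


def _seq_sub(a: Kernel, b: Kernel) -> Kernel:
    lo = min(a.nmin, b.nmin)
    hi = max(a.nmin + len(a.taps), b.nmin + len(b.taps))
    out = np.zeros(hi - lo)
    out[a.nmin - lo : a.nmin - lo + len(a.taps)] += a.taps
    out[b.nmin - lo : b.nmin - lo + len(b.taps)] -= b.taps
    return Kernel(tuple(out), lo)


def _seq_div(p: Kernel, g: Kernel) -> Kernel:
    """Exact deconvolution p / g; raises if the division leaves a remainder."""
    # A kernel is z^{-nmin} * poly(x) with x = z^{-1}, ascending coefficients.
    q, r = np.polydiv(p.taps[::-1], g.taps[::-1])
    if np.max(np.abs(r)) > 1e-10:
        raise ValueError("filter division has a non-zero remainder; no FIR inverse")
    return Kernel(tuple(q[::-1]), p.nmin - g.nmin)


def _trim(k: Kernel, tol: float = 1e-14) -> Kernel:
    taps = np.asarray(k.taps)
    nz = np.nonzero(np.abs(taps) > tol)[0]
    if len(nz) == 0:
        return Kernel((0.0,), 0)
    return Kernel(tuple(taps[nz[0] : nz[-1] + 1]), k.nmin + int(nz[0]))


@dataclass(frozen=True)
class FilterBank:
    """Analysis/synthesis filter quadruple for the undecimated transform.

    The four filters must satisfy the perfect-reconstruction identity
    ``H·H̃ + G·K = δ`` as a convolution identity; this is verified
    numerically at construction.
    """

    analysis_low: Kernel
    analysis_high: Kernel
    synthesis_low: Kernel
    synthesis_high: Kernel
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"boundary must be one of {BOUNDARIES}")
        for k in (self.analysis_low, self.analysis_high,
                  self.synthesis_low, self.synthesis_high):
            if not np.all(np.isfinite(k.taps)):
                raise ValueError("filter taps must be finite")
        # H·H̃ + G·K must equal the unit impulse.
        ident = _seq_sub(
            _seq_mul(self.analysis_low, self.synthesis_low),
            _seq_sub(Kernel((1.0,), 0),
                     _seq_mul(self.analysis_high, self.synthesis_high)),
        )
        err = max(abs(t) for t in _trim(ident).taps)
        if err > 1e-10:
            raise ValueError(f"filter bank violates perfect reconstruction ({err:.2e})")

    def with_boundary(self, boundary: str) -> "FilterBank":
        return FilterBank(self.analysis_low, self.analysis_high,
                          self.synthesis_low, self.synthesis_high, boundary)


def default_spline_bank(boundary: str = "periodic") -> FilterBank:
    """Quadratic-spline analysis pair with the FIR synthesis pair solved
    from the perfect-reconstruction condition.

    The low-pass filter is the binomial [1, 3, 3, 1]/8 (DC gain 1) and the
    high-pass is the two-tap first difference; the synthesis high-pass K is
    obtained by exact polynomial division of ``1 - H·H̃`` by G.
    """
    h = Kernel((0.125, 0.375, 0.375, 0.125), -2)
    g = Kernel((1.0, -1.0), -1)
    h_syn = Kernel(h.taps[::-1], -(h.nmin + len(h.taps) - 1))  # time reverse
    p = _seq_sub(Kernel((1.0,), 0), _seq_mul(h, h_syn))
    k = _trim(_seq_div(p, g))
    return FilterBank(h, g, h_syn, k, boundary)


def _conv_axis(x: np.ndarray, kern: Kernel, axis: int, stride: int,
               boundary: str) -> np.ndarray:
    """Convolve along one axis with the à-trous-dilated kernel.

    ``y[m] = sum_i taps[i] * x_ext[m - (nmin + i) * stride]`` where the
    extension is circular (periodic) or whole-sample reflection (mirror).
    """
    n = x.shape[axis]
    base = np.arange(n)
    y = np.zeros(x.shape, dtype=np.float64)
    for i, t in enumerate(kern.taps):
        if t == 0.0:
            continue
        src = base - (kern.nmin + i) * stride
        if boundary == "periodic":
            src = np.mod(src, n)
        else:
            period = 2 * n - 2 if n > 1 else 1
            src = np.mod(src, period)
            src = np.minimum(src, period - src)
        y += t * np.take(x, src, axis=axis)
    return y


@dataclass
class WaveletPyramid:
    """Undecimated decomposition: one approximation plus J·D detail bands.

    ``details`` maps ``(level, dim)`` with 1-based level (1 = finest) and
    1-based dim (1 = first array axis) to a band of the source shape.
    """

    approximation: np.ndarray
    details: dict[tuple[int, int], np.ndarray]
    levels: int
    ndim: int
    source_shape: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.source_shape:
            self.source_shape = tuple(self.approximation.shape)
        self.validate()

    def validate(self) -> None:
        expected = {(j, d) for j in range(1, self.levels + 1)
                    for d in range(1, self.ndim + 1)}
        if set(self.details) != expected:
            missing = sorted(expected - set(self.details))
            extra = sorted(set(self.details) - expected)
            raise ValueError(
                f"pyramid bands inconsistent: missing {missing}, unexpected {extra}")
        if tuple(self.approximation.shape) != tuple(self.source_shape):
            raise ValueError("approximation shape differs from source shape")
        for key, band in self.details.items():
            if tuple(band.shape) != tuple(self.source_shape):
                raise ValueError(
                    f"band {key} has shape {band.shape}, expected {self.source_shape}")

    def band(self, level: int, dim: int) -> np.ndarray:
        return self.details[(level, dim)]

    def level_bands(self, level: int) -> list[np.ndarray]:
        return [self.details[(level, d)] for d in range(1, self.ndim + 1)]

    def copy(self) -> "WaveletPyramid":
        return WaveletPyramid(
            approximation=self.approximation.copy(),
            details={k: v.copy() for k, v in self.details.items()},
            levels=self.levels,
            ndim=self.ndim,
            source_shape=self.source_shape,
        )


def forward_ddwt(image, levels: int = 3,
                 bank: FilterBank | None = None) -> WaveletPyramid:
    """Decompose an image/volume into ``levels`` undecimated detail levels.

    Raises a sizing error naming the first axis shorter than ``2**levels``.
    """
    if bank is None:
        bank = default_spline_bank()
    if levels < 1:
        raise ValueError("levels must be >= 1")
    x = as_array(image)
    for ax, n in enumerate(x.shape):
        if n < 2 ** levels:
            raise ValueError(
                f"axis {ax} has length {n} < 2**levels = {2 ** levels}; "
                "too small for the requested decomposition depth")
    approx = x.astype(np.float64, copy=True)
    details: dict[tuple[int, int], np.ndarray] = {}
    for j in range(1, levels + 1):
        stride = 2 ** (j - 1)
        for d in range(x.ndim):
            details[(j, d + 1)] = _conv_axis(
                approx, bank.analysis_high, d, stride, bank.boundary)
            approx = _conv_axis(approx, bank.analysis_low, d, stride, bank.boundary)
    return WaveletPyramid(approximation=approx, details=details,
                          levels=levels, ndim=x.ndim, source_shape=x.shape)


def inverse_ddwt(pyramid: WaveletPyramid,
                 bank: FilterBank | None = None) -> np.ndarray:
    """Reconstruct the image from a (possibly modified) pyramid.

    Exact left-inverse of :func:`forward_ddwt` for unmodified coefficients
    under periodic boundary handling.
    """
    if bank is None:
        bank = default_spline_bank()
    pyramid.validate()
    approx = pyramid.approximation.astype(np.float64, copy=True)
    for j in range(pyramid.levels, 0, -1):
        stride = 2 ** (j - 1)
        for d in range(pyramid.ndim - 1, -1, -1):
            approx = (
                _conv_axis(approx, bank.synthesis_low, d, stride, bank.boundary)
                + _conv_axis(pyramid.details[(j, d + 1)], bank.synthesis_high,
                             d, stride, bank.boundary)
            )
    return approx
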