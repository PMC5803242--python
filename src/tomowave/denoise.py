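"""Wavelet-domain denoising strategies for cryo-ET images and volumes.

Four coefficient-modification strategies operate between the forward and
inverse undecimated spline wavelet transform:

``w1``
    Direct soft thresholding of every detail band with one global
    threshold (a user constant or the universal threshold σ√(2 ln N)).
``w2``
    Modified shrinkage: chosen fine levels are zeroed outright; every
    remaining band is soft-thresholded with a subband-dependent threshold
    λ = σ_j² / sd(band), where σ_j is the robust median noise estimate
    Median(|W_j|)/0.6745 pooled over the level's bands.
``w3``
    Spatially adaptive thresholding: bands at the chosen levels are
    replaced by their moving-window mean (5×5 or 5×5×5 by default).
``w4``
    Cross-scale regularization: fine-level coefficients are attenuated by
    the normalized wavelet modulus of the next-coarser level, so only
    features persistent across scales survive.

The package's flagship configuration — the *modified wavelet shrinkage
filter* — is ``w2`` with a three-level decomposition, level 1 zeroed and
subband-dependent soft thresholding; it is the default ``DenoiseConfig``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import ndimage

from .ddwt import FilterBank, WaveletPyramid, default_spline_bank, forward_ddwt, inverse_ddwt
from .image import Image, as_array

__all__ = [
    "DenoiseConfig",
    "ThresholdSet",
    "soft_threshold",
    "universal_threshold",
    "median_sigma",
    "subband_threshold",
    "subband_thresholds",
    "apply_w1",
    "apply_w2",
    "apply_w3",
    "apply_w4",
    "denoise_image",
    "denoise_slices",
]

STRATEGIES = ("w1", "w2", "w3", "w4")
THRESHOLD_MODES = ("universal", "subband")

#: 0.75 quantile of the standard normal; Median(|N(0,σ²)|) = 0.6745·σ.
MAD_SCALE = 0.6745


@dataclass(frozen=True)
class DenoiseConfig:
    """Denoising strategy selection and its tunable parameters.

    The defaults reproduce the modified wavelet shrinkage filter: three
    decomposition levels, strategy ``w2``, level 1 zeroed, subband-dependent
    soft thresholding.
    """

    strategy: str = "w2"
    levels: int = 3
    zero_levels: frozenset[int] = frozenset({1})
    modify_levels: frozenset[int] | None = None
    neighborhood: int = 5
    noise_sigma: float | None = None
    threshold_mode: str = "subband"
    lam: float | None = None
    boundary: str = "periodic"
    # BayesShrink-style variant: use sqrt(max(sd² - σ_j², 0)) instead of the
    # plain subband SD in the threshold denominator.  Non-default.
    subtract_noise_variance: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValueError(f"threshold_mode must be one of {THRESHOLD_MODES}")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        object.__setattr__(self, "zero_levels", frozenset(self.zero_levels))
        if self.modify_levels is not None:
            object.__setattr__(self, "modify_levels", frozenset(self.modify_levels))
        valid = set(range(1, self.levels + 1))
        if not set(self.zero_levels) <= valid:
            raise ValueError(f"zero_levels {sorted(self.zero_levels)} outside 1..{self.levels}")
        if self.modify_levels is not None and not set(self.modify_levels) <= valid:
            raise ValueError(f"modify_levels {sorted(self.modify_levels)} outside 1..{self.levels}")
        if self.neighborhood < 3 or self.neighborhood % 2 == 0:
            raise ValueError("neighborhood must be odd and >= 3")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lam must be >= 0")

    @property
    def resolved_modify_levels(self) -> frozenset[int]:
        if self.modify_levels is not None:
            return self.modify_levels
        if self.strategy == "w3":
            return frozenset({1})
        if self.strategy == "w4":
            return frozenset({1, 2}) & frozenset(range(1, self.levels))
        return frozenset()

    @property
    def label(self) -> str:
        """Results-style label, e.g. ``w2_1`` for w2 with level 1 zeroed."""
        if self.strategy == "w2":
            lv = sorted(self.zero_levels)
        elif self.strategy in ("w3", "w4"):
            lv = sorted(self.resolved_modify_levels)
        else:
            lv = []
        suffix = "".join(str(v) for v in lv)
        return f"{self.strategy}_{suffix}" if suffix else self.strategy

    def to_yaml(self) -> str:
        d = {
            "strategy": self.strategy,
            "levels": self.levels,
            "zero_levels": sorted(self.zero_levels),
            "modify_levels": (None if self.modify_levels is None
                              else sorted(self.modify_levels)),
            "neighborhood": self.neighborhood,
            "noise_sigma": self.noise_sigma,
            "threshold_mode": self.threshold_mode,
            "lam": self.lam,
            "boundary": self.boundary,
            "subtract_noise_variance": self.subtract_noise_variance,
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DenoiseConfig":
        d = yaml.safe_load(text) or {}
        for key in ("zero_levels", "modify_levels"):
            if d.get(key) is not None:
                d[key] = frozenset(d[key])
        return cls(**d)


@dataclass
class ThresholdSet:
    """Thresholds and noise estimates actually used by a shrinkage pass."""

    per_band: dict[tuple[int, int], float] = field(default_factory=dict)
    sigma_per_level: dict[int, float] = field(default_factory=dict)
    sigma_global: float | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.per_band.values()):
            raise ValueError("thresholds must be >= 0")
        if any(v < 0 for v in self.sigma_per_level.values()):
            raise ValueError("sigma estimates must be >= 0")


def soft_threshold(coeffs: np.ndarray, lam: float) -> np.ndarray:
    """Shrink coefficients toward zero by ``lam``, zeroing those below it."""
    if lam < 0:
        raise ValueError("threshold must be >= 0")
    w = np.asarray(coeffs, dtype=np.float64)
    if lam == 0:
        return w.copy()
    if np.isinf(lam):
        return np.zeros_like(w)
    return np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)


def universal_threshold(sigma: float, n: float) -> float:
    """Donoho–Johnstone universal threshold σ√(2 ln N).

    ``n`` is the sample count; any real value >= 1 is accepted.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(sigma) * float(np.sqrt(2.0 * np.log(n)))


def median_sigma(coeffs) -> float:
    """Robust noise-SD estimate Median(|W|)/0.6745.

    ``coeffs`` may be one band or a sequence of bands; bands are pooled.
    For even counts the median is the mean of the two central order
    statistics.
    """
    if isinstance(coeffs, np.ndarray):
        flat = coeffs.ravel()
    else:
        parts = [np.asarray(c).ravel() for c in coeffs]
        flat = np.concatenate(parts) if parts else np.array([])
    if flat.size == 0:
        raise ValueError("median_sigma requires at least one coefficient")
    return float(np.median(np.abs(flat)) / MAD_SCALE)


def subband_threshold(noise_var_j: float, subband_sd: float) -> float:
    """Subband-dependent threshold σ_j² / sd; +inf when the band SD is zero."""
    if noise_var_j < 0:
        raise ValueError("noise variance must be >= 0")
    if noise_var_j == 0:
        return 0.0
    if subband_sd <= 0:
        return np.inf
    return float(noise_var_j / subband_sd)


def _level_sigmas(pyramid: WaveletPyramid, cfg: DenoiseConfig) -> dict[int, float]:
    if cfg.noise_sigma is not None:
        return {j: float(cfg.noise_sigma) for j in range(1, pyramid.levels + 1)}
    return {j: median_sigma(pyramid.level_bands(j))
            for j in range(1, pyramid.levels + 1)}


def subband_thresholds(pyramid: WaveletPyramid, cfg: DenoiseConfig) -> ThresholdSet:
    """Per-band thresholds for the modified-shrinkage strategy (w2)."""
    sigmas = _level_sigmas(pyramid, cfg)
    n = int(np.prod(pyramid.source_shape))
    per_band: dict[tuple[int, int], float] = {}
    for (j, d), band in pyramid.details.items():
        if j in cfg.zero_levels:
            per_band[(j, d)] = np.inf
            continue
        if cfg.threshold_mode == "universal":
            per_band[(j, d)] = universal_threshold(sigmas[j], n)
            continue
        sd = float(np.std(band))
        if cfg.subtract_noise_variance:
            sd = float(np.sqrt(max(sd ** 2 - sigmas[j] ** 2, 0.0)))
        per_band[(j, d)] = subband_threshold(sigmas[j] ** 2, sd)
    return ThresholdSet(per_band=per_band, sigma_per_level=sigmas)


def apply_w1(pyramid: WaveletPyramid, cfg: DenoiseConfig) -> WaveletPyramid:
    """Direct soft thresholding of every detail band with one global λ."""
    if cfg.strategy != "w1":
        raise ValueError("apply_w1 requires cfg.strategy == 'w1'")
    if cfg.lam is not None:
        lam = float(cfg.lam)
    else:
        sigma = cfg.noise_sigma
        if sigma is None:
            sigma = median_sigma(pyramid.level_bands(1))
        lam = universal_threshold(sigma, int(np.prod(pyramid.source_shape)))
    out = pyramid.copy()
    for key in out.details:
        out.details[key] = soft_threshold(out.details[key], lam)
    return out


def apply_w2(pyramid: WaveletPyramid, cfg: DenoiseConfig) -> WaveletPyramid:
    """Modified shrinkage: zero chosen levels, subband-threshold the rest."""
    if cfg.strategy != "w2":
        raise ValueError("apply_w2 requires cfg.strategy == 'w2'")
    ts = subband_thresholds(pyramid, cfg)
    if all(np.isinf(v) for v in ts.per_band.values()):
        warnings.warn("all detail bands zeroed; output is the approximation only",
                      stacklevel=2)
    out = pyramid.copy()
    for key in out.details:
        out.details[key] = soft_threshold(out.details[key], ts.per_band[key])
    return out


def apply_w3(pyramid: WaveletPyramid, cfg: DenoiseConfig) -> WaveletPyramid:
    """Spatially adaptive thresholding: moving-window mean of chosen bands."""
    if cfg.strategy != "w3":
        raise ValueError("apply_w3 requires cfg.strategy == 'w3'")
    m = cfg.neighborhood
    if any(m > s for s in pyramid.source_shape):
        raise ValueError(
            f"neighborhood {m} exceeds band shape {pyramid.source_shape}")
    out = pyramid.copy()
    for (j, d), band in out.details.items():
        if j in cfg.zero_levels and j not in cfg.resolved_modify_levels:
            out.details[(j, d)] = np.zeros_like(band)
        elif j in cfg.resolved_modify_levels:
            out.details[(j, d)] = ndimage.uniform_filter(band, size=m, mode="mirror")
    return out


def apply_w4(pyramid: WaveletPyramid, cfg: DenoiseConfig) -> WaveletPyramid:
    """Cross-scale regularization via the normalized coarser-level modulus.

    For each level j (coarse to fine) the detail vector is scaled pointwise
    by the [0, 1]-normalized wavelet modulus of the already-processed level
    j+1.  The fused update W̃ = M^norm·W is used, which equals the
    modulus/direction decomposition wherever the modulus is non-zero and is
    zero (well-defined) where it vanishes.
    """
    if cfg.strategy != "w4":
        raise ValueError("apply_w4 requires cfg.strategy == 'w4'")
    modify = sorted(cfg.resolved_modify_levels, reverse=True)
    if any(j + 1 > pyramid.levels for j in modify):
        raise ValueError("cross-scale regularization needs a coarser level: "
                         f"modify_levels must be within 1..{pyramid.levels - 1}")
    out = pyramid.copy()
    for j in modify:
        coarse = np.sqrt(sum(b ** 2 for b in out.level_bands(j + 1)))
        mx = float(coarse.max())
        if mx == 0.0:
            warnings.warn(
                f"wavelet modulus at level {j + 1} is identically zero; "
                f"zeroing level {j} bands", stacklevel=2)
            scale = np.zeros_like(coarse)
        else:
            scale = coarse / mx
        for d in range(1, out.ndim + 1):
            out.details[(j, d)] = scale * out.details[(j, d)]
    return out


_APPLY = {"w1": apply_w1, "w2": apply_w2, "w3": apply_w3, "w4": apply_w4}


def apply_strategy(pyramid: WaveletPyramid, cfg: DenoiseConfig) -> WaveletPyramid:
    return _APPLY[cfg.strategy](pyramid, cfg)


def denoise_image(image, cfg: DenoiseConfig | None = None,
                  bank: FilterBank | None = None):
    """Forward transform, coefficient modification, inverse transform.

    Returns the same container kind as the input (``Image`` in, ``Image``
    out; array in, array out).
    """
    if cfg is None:
        cfg = DenoiseConfig()
    if bank is None:
        bank = default_spline_bank(cfg.boundary)
    elif bank.boundary != cfg.boundary:
        bank = bank.with_boundary(cfg.boundary)
    data = as_array(image)
    if cfg.strategy == "w1" and cfg.lam is None and cfg.noise_sigma is None:
        # universal threshold from the SD of the measured data itself
        cfg = replace(cfg, noise_sigma=float(np.std(data)))
    pyr = forward_ddwt(data, cfg.levels, bank)
    pyr = apply_strategy(pyr, cfg)
    result = inverse_ddwt(pyr, bank)
    if isinstance(image, Image):
        return Image(result, spacing=image.spacing)
    return result


def denoise_slices(volume, cfg: DenoiseConfig | None = None,
                   bank: FilterBank | None = None, axis: int = 1):
    """Denoise a 3-D volume slice-by-slice with the 2-D filter.

    ``axis`` selects the slicing axis; the default (1, the y axis of a
    z-y-x volume) reproduces per-y-slice 2-D filtering.  Each slice is
    processed independently.
    """
    data = as_array(volume)
    if data.ndim != 3:
        raise ValueError("denoise_slices requires a 3-D volume")
    out = np.empty_like(data)
    mover = np.moveaxis(data, axis, 0)
    dest = np.moveaxis(out, axis, 0)
    for i in range(mover.shape[0]):
        dest[i] = denoise_image(mover[i], cfg, bank)
    if isinstance(volume, Image):
        return Image(out, spacing=volume.spacing)
    return out
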