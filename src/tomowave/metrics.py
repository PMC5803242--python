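"""Evaluation of a denoised or reconstructed field against a noise-free
reference: variance-ratio SNR, MSE and the cross-correlation coefficient,
optionally restricted to a binary mask.

SNR here is the centered sum of squares of the reference divided by the
squared-error sum of the candidate — an output-quality measure, not the
acquisition SNR.  Means are taken within the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image import as_array

__all__ = ["MetricsReport", "snr", "mse", "ccc", "evaluate"]


def _masked_pair(candidate, reference, mask):
    c = as_array(candidate).ravel()
    r = as_array(reference).ravel()
    if c.shape != r.shape:
        raise ValueError("candidate and reference shapes differ")
    if mask is not None:
        m = np.asarray(mask).astype(bool).ravel()
        if m.shape != c.shape:
            raise ValueError("mask shape differs from images")
        c, r = c[m], r[m]
    if c.size < 2:
        raise ValueError("need at least 2 evaluated voxels")
    return c, r


def snr(candidate, reference, mask=None) -> float:
    """Reference centered sum of squares over the squared-error sum."""
    c, r = _masked_pair(candidate, reference, mask)
    num = float(np.sum((r - r.mean()) ** 2))
    if num == 0.0:
        raise ValueError("reference is constant within the mask; SNR undefined")
    den = float(np.sum((c - r) ** 2))
    if den == 0.0:
        warnings.warn("candidate equals reference; SNR is infinite", stacklevel=2)
        return np.inf
    return num / den


def mse(candidate, reference, mask=None) -> float:
    """Mean squared difference within the mask."""
    c, r = _masked_pair(candidate, reference, mask)
    return float(np.mean((c - r) ** 2))


def ccc(candidate, reference, mask=None) -> float:
    """Cross-correlation coefficient of the centered values, in [-1, 1]."""
    c, r = _masked_pair(candidate, reference, mask)
    dc = c - c.mean()
    dr = r - r.mean()
    vc = float(np.sum(dc ** 2))
    vr = float(np.sum(dr ** 2))
    if vc == 0.0 or vr == 0.0:
        raise ValueError("zero variance within the mask; CCC undefined")
    val = float(np.sum(dc * dr) / np.sqrt(vc * vr))
    return float(np.clip(val, -1.0, 1.0))


@dataclass(frozen=True)
class MetricsReport:
    """SNR/MSE/CCC of one candidate against one reference."""

    snr: float
    mse: float
    ccc: float
    n: int
    mask_used: bool = False

    def as_dict(self) -> dict:
        return {"snr": self.snr, "mse": self.mse, "ccc": self.ccc, "n": self.n}


def evaluate(candidate, reference, mask=None) -> MetricsReport:
    """All three figures of merit in one report."""
    c, _ = _masked_pair(candidate, reference, mask)
    return MetricsReport(
        snr=snr(candidate, reference, mask),
        mse=mse(candidate, reference, mask),
        ccc=ccc(candidate, reference, mask),
        n=int(c.size),
        mask_used=mask is not None,
    )
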