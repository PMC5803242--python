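"""Lightweight image/volume container.

Arrays are kept in (z, y, x) order for volumes and (y, x) for single
images.  ``spacing`` is the per-axis physical voxel size in Ångström and is
metadata only: no operation in this package rescales by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Image", "as_array", "validate_field"]


def validate_field(data: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Validate a 2-D/3-D scalar field and return it as float64."""
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim not in (2, 3):
        raise ValueError(f"{name} must be 2-D or 3-D, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values (NaN/Inf)")
    return arr


@dataclass
class Image:
    """A 2-D image or 3-D volume with optional voxel spacing metadata."""

    data: np.ndarray
    spacing: tuple[float, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = validate_field(self.data)
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)
            if len(self.spacing) != self.data.ndim:
                raise ValueError(
                    f"spacing has {len(self.spacing)} entries for a "
                    f"{self.data.ndim}-D image"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim


def as_array(image) -> np.ndarray:
    """Accept an :class:`Image` or a bare array; return a validated float64 array."""
    if isinstance(image, Image):
        return image.data
    return validate_field(image)
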