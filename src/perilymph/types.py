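"""Core data containers shared across the pipeline.

Conventions
-----------
* Image axis order is ``(z, y, x)`` for stacks and ``(y, x)`` for planar
  images; ``spacing`` gives the physical size of one pixel (µm) along each
  axis in the same order.
* Pixel indices are 0-based; the physical coordinate of a pixel is
  ``index * spacing`` with the origin at the centre of the first pixel.
* Track coordinates are physical chamber coordinates in µm, column order
  ``(x, y[, z])``; the chamber y axis is the stimulus axis and is decoupled
  from image pixel-y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "VesselMask", "Track"]


def _check_spacing(spacing, ndim: int) -> tuple[float, ...]:
    spacing = tuple(float(s) for s in np.atleast_1d(spacing))
    if len(spacing) == 1 and ndim > 1:
        spacing = spacing * ndim
    if len(spacing) != ndim:
        raise ValueError(f"spacing has {len(spacing)} entries for a {ndim}-D grid")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive and finite, got {spacing}")
    return spacing


@dataclass
class ImageStack:
    """A 2-D or 3-D fluorescence intensity grid with physical pixel spacing.

    Parameters
    ----------
    data
        Intensity values (arbitrary units), axes ``(z, y, x)`` or ``(y, x)``.
    spacing
        µm per pixel along each axis, same order as ``data`` axes. A scalar
        is broadcast to all axes.
    channel
        Optional channel / stain name carried through for provenance.
    """

    data: np.ndarray
    spacing: tuple[float, ...]
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.number):
            raise ValueError("image pixels must be numeric")
        if self.data.ndim not in (2, 3):
            raise ValueError(f"image must be 2-D or 3-D, got ndim={self.data.ndim}")
        if self.data.size == 0:
            raise ValueError("image grid is empty")
        self.spacing = _check_spacing(self.spacing, self.data.ndim)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim


@dataclass
class VesselMask:
    """Binary lymphatic-vessel mask aligned to an :class:`ImageStack`."""

    data: np.ndarray
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"mask must be 2-D or 3-D, got ndim={self.data.ndim}")
        if self.data.size == 0:
            raise ValueError("mask grid is empty")
        self.spacing = _check_spacing(self.spacing, self.data.ndim)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_vessel_pixels(self) -> int:
        return int(self.data.sum())

    def check_aligned(self, image: ImageStack) -> None:
        if self.data.shape != image.data.shape:
            raise ValueError(
                f"mask shape {self.data.shape} does not match image shape {image.data.shape}"
            )


@dataclass
class Track:
    """Time-ordered positions of one migrating cell.

    ``positions`` holds physical coordinates in µm with columns ``(x, y)``
    or ``(x, y, z)``; ``t`` holds timestamps in seconds, strictly
    increasing. ``assay`` tags the source assay (``"chemotaxis3d"`` for the
    3-D collagen chamber, ``"crawling"`` for monolayer crawling).
    """

    track_id: str
    t: np.ndarray
    positions: np.ndarray
    assay: str = ""
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.t.ndim != 1 or self.positions.ndim != 2:
            raise ValueError("t must be 1-D and positions 2-D")
        if len(self.t) != len(self.positions):
            raise ValueError("t and positions lengths differ")
        if len(self.t) < 2:
            raise ValueError(f"track {self.track_id!r} has fewer than 2 points")
        if self.positions.shape[1] not in (2, 3):
            raise ValueError("positions must have 2 or 3 spatial columns")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError(f"track {self.track_id!r} timestamps not strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def is_3d(self) -> bool:
        return self.positions.shape[1] == 3
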