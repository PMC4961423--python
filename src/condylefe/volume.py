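"""Voxel volume container.

Axis convention (fixed package-wide):

* axis 0 (``x``): lateral -> medial
* axis 1 (``y``): palmar -> dorsal
* axis 2 (``z``): proximal -> distal

``data[i, j, k]`` is the value of the voxel whose *center* sits at
``origin + (i, j, k) * spacing``.  ``value_kind`` declares the physical
quantity stored: ``"density"`` (apparent density, g/cm^3), ``"hu"``
(Hounsfield units) or ``"mask"`` (binary occupancy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALUE_KINDS = ("density", "hu", "mask")


@dataclass
class VoxelVolume:
    """A 3D scalar raster with isotropic-or-not spacing and an origin.

    Parameters
    ----------
    data:
        3D float (or bool, for masks) array indexed ``[x, y, z]``.
    spacing:
        mm per axis, length-3, all positive.
    origin:
        mm coordinates of the center of voxel ``(0, 0, 0)``.
    value_kind:
        one of :data:`VALUE_KINDS`.
    meta:
        free-form provenance (phantom spec, seed, calibration, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: np.ndarray
    value_kind: str = "density"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in np.atleast_1d(self.spacing).repeat(
            3 if np.size(self.spacing) == 1 else 1)[:3])
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"value_kind {self.value_kind!r} not in {VALUE_KINDS}")
        if self.data.dtype.kind == "f" and not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (mm)."""
        n = self.data.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def center_grids(self):
        """Broadcastable (X, Y, Z) voxel-center coordinate arrays (mm)."""
        x = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        z = self.axis_centers(2)[None, None, :]
        return x, y, z

    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def copy(self, **overrides) -> "VoxelVolume":
        kw = dict(
            data=self.data.copy(),
            spacing=self.spacing,
            origin=self.origin.copy(),
            value_kind=self.value_kind,
            meta=dict(self.meta),
        )
        kw.update(overrides)
        return VoxelVolume(**kw)

    def require_kind(self, kind: str):
        if self.value_kind != kind:
            raise ValueError(
                f"expected a {kind!r}-valued volume, got {self.value_kind!r}")
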