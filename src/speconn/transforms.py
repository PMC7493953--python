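"""Spatial transforms shared by the scene generator and registration.

A transform maps *fixed-frame* physical positions (x, y, z) in pre-expansion
nm to moving-frame positions: resampling the moving image at ``T(x)`` aligns
it onto the fixed image.  The affine part acts about a center ``c``:
``T(p) = A (p - c) + c + t [+ D(p)]`` with an optional smooth displacement
field ``D`` stored on a coarse control grid and interpolated trilinearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .types import VoxelGrid

__all__ = ["DisplacementField", "SpatialTransform", "SinusoidalWarp",
           "resample_through", "invert_points"]


@dataclass
class DisplacementField:
    """Coarse grid of correction vectors (xyz nm components) over the volume.

    ``values`` has shape (3, gz, gy, gx); control point ``(k,j,i)`` sits at
    physical position ``origin + spacing * (i, j, k)`` (xyz nm).
    """

    values: np.ndarray
    spacing_nm: tuple[float, float, float]  # (x, y, z) control-point spacing
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.values.ndim != 4 or self.values.shape[0] != 3:
            raise ValueError("displacement values must have shape (3, gz, gy, gx)")

    @property
    def max_magnitude(self) -> float:
        return float(np.sqrt((self.values ** 2).sum(axis=0)).max())

    def sample(self, pts_xyz: np.ndarray) -> np.ndarray:
        """Interpolated displacement (n, 3) xyz nm at physical points."""
        pts = np.atleast_2d(pts_xyz)
        sx, sy, sz = self.spacing_nm
        ox, oy, oz = self.origin_nm
        coords = np.stack([
            (pts[:, 2] - oz) / sz,
            (pts[:, 1] - oy) / sy,
            (pts[:, 0] - ox) / sx,
        ])
        out = np.empty((len(pts), 3))
        for d in range(3):
            out[:, d] = map_coordinates(self.values[d], coords, order=1, mode="nearest")
        return out


@dataclass
class SpatialTransform:
    """Affine (+ optional free-form displacement) alignment transform."""

    linear: np.ndarray = field(default_factory=lambda: np.eye(3))  # xyz
    translation_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    displacement: Optional[DisplacementField] = None
    residual_nm: float = float("nan")

    def __post_init__(self):
        self.linear = np.asarray(self.linear, dtype=float)
        self.translation_nm = np.asarray(self.translation_nm, dtype=float)
        self.center_nm = np.asarray(self.center_nm, dtype=float)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("affine linear part is singular")

    def map_points(self, pts_xyz: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_xyz, dtype=float))
        out = (pts - self.center_nm) @ self.linear.T + self.center_nm + self.translation_nm
        if self.displacement is not None:
            out = out + self.displacement.sample(pts)
        return out

    def affine_only(self) -> "SpatialTransform":
        return SpatialTransform(self.linear.copy(), self.translation_nm.copy(),
                                self.center_nm.copy(), None, self.residual_nm)

    @property
    def axis_scales(self) -> np.ndarray:
        """Per-axis (x, y, z) scale factors: column norms of the linear part
        (image of each axis unit vector)."""
        return np.linalg.norm(self.linear, axis=0)

    def to_dict(self) -> dict:
        return {
            "linear": self.linear.tolist(),
            "translation_nm": self.translation_nm.tolist(),
            "center_nm": self.center_nm.tolist(),
            "residual_nm": self.residual_nm,
            "displacement": None if self.displacement is None else {
                "values": self.displacement.values.tolist(),
                "spacing_nm": list(self.displacement.spacing_nm),
                "origin_nm": list(self.displacement.origin_nm),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpatialTransform":
        disp = d.get("displacement")
        df = None
        if disp is not None:
            df = DisplacementField(np.asarray(disp["values"], dtype=float),
                                   tuple(disp["spacing_nm"]), tuple(disp["origin_nm"]))
        return cls(np.asarray(d["linear"], dtype=float),
                   np.asarray(d["translation_nm"], dtype=float),
                   np.asarray(d["center_nm"], dtype=float),
                   df, float(d.get("residual_nm", float("nan"))))


@dataclass
class SinusoidalWarp:
    """A planted round-to-round warp: affine plus a smooth sinusoidal
    displacement (the generator's stand-in for gel wobble)."""

    linear: np.ndarray
    translation_nm: np.ndarray
    center_nm: np.ndarray
    amplitude_nm: np.ndarray      # (3,) xyz amplitudes
    period_nm: np.ndarray         # (3,) xyz periods of the sinusoid
    phase: np.ndarray             # (3,)

    def map_points(self, pts_xyz: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_xyz, dtype=float))
        out = (pts - self.center_nm) @ np.asarray(self.linear).T \
            + self.center_nm + self.translation_nm
        # displacement along each axis driven by the orthogonal coordinates
        drive = np.roll(pts, 1, axis=1)
        out = out + self.amplitude_nm * np.sin(
            2 * np.pi * drive / self.period_nm + self.phase
        )
        return out


def invert_points(transform, pts_xyz: np.ndarray, iters: int = 40,
                  tol_nm: float = 0.01) -> np.ndarray:
    """Solve ``T(y) = p`` per point by fixed-point iteration (valid for
    warps close to the identity)."""
    pts = np.atleast_2d(np.asarray(pts_xyz, dtype=float))
    y = pts.copy()
    for _ in range(iters):
        err = transform.map_points(y) - pts
        y = y - err
        if np.abs(err).max() < tol_nm:
            break
    return y


def resample_through(grid: VoxelGrid, transform, order: int = 1,
                     channels: Optional[list[str]] = None) -> VoxelGrid:
    """Resample every channel at ``T(x)``: out(x) = in(T(x)); outside -> 0."""
    nz, ny, nx = grid.shape
    pz, py, px = grid.pitch_nm
    zz, yy, xx = np.meshgrid(
        np.arange(nz) * pz, np.arange(ny) * py, np.arange(nx) * px,
        indexing="ij", copy=False,
    )
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    mapped = transform.map_points(pts)
    coords = np.stack([
        mapped[:, 2] / pz, mapped[:, 1] / py, mapped[:, 0] / px,
    ]).astype(np.float32)
    del pts, mapped, zz, yy, xx
    names = channels if channels is not None else list(grid.channels)
    out = np.empty((len(names), nz, ny, nx), dtype=np.float32)
    for i, name in enumerate(names):
        out[i] = map_coordinates(
            grid.channel(name).astype(np.float32), coords, order=order,
            mode="constant", cval=0.0,
        ).reshape(nz, ny, nx)
    return VoxelGrid(channels=list(names), data=out, pitch_nm=grid.pitch_nm,
                     expansion_factor=grid.expansion_factor, round_id=grid.round_id)
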