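"""Coordinate conventions, rigid-body transforms and volume resampling.

Conventions used throughout the package:

* world frame: right-handed, axes aligned with the array axes, millimetres;
* 0-based voxel indices; the world coordinate of voxel ``(i, j, k)`` is
  ``origin + (i*dx, j*dy, k*dz)``;
* rigid transforms are parameterised by three translations (mm) and three
  extrinsic rotations (degrees) about the world axes through the volume
  centre, applied in x -> y -> z order, followed by the translation;
* resampling is pull (inverse-map) interpolation with zeros outside the
  field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse

__all__ = [
    "Grid3D",
    "RigidTransform",
    "GimbalLockError",
    "compose_rigid",
    "invert_rigid",
    "apply_rigid",
    "resampler_matrix",
    "write_transform_tsv",
    "read_transform_tsv",
]

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


class GimbalLockError(ValueError):
    """Raised when a rotation cannot be decomposed (|rot_y| = 90 degrees)."""


@dataclass(frozen=True)
class Grid3D:
    """Regular 3D sampling grid in world (mm) coordinates."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @classmethod
    def centered(
        cls,
        shape: tuple[int, int, int],
        voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    ) -> "Grid3D":
        """Grid whose world origin sits at the volume centre."""
        origin = tuple(
            -0.5 * (n - 1) * v for n, v in zip(shape, voxel_size)
        )
        return cls(shape, voxel_size, origin)

    @property
    def fov(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))

    @property
    def center(self) -> np.ndarray:
        """World coordinate of the volume centre (mm)."""
        return np.asarray(self.origin) + 0.5 * (np.asarray(self.shape) - 1) * np.asarray(
            self.voxel_size
        )

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (1D arrays, mm)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.voxel_size[a]
            for a in range(3)
        )

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world affine (NIfTI style)."""
        A = np.eye(4)
        A[:3, :3] = np.diag(self.voxel_size)
        A[:3, 3] = self.origin
        return A


def _axis_rotation(axis: int, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    R = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    R[i, i] = c
    R[j, j] = c
    if axis == 1:
        R[i, j] = s
        R[j, i] = -s
    else:
        R[i, j] = -s
        R[j, i] = s
    return R


@dataclass(frozen=True)
class RigidTransform:
    """6-parameter rigid-body pose: translations in mm, rotations in degrees.

    Rotations are extrinsic about the world x, y, z axes (in that order)
    through the rotation centre, followed by the translation.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], float)

    @property
    def rotation_deg(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz], float)

    @property
    def parameters(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz], float)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_parameters(cls, p) -> "RigidTransform":
        p = np.asarray(p, float)
        return cls(*p.tolist())

    def rotation_matrix(self) -> np.ndarray:
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        return _axis_rotation(2, rz) @ _axis_rotation(1, ry) @ _axis_rotation(0, rx)

    def matrix(self, center=(0.0, 0.0, 0.0)) -> np.ndarray:
        """Homogeneous 4x4 point map ``p -> R (p - c) + c + t``."""
        R = self.rotation_matrix()
        c = np.asarray(center, float)
        H = np.eye(4)
        H[:3, :3] = R
        H[:3, 3] = c + self.translation - R @ c
        return H

    @classmethod
    def from_matrix(cls, H, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        R = np.asarray(H, float)[:3, :3]
        c = np.asarray(center, float)
        # extrinsic x->y->z: R = Rz Ry Rx, so R[2,0] = -sin(ry)
        sy = -R[2, 0]
        if abs(sy) > 1 - 1e-9:
            raise GimbalLockError(
                "rotation decomposition degenerate: |rot_y| = 90 degrees"
            )
        ry = np.arcsin(np.clip(sy, -1.0, 1.0))
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
        t = np.asarray(H, float)[:3, 3] - c + R @ c
        return cls(*t.tolist(), *np.rad2deg([rx, ry, rz]).tolist())

    def apply_points(self, points, center=(0.0, 0.0, 0.0)) -> np.ndarray:
        """Map world points (N, 3) through the transform."""
        pts = np.atleast_2d(np.asarray(points, float))
        c = np.asarray(center, float)
        return (pts - c) @ self.rotation_matrix().T + c + self.translation

    def is_identity(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.parameters) <= tol))


def compose_rigid(
    a: RigidTransform, b: RigidTransform, center=(0.0, 0.0, 0.0)
) -> RigidTransform:
    """Composition ``a o b`` as point maps (apply ``b`` first, then ``a``)."""
    return RigidTransform.from_matrix(a.matrix(center) @ b.matrix(center), center)


def invert_rigid(t: RigidTransform, center=(0.0, 0.0, 0.0)) -> RigidTransform:
    H = t.matrix(center)
    Hi = np.eye(4)
    Hi[:3, :3] = H[:3, :3].T
    Hi[:3, 3] = -H[:3, :3].T @ H[:3, 3]
    return RigidTransform.from_matrix(Hi, center)


def _pull_coordinates(grid: Grid3D, transform: RigidTransform) -> np.ndarray:
    """Voxel coordinates at which the input must be sampled (pull map)."""
    H = transform.matrix(grid.center)
    Ri = H[:3, :3].T
    d = H[:3, 3]
    ax = grid.world_coordinates()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=0).reshape(3, -1)
    mapped = Ri @ (pts - d[:, None])
    vox = (mapped - np.asarray(grid.origin)[:, None]) / np.asarray(grid.voxel_size)[
        :, None
    ]
    return vox.reshape(3, *grid.shape)


def apply_rigid(
    vol: np.ndarray,
    transform: RigidTransform,
    grid: Grid3D | None = None,
    interp: str = "trilinear",
) -> np.ndarray:
    """Resample ``vol`` under a rigid transform (pull resampling).

    The returned volume is ``vol`` *moved by* ``transform``: output voxel at
    world position x takes the input value at ``T^{-1} x``. Out-of-field
    voxels are zero.
    """
    vol = np.asarray(vol)
    if not np.all(np.isfinite(vol if not np.iscomplexobj(vol) else vol.view(float))):
        raise ValueError("apply_rigid: input volume contains non-finite values")
    if grid is None:
        grid = Grid3D.centered(vol.shape)
    if tuple(vol.shape) != tuple(grid.shape):
        raise ValueError(f"volume shape {vol.shape} != grid shape {grid.shape}")
    if transform.is_identity():
        return vol.copy()
    order = {"trilinear": 1, "nearest": 0}[interp]
    coords = _pull_coordinates(grid, transform)
    if np.iscomplexobj(vol):
        re = ndimage.map_coordinates(vol.real, coords, order=order, cval=0.0)
        im = ndimage.map_coordinates(vol.imag, coords, order=order, cval=0.0)
        return re + 1j * im
    return ndimage.map_coordinates(vol, coords, order=order, cval=0.0)


def _catmull_rom_weight(t: np.ndarray) -> np.ndarray:
    """Keys cubic-convolution kernel (a = -1/2), support |t| < 2."""
    at = np.abs(t)
    w = np.zeros_like(at)
    near = at <= 1
    far = (at > 1) & (at < 2)
    w[near] = 1.5 * at[near] ** 3 - 2.5 * at[near] ** 2 + 1.0
    w[far] = -0.5 * at[far] ** 3 + 2.5 * at[far] ** 2 - 4.0 * at[far] + 2.0
    return w


def resampler_matrix(
    grid: Grid3D, transform: RigidTransform, interp: str = "trilinear"
) -> sparse.csr_matrix:
    """Sparse matrix form of rigid pull-resampling on flattened volumes.

    The exact adjoint of the resampling step is then the matrix transpose,
    which the reconstruction forward operator relies on.  ``interp`` is
    ``trilinear`` (matches :func:`apply_rigid`), ``nearest``, or ``cubic``
    (Catmull-Rom cubic convolution — an interpolating kernel that needs no
    prefilter, used by the reconstruction forward model where trilinear
    blur would leak into the data consistency).
    """
    n = int(np.prod(grid.shape))
    coords = _pull_coordinates(grid, transform).reshape(3, -1)
    shape = np.asarray(grid.shape)
    if interp == "cubic":
        inside = np.all(
            (coords >= 0) & (coords <= (shape - 1)[:, None]), axis=0
        )
        f = np.floor(coords).astype(np.int64)
        rows_all, cols_all, data_all = [], [], []
        for ox in range(-1, 3):
            wx = _catmull_rom_weight(coords[0] - (f[0] + ox))
            ix = np.clip(f[0] + ox, 0, shape[0] - 1)
            for oy in range(-1, 3):
                wy = _catmull_rom_weight(coords[1] - (f[1] + oy))
                iy = np.clip(f[1] + oy, 0, shape[1] - 1)
                wxy = wx * wy
                for oz in range(-1, 3):
                    wz = _catmull_rom_weight(coords[2] - (f[2] + oz))
                    iz = np.clip(f[2] + oz, 0, shape[2] - 1)
                    w = wxy * wz
                    valid = inside & (np.abs(w) > 1e-12)
                    rows_all.append(np.nonzero(valid)[0])
                    cols_all.append(
                        np.ravel_multi_index(
                            (ix[valid], iy[valid], iz[valid]), grid.shape
                        )
                    )
                    data_all.append(w[valid])
        M = sparse.coo_matrix(
            (
                np.concatenate(data_all),
                (np.concatenate(rows_all), np.concatenate(cols_all)),
            ),
            shape=(n, n),
        )
        return M.tocsr()
    if interp == "nearest":
        idx = np.rint(coords).astype(np.int64)
        valid = np.all((idx >= 0) & (idx < shape[:, None]), axis=0)
        rows = np.nonzero(valid)[0]
        cols = np.ravel_multi_index(tuple(idx[:, valid]), grid.shape)
        data = np.ones(rows.size)
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    f = np.floor(coords).astype(np.int64)
    w = coords - f
    # match map_coordinates(mode="constant"): any point mapping outside the
    # domain [0, N-1] takes the constant 0, with no partial interpolation
    inside = np.all((coords >= 0) & (coords <= (shape - 1)[:, None]), axis=0)
    rows_all, cols_all, data_all = [], [], []
    for corner in range(8):
        off = np.array([(corner >> a) & 1 for a in range(3)])[:, None]
        idx = f + off
        weight = np.prod(np.where(off == 1, w, 1.0 - w), axis=0)
        valid = (
            inside
            & np.all((idx >= 0) & (idx < shape[:, None]), axis=0)
            & (weight > 0)
        )
        rows_all.append(np.nonzero(valid)[0])
        cols_all.append(np.ravel_multi_index(tuple(idx[:, valid]), grid.shape))
        data_all.append(weight[valid])
    M = sparse.coo_matrix(
        (np.concatenate(data_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n, n),
    )
    return M.tocsr()


def write_transform_tsv(path, transforms) -> None:
    """Serialise a sequence of transforms as a 6-column TSV (mm, degrees)."""
    rows = [t.parameters for t in transforms]
    pd.DataFrame(rows, columns=list(MOTION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_transform_tsv(path) -> list[RigidTransform]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transform TSV missing columns {missing}")
    return [
        RigidTransform.from_parameters(row[list(MOTION_COLUMNS)].to_numpy(float))
        for _, row in df.iterrows()
    ]
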