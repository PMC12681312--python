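"""Navigator reconstruction and motion/field tracking.

Accelerated volumetric navigators are reconstructed with 2D-GRAPPA on the
ky-kz plane (kx fully sampled), rigid head pose is estimated from the
navigator magnitude by Gauss-Newton multiresolution registration, and the
global + spatially linear B0 change is estimated from the navigator phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import (
    Grid3D,
    RigidTransform,
    apply_rigid,
    invert_rigid,
)
from .sampling import SamplingPattern, caipi_mask

__all__ = [
    "FieldState",
    "GrappaKernel",
    "NavigatorFrame",
    "grappa_calibrate",
    "grappa_reconstruct",
    "combine_channels",
    "estimate_motion",
    "estimate_field_change",
    "FieldWrapWarning",
]


class FieldWrapWarning(UserWarning):
    """Navigator phase difference approaches +/- pi; field fit may be wrapped."""


@dataclass(frozen=True)
class FieldState:
    """Global and spatially linear field offset: g0 in Hz, gradients in Hz/mm."""

    g0: float = 0.0
    gx: float = 0.0
    gy: float = 0.0
    gz: float = 0.0

    @property
    def parameters(self) -> np.ndarray:
        return np.array([self.g0, self.gx, self.gy, self.gz], float)

    def is_zero(self) -> bool:
        return bool(np.all(self.parameters == 0))


@dataclass
class NavigatorFrame:
    """One reconstructed navigator volume (complex, channel-combined).

    ``rss`` optionally carries the root-sum-of-squares channel magnitude,
    which model-based registration prefers (its prediction is an RSS
    image); ``image`` is the phase-preserving weighted combination used by
    the field estimator.
    """

    image: np.ndarray
    grid: Grid3D
    frame_index: int = 0
    time_s: float = 0.0
    rss: np.ndarray | None = None

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.image)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.image)


# ---------------------------------------------------------------------------
# 2D-GRAPPA
# ---------------------------------------------------------------------------


@dataclass
class GrappaKernel:
    """GRAPPA weights, one set per missing (ky, kz) offset class.

    ``weights[cls]`` has shape (n_channels, n_channels * n_sources) mapping
    gathered source samples to the missing target in every channel;
    ``sources[cls]`` is the (n_sources, 3) table of (dkx, dky, dkz) offsets
    of the acquired source points relative to the missing target.
    """

    accel: tuple[int, int]
    caipi_shift: int
    kernel_size: tuple[int, int, int]
    weights: dict
    sources: dict
    fit_residual: float = 0.0
    _plans: dict = field(default_factory=dict, repr=False)

    @property
    def n_channels(self) -> int:
        for w in self.weights.values():
            return w.shape[0]
        return 0

    def fill_plan(self, shape: tuple[int, int, int]) -> list:
        """Cached gather/scatter index plan for k-spaces of this shape."""
        key = tuple(shape)
        if key not in self._plans:
            self._plans[key] = _build_fill_plan(self, shape)
        return self._plans[key]


def _lattice_source_offsets(dy, dz, Ry, Rz, caipi_shift, n_ky, n_kz):
    """Acquired-lattice (dky, dkz) offsets surrounding a missing offset.

    The acquired (ky, kz) set is the lattice generated by (Ry, 0) and
    (caipi_shift, Rz).  Sources are the n_ky x n_kz lattice points nearest
    the missing point in lattice coordinates.
    """
    beta = dz / Rz
    alpha = (dy - caipi_shift * beta) / Ry
    a0 = int(np.floor(alpha)) - (n_ky - 2) // 2
    b0 = int(np.floor(beta)) - (n_kz - 2) // 2
    offs = []
    for b in range(b0, b0 + n_kz):
        for a in range(a0, a0 + n_ky):
            offs.append((a * Ry + b * caipi_shift - dy, b * Rz - dz))
    return offs


def _source_table(accel, caipi_shift, kernel_size):
    """(dkx, dky, dkz) source offsets for every missing (dy, dz) class."""
    Ry, Rz = accel
    kx_half = (kernel_size[0] - 1) // 2
    dkx = np.arange(-kx_half, kernel_size[0] - kx_half)
    tables = {}
    for dz in range(Rz):
        for dy in range(Ry):
            if dz % Rz == 0 and dy % Ry == (caipi_shift * (dz // Rz)) % Ry:
                continue  # acquired class
            offs = _lattice_source_offsets(
                dy, dz, Ry, Rz, caipi_shift, kernel_size[1], kernel_size[2]
            )
            src = np.array(
                [(int(x), int(oy), int(oz)) for oy, oz in offs for x in dkx],
                dtype=np.int64,
            )
            tables[(dy, dz)] = src
    return tables


def grappa_calibrate(
    acs: np.ndarray,
    accel: tuple[int, int],
    caipi_shift: int = 1,
    kernel_size: tuple[int, int, int] = (5, 2, 2),
    tikhonov: float = 1e-4,
    min_equation_ratio: float = 4.0,
) -> GrappaKernel:
    """Fit GRAPPA weights from a fully sampled ACS block.

    Parameters
    ----------
    acs : complex array (n_channels, nx, ny, nz)
        Fully sampled autocalibration k-space.
    tikhonov : float
        Relative Tikhonov factor; the solve is regularised by
        ``tikhonov * trace(S^H S) / n_unknowns``.
    """
    acs = np.asarray(acs)
    if acs.ndim != 4:
        raise ValueError("ACS must be (channels, nx, ny, nz)")
    nc, nx, ny, nz = acs.shape
    Ry, Rz = accel
    if Ry * Rz == 1:
        return GrappaKernel(accel, caipi_shift, kernel_size, {}, {}, 0.0)
    tables = _source_table(accel, caipi_shift, kernel_size)
    weights, sources = {}, {}
    sse = 0.0
    sst = 0.0
    for cls, src in tables.items():
        lo = np.maximum(0, -src.min(axis=0))
        hi = np.array([nx, ny, nz]) - np.maximum(0, src.max(axis=0))
        if np.any(hi - lo < 1):
            raise ValueError(
                f"ACS of shape {(nx, ny, nz)} too small for kernel sources "
                f"of class {cls}"
            )
        tx = np.arange(lo[0], hi[0])
        ty = np.arange(lo[1], hi[1])
        tz = np.arange(lo[2], hi[2])
        TX, TY, TZ = np.meshgrid(tx, ty, tz, indexing="ij")
        tpos = np.stack([TX.ravel(), TY.ravel(), TZ.ravel()], axis=1)
        n_pos = tpos.shape[0]
        n_unknown = nc * src.shape[0]
        if n_pos < min_equation_ratio * n_unknown:
            raise ValueError(
                f"underdetermined GRAPPA fit for class {cls}: "
                f"{n_pos} equations for {n_unknown} unknowns "
                f"(need >= {min_equation_ratio}x)"
            )
        # S: (n_pos, nc * n_src); T: (n_pos, nc)
        spos = tpos[:, None, :] + src[None, :, :]
        S = acs[:, spos[..., 0], spos[..., 1], spos[..., 2]]
        S = np.moveaxis(S, 0, 1).reshape(n_pos, nc * src.shape[0])
        T = acs[:, tpos[:, 0], tpos[:, 1], tpos[:, 2]].T
        G = S.conj().T @ S
        lam = tikhonov * np.trace(G).real / max(G.shape[0], 1)
        W = np.linalg.solve(G + lam * np.eye(G.shape[0]), S.conj().T @ T)
        resid = S @ W - T
        sse += float(np.sum(np.abs(resid) ** 2))
        sst += float(np.sum(np.abs(T) ** 2))
        weights[cls] = W.T  # (nc_target, nc*n_src)
        sources[cls] = src
    fit_residual = np.sqrt(sse / sst) if sst > 0 else 0.0
    return GrappaKernel(accel, caipi_shift, kernel_size, weights, sources, fit_residual)


def _build_fill_plan(kernel: GrappaKernel, shape) -> list:
    """Flat gather indices per missing-offset class for one k-space shape.

    The lattice class of a position is dz = kz mod Rz and, accounting for
    the CAIPI shear, dy = (ky - shift * (kz div Rz)) mod Ry.
    """
    nx, ny, nz = shape
    Ry, Rz = kernel.accel
    shift = kernel.caipi_shift
    plan = []
    bounds = np.array([nx, ny, nz])
    for cls, src in kernel.sources.items():
        dy, dz = cls
        ky_list, kz_list = [], []
        for kz in range(dz, nz, Rz):
            residue = (dy + shift * (kz // Rz)) % Ry
            ky = np.arange(residue, ny, Ry)
            ky_list.append(ky)
            kz_list.append(np.full(ky.size, kz))
        ky_all = np.concatenate(ky_list)
        kz_all = np.concatenate(kz_list)
        KX, KY = np.meshgrid(np.arange(nx), ky_all, indexing="ij")
        KZ = np.broadcast_to(kz_all[None, :], KY.shape)
        tpos = np.stack([KX.ravel(), KY.ravel(), KZ.ravel()], axis=1)
        spos = tpos[:, None, :] + src[None, :, :]
        valid = np.all((spos >= 0) & (spos < bounds), axis=2)  # zero-pad edges
        spos_c = np.clip(spos, 0, bounds - 1)
        tflat = np.ravel_multi_index(tuple(tpos.T), shape)
        sflat = np.ravel_multi_index(
            (spos_c[..., 0], spos_c[..., 1], spos_c[..., 2]), shape
        )
        plan.append((cls, tflat, sflat, valid.astype(np.float64)))
    return plan


def grappa_fill(kspace: np.ndarray, kernel: GrappaKernel) -> np.ndarray:
    """Synthesise missing (ky, kz) lines; acquired samples are untouched."""
    ks = np.array(kspace, copy=True)
    nc, nx, ny, nz = ks.shape
    Ry, Rz = kernel.accel
    if Ry * Rz == 1:
        return ks
    acq = caipi_mask(ny, nz, Ry, Rz, kernel.caipi_shift)
    flat = ks.reshape(nc, -1)
    out = flat.copy()
    for cls, tflat, sflat, valid in kernel.fill_plan((nx, ny, nz)):
        S = flat[:, sflat] * valid[None]  # (nc, n_pos, n_src)
        S = np.moveaxis(S, 0, 1).reshape(tflat.size, -1)
        vals = S @ kernel.weights[cls].T  # (n_pos, nc)
        out[:, tflat] = vals.T
    ks = out.reshape(nc, nx, ny, nz)
    # restore acquired samples verbatim
    ks[:, :, acq] = np.asarray(kspace)[:, :, acq]
    return ks


def _centered_ifft3(ks: np.ndarray) -> np.ndarray:
    axes = (-3, -2, -1)
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(ks, axes=axes), axes=axes), axes=axes
    )


def compute_combination_weights(
    channel_images: np.ndarray, smooth_vox: float = 2.0
) -> np.ndarray:
    """Phase-preserving channel-combination weights from reference images.

    Smoothed channel images normalised by their root-sum-of-squares serve as
    sensitivity estimates; combining every frame with weights computed from
    the *reference* frame preserves inter-frame phase differences for the
    field estimator.
    """
    sm = np.empty_like(channel_images)
    for c in range(channel_images.shape[0]):
        sm[c] = ndimage.gaussian_filter(
            channel_images[c].real, smooth_vox
        ) + 1j * ndimage.gaussian_filter(channel_images[c].imag, smooth_vox)
    rss = np.sqrt(np.sum(np.abs(sm) ** 2, axis=0))
    rss = np.where(rss > 0, rss, 1.0)
    return sm / rss


def combine_channels(
    channel_images: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Weighted complex channel combination (conjugate-sensitivity sum)."""
    if weights is None:
        weights = compute_combination_weights(channel_images)
    return np.sum(np.conj(weights) * channel_images, axis=0)


def grappa_reconstruct(
    kspace: np.ndarray,
    kernel: GrappaKernel,
    grid: Grid3D | None = None,
    weights: np.ndarray | None = None,
    frame_index: int = 0,
    time_s: float = 0.0,
) -> NavigatorFrame:
    """GRAPPA-fill missing lines, inverse FFT and combine channels.

    ``kspace`` is a zero-filled (n_channels, nx, ny, nz) array with DC at
    ``floor(N/2)`` on every axis.
    """
    filled = grappa_fill(kspace, kernel)
    imgs = _centered_ifft3(filled)
    combined = combine_channels(imgs, weights)
    rss = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
    if grid is None:
        grid = Grid3D.centered(combined.shape)
    return NavigatorFrame(combined, grid, frame_index, time_s, rss=rss)


# ---------------------------------------------------------------------------
# Rigid motion estimation
# ---------------------------------------------------------------------------


def _downsample2(vol: np.ndarray, grid: Grid3D) -> tuple[np.ndarray, Grid3D]:
    """Average 2x2x2 blocks (trailing odd samples dropped)."""
    nx, ny, nz = (s // 2 for s in vol.shape)
    if min(nx, ny, nz) < 4:
        return vol, grid
    v = vol[: 2 * nx, : 2 * ny, : 2 * nz]
    v = v.reshape(nx, 2, ny, 2, nz, 2).mean(axis=(1, 3, 5))
    g = Grid3D(
        (nx, ny, nz),
        tuple(2 * s for s in grid.voxel_size),
        tuple(o + 0.5 * s for o, s in zip(grid.origin, grid.voxel_size)),
    )
    return v, g


def _rotation_derivatives(rx_deg, ry_deg, rz_deg):
    """d(R^{-1})/d(angle) for R = Rz Ry Rx, per angle in radians."""
    rx, ry, rz = np.deg2rad([rx_deg, ry_deg, rz_deg])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    dRx = np.array([[0, 0, 0], [0, -sx, -cx], [0, cx, -sx]])
    dRy = np.array([[-sy, 0, cy], [0, 0, 0], [-cy, 0, -sy]])
    dRz = np.array([[-sz, -cz, 0], [cz, -sz, 0], [0, 0, 0]])
    # R^{-1} = Rx^T Ry^T Rz^T
    dinv = [
        dRx.T @ Ry.T @ Rz.T,
        Rx.T @ dRy.T @ Rz.T,
        Rx.T @ Ry.T @ dRz.T,
    ]
    return dinv


def _warp_and_jacobian(ref, grid, params):
    """Warped reference apply_rigid(ref, p) and its 6-column Jacobian.

    Derivatives are with respect to (tx, ty, tz [mm], rx, ry, rz [deg]).
    """
    t = RigidTransform.from_parameters(params)
    R = t.rotation_matrix()
    Ri = R.T
    c = grid.center
    d = c + t.translation
    ax = grid.world_coordinates()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=0).reshape(3, -1)
    rel = pts - d[:, None]
    mapped = Ri @ rel + c[:, None]
    vox = (mapped - np.asarray(grid.origin)[:, None]) / np.asarray(grid.voxel_size)[
        :, None
    ]
    warped = ndimage.map_coordinates(
        ref, vox.reshape(3, *grid.shape), order=1, cval=0.0
    ).ravel()
    inside = np.all(
        (vox >= 0) & (vox <= (np.asarray(grid.shape) - 1)[:, None]), axis=0
    ).reshape(grid.shape)
    # image gradient of ref in world units (per mm), sampled at mapped points
    grads = np.gradient(ref, *grid.voxel_size)
    gmap = np.stack(
        [
            ndimage.map_coordinates(g, vox.reshape(3, *grid.shape), order=1, cval=0.0)
            for g in grads
        ],
        axis=0,
    ).reshape(3, -1)
    J = np.empty((pts.shape[1], 6))
    # translations: dy/dt_j = -Ri e_j
    for j in range(3):
        J[:, j] = -(Ri[:, j][:, None] * gmap).sum(axis=0)
    dinvs = _rotation_derivatives(*params[3:])
    deg = np.pi / 180.0
    for j, dinv in enumerate(dinvs):
        dmap = dinv @ rel * deg
        J[:, 3 + j] = (dmap * gmap).sum(axis=0)
    return warped, J, inside.ravel()


def _estimate_motion_modelbased(
    frame_mag: np.ndarray,
    nav_grid: Grid3D,
    ref_hi: np.ndarray,
    coils_hi: np.ndarray,
    grid_hi: Grid3D,
    max_iter: int = 25,
    tol: float = 1e-4,
    init: RigidTransform | None = None,
    kernel: "GrappaKernel | None" = None,
    sampled_mask: np.ndarray | None = None,
) -> tuple[RigidTransform, bool]:
    """Registration against an acquisition-consistent navigator prediction.

    The navigator is an anisotropically band-limited view of the head, so
    warping the *navigator-resolution* reference cannot reproduce a rotated
    frame exactly (rotation does not commute with the truncation to the
    navigator k-box).  When a high-resolution reference volume is available
    — the protocol's fully sampled reference scan — the model instead warps
    that volume, applies the receive sensitivities and truncates to the
    navigator band, so the prediction carries exactly the band-limitation
    the measured frame does.  If the GRAPPA kernel and undersampling mask
    are supplied, the prediction is additionally undersampled and
    GRAPPA-filled, so the pose-dependent residual aliasing of the
    accelerated navigator appears in the model as well and cancels in the
    fit.  Gauss-Newton on the root-sum-of-squares magnitude with a
    finite-difference Jacobian.
    """
    nav_shape = tuple(nav_grid.shape)
    ax = grid_hi.world_coordinates()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=0).reshape(3, -1)
    vs = np.asarray(grid_hi.voxel_size)
    org = np.asarray(grid_hi.origin)
    c = grid_hi.center
    axes = (-3, -2, -1)
    # cubic-spline warp of the high-res reference: at imaging resolution the
    # spline interpolant is accurate enough that the prediction's rotation
    # behaviour matches a continuously moving object
    ref_coeff = ndimage.spline_filter(np.asarray(ref_hi, float), order=3)

    def model(p: np.ndarray) -> np.ndarray:
        t = RigidTransform.from_parameters(p)
        Ri = t.rotation_matrix().T
        d = c + t.translation
        vox = (Ri @ (pts - d[:, None]) + c[:, None] - org[:, None]) / vs[:, None]
        w = ndimage.map_coordinates(
            ref_coeff, vox.reshape(3, *grid_hi.shape), order=3,
            prefilter=False, cval=0.0,
        )
        k = np.fft.fftshift(
            np.fft.fftn(np.fft.ifftshift(w[None] * coils_hi, axes=axes), axes=axes),
            axes=axes,
        )
        sl = tuple(
            slice(n // 2 - m // 2, n // 2 - m // 2 + m)
            for n, m in zip(k.shape[-3:], nav_shape)
        )
        k = k[(..., *sl)]
        if kernel is not None and sampled_mask is not None:
            k = grappa_fill(k * sampled_mask[None, None, :, :], kernel)
        imgs = _centered_ifft3(k)
        return np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0)).ravel()

    fv = frame_mag.ravel()
    scale = float(np.max(fv)) or 1.0
    fv = fv / scale
    p = np.zeros(6) if init is None else init.parameters.copy()
    eps = 1e-3

    def jacobian(p0, m0):
        J = np.empty((m0.size, 6))
        for j in range(6):
            q = p0.copy()
            q[j] += eps
            J[:, j] = (model(q) / scale - m0) / eps
        return J

    # Gauss-Newton with a chord (frozen) Jacobian once the iteration starts
    # contracting: the model is expensive, and near the optimum the
    # sensitivity changes little.  Early iterations (far from the optimum,
    # e.g. without a warm start) recompute the Jacobian after every accepted
    # step; later ones reuse it and recompute only on a rejected step.
    m0 = model(p) / scale
    r = m0 - fv
    sse = float(r @ r)
    J = jacobian(p, m0)
    lm = 0.0
    converged = False
    recomputes = 0
    fresh_every_step = 3  # accepted steps that refresh J unconditionally
    accepted = 0
    for _ in range(max_iter):
        H = J.T @ J
        delta = np.linalg.solve(H + lm * np.diag(np.diag(H)), -(J.T @ r))
        p_new = p + delta
        m_new = model(p_new) / scale
        r_new = m_new - fv
        sse_new = float(r_new @ r_new)
        if sse_new <= sse * (1 + 1e-12):
            p, m0, r, sse = p_new, m_new, r_new, sse_new
            lm = lm / 10 if lm > 1e-12 else 0.0
            accepted += 1
            if np.linalg.norm(delta) < tol:
                converged = True
                break
            if accepted <= fresh_every_step:
                J = jacobian(p, m0)
        elif recomputes < 6:
            J = jacobian(p, m0)
            recomputes += 1
            lm = max(lm, 1e-6)
        else:
            lm = max(lm * 10, 1e-6)
            if lm > 1e6:
                break
    return RigidTransform.from_parameters(p), converged


def estimate_motion(
    frame,
    reference,
    grid: Grid3D | None = None,
    pyramid_levels: int = 2,
    max_iter: int = 50,
    tol: float = 1e-4,
    init: RigidTransform | None = None,
    reference_model: tuple | None = None,
) -> RigidTransform:
    """Rigid pose of ``frame`` relative to ``reference``.

    Gauss-Newton minimisation of the masked sum of squared differences
    between the warped reference magnitude and the frame magnitude, run
    coarse-to-fine on a downsample-by-2 pyramid.  The returned transform T
    satisfies ``frame ~= apply_rigid(reference, T)``.

    ``reference_model`` — optional ``(ref_hi, coils_hi, grid_hi)`` tuple
    with a high-resolution reference volume (e.g. from the fully sampled
    reference scan) and the receive maps: registration then compares the
    frame against band-limit-consistent navigator predictions instead of
    warping the low-resolution reference, which removes the rotation bias
    of the anisotropic navigator band (see
    :func:`_estimate_motion_modelbased`).
    """
    fmag = frame.magnitude if isinstance(frame, NavigatorFrame) else np.abs(frame)
    rmag = (
        reference.magnitude
        if isinstance(reference, NavigatorFrame)
        else np.abs(reference)
    )
    if grid is None:
        grid = (
            frame.grid
            if isinstance(frame, NavigatorFrame)
            else Grid3D.centered(fmag.shape)
        )
    if fmag.shape != rmag.shape:
        raise ValueError("frame and reference must share a grid")
    if reference_model is not None:
        ref_hi, coils_hi, grid_hi, *rest = reference_model
        kernel, sampled_mask = rest if rest else (None, None)
        if isinstance(frame, NavigatorFrame) and frame.rss is not None:
            fmag = frame.rss  # the model predicts the RSS magnitude
        result, ok = _estimate_motion_modelbased(
            fmag, grid, ref_hi, coils_hi, grid_hi,
            max_iter=max_iter, tol=tol, init=init,
            kernel=kernel, sampled_mask=sampled_mask,
        )
        if not ok:
            warnings.warn(
                "model-based motion estimation did not converge", RuntimeWarning
            )
        return result
    levels = [(rmag.astype(float), fmag.astype(float), grid)]
    for _ in range(pyramid_levels - 1):
        r, g = _downsample2(levels[-1][0], levels[-1][2])
        f, _ = _downsample2(levels[-1][1], levels[-1][2])
        if r.shape == levels[-1][0].shape:
            break
        levels.append((r, f, g))
    params = (init.parameters if init is not None else np.zeros(6)).copy()
    converged = False
    for ref_l, frm_l, grid_l in reversed(levels):
        fvec = frm_l.ravel()
        scale = np.max(np.abs(fvec)) or 1.0
        fvec = fvec / scale
        ref_s = ref_l / scale
        lm = 0.0

        def sse_at(p):
            warped, J, inside = _warp_and_jacobian(ref_s, grid_l, p)
            r = (warped - fvec) * inside
            return float(r @ r), r, J * inside[:, None]

        sse, r, Jm = sse_at(params)
        for _ in range(max_iter):
            H = Jm.T @ Jm
            g = Jm.T @ r
            try:
                delta = np.linalg.solve(H + lm * np.diag(np.diag(H)), -g)
            except np.linalg.LinAlgError:
                delta = -np.linalg.lstsq(H, g, rcond=None)[0]
            cand = params + delta
            sse_new, r_new, J_new = sse_at(cand)
            if sse_new <= sse * (1 + 1e-12):  # accept
                params, sse, r, Jm = cand, sse_new, r_new, J_new
                lm = lm / 10 if lm > 1e-12 else 0.0
                if np.linalg.norm(delta) < tol:
                    converged = True
                    break
            else:  # reject, damp harder
                lm = max(lm * 10, 1e-6)
                if lm > 1e8:
                    break
    result = RigidTransform.from_parameters(params)
    if not converged:
        warnings.warn(
            f"motion estimation did not converge (last update norm "
            f"{np.linalg.norm(delta):.2e})",
            RuntimeWarning,
        )
    return result


# ---------------------------------------------------------------------------
# Field-change estimation
# ---------------------------------------------------------------------------


def estimate_field_change(
    frame,
    reference,
    mask: np.ndarray,
    nav_te: float,
    motion: RigidTransform | None = None,
    grid: Grid3D | None = None,
) -> FieldState:
    """Global + linear field change from the navigator phase difference.

    The frame is first motion-compensated with the supplied rigid estimate,
    then ``dphi = arg(frame * conj(reference))`` is fit against [1, x, y, z]
    (world mm) by weighted least squares with magnitude-squared weights.
    Output units: g0 in Hz, gradients in Hz/mm.
    """
    if nav_te <= 0:
        raise ValueError("nav_te must be positive")
    fimg = frame.image if isinstance(frame, NavigatorFrame) else np.asarray(frame)
    rimg = (
        reference.image
        if isinstance(reference, NavigatorFrame)
        else np.asarray(reference)
    )
    if grid is None:
        grid = (
            frame.grid
            if isinstance(frame, NavigatorFrame)
            else Grid3D.centered(fimg.shape)
        )
    if motion is not None and not motion.is_identity():
        fimg = apply_rigid(fimg, invert_rigid(motion, grid.center), grid)
    diff = fimg * np.conj(rimg)
    m = np.asarray(mask, bool) & (np.abs(diff) > 0)
    if not np.any(m):
        raise ValueError("empty mask in field estimation")
    dphi = np.angle(diff[m])
    frac_wrapped = float(np.mean(np.abs(dphi) > 0.9 * np.pi))
    if frac_wrapped > 0.05:
        warnings.warn(
            f"{100 * frac_wrapped:.1f}% of masked voxels near phase wrap; "
            "field estimate may be aliased",
            FieldWrapWarning,
        )
    w = np.abs(diff[m])  # magnitude product; weights = |.|^2 in the fit
    ax = grid.world_coordinates()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    A = np.column_stack(
        [np.ones(m.sum()), X[m], Y[m], Z[m]]
    )
    f = dphi / (2 * np.pi * nav_te)
    Aw = A * w[:, None]
    coef, *_ = np.linalg.lstsq(Aw, f * w, rcond=None)
    return FieldState(*coef.tolist())
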