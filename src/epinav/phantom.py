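"""Synthetic fixtures: brain-like phantom, coil and transmit maps, motion
and field trajectories, and BOLD-like dynamics.

Everything here is procedural and a pure function of its specification and
seed, so any downstream module can be exercised without data downloads.
The phantom is defined in *world* (mm) coordinates, which makes it
resolution-independent: evaluating the same seeded specification on the
imaging grid and on a coarser navigator grid yields consistent objects.

These are algorithm-validation fixtures, not physics: coil and transmit
profiles are smooth low-order fields rather than Biot-Savart solutions,
and no physiological noise, relaxation or spin-history effects are
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import Grid3D, RigidTransform
from .recon import TimeSeries4D

__all__ = [
    "PhantomSpec",
    "CoilProfileSet",
    "B1MapSet",
    "MotionTrace",
    "FieldTrace",
    "make_phantom",
    "make_coil_sensitivities",
    "make_b1_transmit_maps",
    "make_motion_trace",
    "make_field_trace",
    "make_parcel_params",
    "parcel_masks",
    "simulate_bold_series",
    "default_test_grid",
]


def default_test_grid() -> Grid3D:
    """Default desk-scale imaging grid: 48 x 44 x 36 voxels at 4 mm."""
    return Grid3D.centered((48, 44, 36), (4.0, 4.0, 4.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Procedural head-phantom specification.

    ``edge_mm`` is the width of the smooth transition at compartment
    boundaries, emulating the partial-volume and relaxation blur of a real
    acquisition; a hard-edged (infinite-bandwidth) object would ring far
    more at navigator resolution than any in-vivo image does.
    """

    grid: Grid3D
    n_tissues: int = 3
    seed: int = 0
    edge_mm: float = 6.0


@dataclass
class CoilProfileSet:
    """Complex receive-sensitivity map per channel: (n_channels,) + shape."""

    maps: np.ndarray

    @property
    def n_channels(self) -> int:
        return int(self.maps.shape[0])

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass
class B1MapSet:
    """Complex transmit (B1+) profile per channel, normalised drive units."""

    maps: np.ndarray

    @property
    def n_tx(self) -> int:
        return int(self.maps.shape[0])

    def cp_weights(self) -> np.ndarray:
        """Circularly-polarised drive: unit amplitudes, 2*pi/n phase steps."""
        n = self.n_tx
        return np.exp(2j * np.pi * np.arange(n) / n) / np.sqrt(n)

    def cp_map(self) -> np.ndarray:
        """Net transmit field of the CP drive."""
        w = self.cp_weights()
        return np.tensordot(w, self.maps, axes=(0, 0))


@dataclass
class MotionTrace:
    """Rigid pose per navigator frame; frame 0 is the identity reference."""

    frames: list
    frame_interval: float

    def __len__(self) -> int:
        return len(self.frames)

    def parameters(self) -> np.ndarray:
        return np.stack([t.parameters for t in self.frames])


@dataclass
class FieldTrace:
    """Global (Hz) and linear (Hz/mm) field offset per navigator frame."""

    g0: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    frame_interval: float = 0.0

    def __len__(self) -> int:
        return len(self.g0)

    def state_arrays(self) -> np.ndarray:
        return np.stack([self.g0, self.gx, self.gy, self.gz], axis=1)


def _normalized_coords(grid: Grid3D) -> tuple[np.ndarray, ...]:
    """World coordinates scaled by the half-FOV, so the object fills [-1, 1]."""
    ax = grid.world_coordinates()
    c = grid.center
    half = np.maximum(np.asarray(grid.fov) / 2.0, 1e-9)
    return tuple(
        (a - c[i]) / half[i] for i, a in enumerate(ax)
    )


def make_phantom(
    spec: PhantomSpec, pose: RigidTransform | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoidal head phantom with nested perturbed tissue compartments.

    Returns (image, mask): intensities in [0, 1], mask = object support.
    Deterministic per (grid FOV, n_tissues, seed); the same spec evaluated
    on a coarser grid over the same FOV gives the same object.

    ``pose`` evaluates the phantom *moved by* the given rigid transform
    analytically (the ellipsoids themselves are transformed), which avoids
    the interpolation blur of resampling a gridded image and so emulates a
    genuinely moving object.
    """
    if any(n < 16 for n in spec.grid.shape):
        raise ValueError("phantom grid must be at least 16 voxels per axis")
    if spec.n_tissues < 1:
        raise ValueError("need at least one tissue")
    rng = np.random.default_rng(spec.seed)
    if pose is not None and not pose.is_identity():
        from .geometry import invert_rigid

        ax = spec.grid.world_coordinates()
        Xw, Yw, Zw = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([Xw.ravel(), Yw.ravel(), Zw.ravel()], axis=1)
        mapped = invert_rigid(pose, spec.grid.center).apply_points(
            pts, spec.grid.center
        )
        c = spec.grid.center
        half = np.maximum(np.asarray(spec.grid.fov) / 2.0, 1e-9)
        X = ((mapped[:, 0] - c[0]) / half[0]).reshape(spec.grid.shape)
        Y = ((mapped[:, 1] - c[1]) / half[1]).reshape(spec.grid.shape)
        Z = ((mapped[:, 2] - c[2]) / half[2]).reshape(spec.grid.shape)
    else:
        xs, ys, zs = _normalized_coords(spec.grid)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    half = np.asarray(spec.grid.fov) / 2.0

    def soft_ellipsoid(center, axes):
        """Soft membership of an ellipsoid with an edge_mm transition."""
        q = np.sqrt(
            ((X - center[0]) / axes[0]) ** 2
            + ((Y - center[1]) / axes[1]) ** 2
            + ((Z - center[2]) / axes[2]) ** 2
        )
        r_eff = float(3.0 / np.sum(1.0 / (np.asarray(axes) * half)))  # mm
        if spec.edge_mm <= 0:
            return (q <= 1.0).astype(float)
        d_mm = (1.0 - q) * r_eff
        return 0.5 * (1.0 + np.tanh(2.0 * d_mm / spec.edge_mm))

    # outer head: slightly perturbed ellipsoid at 85% of the half-FOV
    semi = 0.85 * (1.0 + 0.05 * rng.uniform(-1, 1, size=3))
    w_head = soft_ellipsoid((0.0, 0.0, 0.0), semi)
    img = 0.35 * w_head
    levels = np.linspace(0.55, 1.0, spec.n_tissues)
    if spec.n_tissues == 1:
        img = levels[0] * w_head
        # keep the rng stream identical across n_tissues settings
        rng.uniform(-1, 1, size=3)
        rng.uniform(-1, 1, size=3)
    else:
        # compartments are deliberately eccentric and anisotropic: a head's
        # internal anatomy is far from rotationally symmetric, and that
        # asymmetry is what makes rotations observable at coarse resolution
        for t in range(spec.n_tissues):
            shrink = 0.72 * (1.0 - 0.55 * t / max(spec.n_tissues, 1))
            center = 0.28 * rng.uniform(-1, 1, size=3)
            axes = shrink * semi * (1.0 + 0.3 * rng.uniform(-1, 1, size=3))
            w = soft_ellipsoid(center, axes) * w_head
            img = img + (levels[t] - img) * w
    mask = w_head > 0.5
    return img, mask


def make_coil_sensitivities(
    grid: Grid3D, n_channels: int, seed: int = 0, flat: bool = False
) -> CoilProfileSet:
    """Smooth complex receive profiles (Gaussian lobes on a ring + phase).

    Channel centres sit on an ellipse around the head with broad Gaussian
    falloff and channel-specific smooth phase, emulating (loosely) a
    close-fitting receive array.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    if flat:
        maps = np.ones((n_channels,) + tuple(grid.shape), np.complex128)
        return CoilProfileSet(maps)
    rng = np.random.default_rng(seed)
    xs, ys, zs = _normalized_coords(grid)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    maps = np.empty((n_channels,) + tuple(grid.shape), np.complex128)
    # helmet layout: elements tiled evenly over the head surface in rings,
    # as close-fitting receive arrays are built; localized magnitude lobes
    # plus channel-specific linear and quadratic phase give the spatial
    # encoding diversity a real array provides (without it, 12-fold
    # undersampling is not invertible with 16 channels)
    n_rings = max(1, int(np.round(np.sqrt(n_channels / 2))))
    ring_of = np.array_split(np.arange(n_channels), n_rings)
    for ring_i, members in enumerate(ring_of):
        zc = -0.7 + 1.4 * (ring_i + 0.5) / n_rings
        for j, c in enumerate(members):
            phi = (
                2 * np.pi * j / max(len(members), 1)
                + np.pi * ring_i / n_rings
                + rng.uniform(-0.1, 0.1)
            )
            cx, cy = 1.2 * np.cos(phi), 1.2 * np.sin(phi)
            d2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - zc) ** 2
            mag = np.exp(-d2 / (2 * 0.8**2))
            ph = (
                rng.uniform(-np.pi, np.pi)
                + 3.0 * (rng.uniform(-1, 1) * X + rng.uniform(-1, 1) * Y
                         + rng.uniform(-1, 1) * Z)
                + 2.0 * (rng.uniform(-1, 1) * X * Y + rng.uniform(-1, 1) * Y * Z
                         + rng.uniform(-1, 1) * X * Z
                         + rng.uniform(-1, 1) * (X**2 - Z**2))
            )
            maps[c] = mag * np.exp(1j * ph)
    return CoilProfileSet(maps)


def make_b1_transmit_maps(
    grid: Grid3D, n_tx: int, seed: int = 0, flat: bool = False
) -> B1MapSet:
    """Smooth complex transmit profiles with a centre-dominant CP sum.

    Each element's phase tracks its azimuthal position, so the CP drive
    interferes constructively at the head centre and decoheres towards the
    periphery, producing the characteristic centre-bright CP mode whose
    nonuniformity the pTx design has to fix.
    """
    if n_tx < 1:
        raise ValueError("need at least one transmit channel")
    if flat:
        return B1MapSet(np.ones((n_tx,) + tuple(grid.shape), np.complex128))
    rng = np.random.default_rng(seed)
    xs, ys, zs = _normalized_coords(grid)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    maps = np.empty((n_tx,) + tuple(grid.shape), np.complex128)
    for c in range(n_tx):
        phi = 2 * np.pi * c / n_tx
        cx, cy = 1.4 * np.cos(phi), 1.4 * np.sin(phi)
        d2 = (X - cx) ** 2 + (Y - cy) ** 2 + 0.5 * Z**2
        mag = np.exp(-d2 / (2 * 1.0**2)) * (1.0 + 0.1 * rng.uniform(-1, 1))
        # element phase: CP-compensating azimuthal term + propagation-like
        # phase growing with distance from the element; at the defaults the
        # CP-mode magnitude shows a centre-bright profile with CoV ~ 0.3
        # over the head, the nonuniformity scale reported for CP drive at
        # this field strength
        ph = (
            -2 * np.pi * c / n_tx
            + 3.0 * np.sqrt(d2)
            + rng.uniform(-0.3, 0.3)
        )
        maps[c] = mag * np.exp(1j * ph)
    return B1MapSet(maps)


def _smooth_random_walk(n: int, rng: np.random.Generator, sigma: float = 2.0):
    steps = rng.standard_normal(n)
    walk = np.cumsum(steps)
    walk = ndimage.gaussian_filter1d(walk, sigma, mode="nearest")
    walk -= walk[0]
    return walk


def make_motion_trace(
    n_frames: int,
    max_translation_mm: float,
    max_rotation_deg: float,
    style: str = "smooth_drift",
    seed: int = 0,
    frame_interval: float = 0.468,
    resp_fraction: float = 0.0,
    resp_freq_hz: float = 0.3,
) -> MotionTrace:
    """Seeded head-motion trajectory; frame 0 is always the identity.

    ``smooth_drift`` integrates a low-pass-filtered random walk per
    parameter, rescaled so each parameter's excursion stays within 50-100%
    of the stated maximum; ``step`` is a single abrupt pose change at the
    middle of the series.  ``resp_fraction`` > 0 superimposes a
    respiratory-like oscillation (head nodding with breathing) of that
    fraction of the maxima at ``resp_freq_hz`` on tz and rx, the axes that
    dominate breathing-linked head motion.
    """
    if max_translation_mm < 0 or max_rotation_deg < 0:
        raise ValueError("amplitudes must be non-negative")
    rng = np.random.default_rng(seed)
    params = np.zeros((n_frames, 6))
    maxima = [max_translation_mm] * 3 + [max_rotation_deg] * 3
    if style == "smooth_drift":
        for p in range(6):
            w = _smooth_random_walk(n_frames, rng)
            peak = np.max(np.abs(w))
            amp = maxima[p] * rng.uniform(0.5, 1.0) * (1.0 - resp_fraction)
            if peak > 0:
                params[:, p] = w / peak * amp
        if resp_fraction > 0:
            t = np.arange(n_frames) * frame_interval
            phase = rng.uniform(0, 2 * np.pi)
            breath = np.sin(2 * np.pi * resp_freq_hz * t + phase)
            breath = 0.5 * (breath - breath[0])  # in [-1, 1], identity at 0
            params[:, 2] += resp_fraction * maxima[2] * breath
            params[:, 3] += resp_fraction * maxima[3] * breath
    elif style == "step":
        pose = np.array(
            [rng.uniform(0.5, 1.0) * rng.choice([-1, 1]) * m for m in maxima]
        )
        params[n_frames // 2 :, :] = pose
    else:
        raise ValueError(f"unknown motion style {style!r}")
    frames = [RigidTransform.from_parameters(p) for p in params]
    return MotionTrace(frames, frame_interval)


def make_field_trace(
    n_frames: int,
    max_g0_hz: float,
    max_grad_hz_per_mm: float,
    seed: int = 0,
    style: str = "smooth_drift",
    frame_interval: float = 0.468,
) -> FieldTrace:
    """Seeded B0 drift trajectory (global Hz + linear Hz/mm terms)."""
    if max_g0_hz < 0 or max_grad_hz_per_mm < 0:
        raise ValueError("amplitudes must be non-negative")
    rng = np.random.default_rng(seed)
    out = np.zeros((n_frames, 4))
    maxima = [max_g0_hz] + [max_grad_hz_per_mm] * 3
    if style == "smooth_drift":
        for p in range(4):
            w = _smooth_random_walk(n_frames, rng)
            peak = np.max(np.abs(w))
            amp = maxima[p] * rng.uniform(0.5, 1.0)
            if peak > 0:
                out[:, p] = w / peak * amp
    elif style == "step":
        vals = np.array(
            [rng.uniform(0.5, 1.0) * rng.choice([-1, 1]) * m for m in maxima]
        )
        out[n_frames // 2 :, :] = vals
    else:
        raise ValueError(f"unknown field style {style!r}")
    return FieldTrace(out[:, 0], out[:, 1], out[:, 2], out[:, 3], frame_interval)


def make_parcel_params(n_parcels: int, rng: np.random.Generator) -> list:
    """Seeded spherical parcel geometry (centres and radii, normalized)."""
    return [
        (0.45 * rng.uniform(-1, 1, size=3), rng.uniform(0.15, 0.25))
        for _ in range(n_parcels)
    ]


def parcel_masks(
    grid: Grid3D,
    params: list,
    mask: np.ndarray,
    pose: RigidTransform | None = None,
) -> np.ndarray:
    """Labels of the 'active' parcels (1..n inside, 0 outside), posable.

    Parcels are defined in the head frame; under a pose they move with the
    head, like the phantom itself.
    """
    if pose is not None and not pose.is_identity():
        from .geometry import invert_rigid

        ax = grid.world_coordinates()
        Xw, Yw, Zw = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([Xw.ravel(), Yw.ravel(), Zw.ravel()], axis=1)
        mapped = invert_rigid(pose, grid.center).apply_points(pts, grid.center)
        c = grid.center
        half = np.maximum(np.asarray(grid.fov) / 2.0, 1e-9)
        X = ((mapped[:, 0] - c[0]) / half[0]).reshape(grid.shape)
        Y = ((mapped[:, 1] - c[1]) / half[1]).reshape(grid.shape)
        Z = ((mapped[:, 2] - c[2]) / half[2]).reshape(grid.shape)
    else:
        xs, ys, zs = _normalized_coords(grid)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    labels = np.zeros(grid.shape, np.int32)
    for p, (center, radius) in enumerate(params):
        blob = (
            (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
        ) <= radius**2
        labels[blob & mask & (labels == 0)] = p + 1
    return labels


def _make_parcels(
    mask: np.ndarray, grid: Grid3D, n_parcels: int, rng: np.random.Generator
) -> np.ndarray:
    return parcel_masks(grid, make_parcel_params(n_parcels, rng), mask)


def simulate_bold_series(
    phantom: np.ndarray,
    mask: np.ndarray,
    n_volumes: int,
    tr_volume_s: float,
    band_hz: tuple[float, float] = (0.01, 0.08),
    amplitude_percent: float = 2.0,
    noise_sd: float = 0.0,
    n_parcels: int = 4,
    seed: int = 0,
    grid: Grid3D | None = None,
) -> tuple[TimeSeries4D, np.ndarray, np.ndarray]:
    """Baseline phantom plus coherent low-frequency fluctuations + noise.

    Each of ``n_parcels`` ellipsoidal parcels receives a common sinusoid at
    a seeded frequency inside ``band_hz`` (amplitude in percent of the
    parcel-mean baseline); white Gaussian noise of SD ``noise_sd`` is added
    everywhere inside the mask.  Returns the series, the ground-truth
    parcel labels and the ground-truth per-voxel fluctuation amplitude.
    """
    if n_volumes < 8:
        raise ValueError("need at least 8 volumes")
    fs = 1.0 / tr_volume_s
    if band_hz[1] > fs / 2:
        raise ValueError(
            f"band upper edge {band_hz[1]} Hz exceeds Nyquist {fs / 2:.4f} Hz"
        )
    if grid is None:
        grid = Grid3D.centered(phantom.shape)
    rng = np.random.default_rng(seed)
    labels = _make_parcels(mask, grid, n_parcels, rng)
    t = np.arange(n_volumes) * tr_volume_s
    data = np.repeat(phantom[None].astype(float), n_volumes, axis=0)
    amp_map = np.zeros(phantom.shape)
    for p in range(1, n_parcels + 1):
        sel = labels == p
        if not np.any(sel):
            continue
        f = rng.uniform(*band_hz)
        phase = rng.uniform(0, 2 * np.pi)
        base = float(np.mean(phantom[sel]))
        amp = amplitude_percent / 100.0 * base
        wave = amp * np.sin(2 * np.pi * f * t + phase)
        data[:, sel] += wave[:, None]
        amp_map[sel] = amp
    if noise_sd > 0:
        data[:, mask] += rng.normal(scale=noise_sd, size=(n_volumes, int(mask.sum())))
    return TimeSeries4D(data, grid, tr_volume_s), labels, amp_map
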