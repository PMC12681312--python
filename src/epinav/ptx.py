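"""kT-point spatial-spectral pTx pulse design with Bloch verification.

A kT-point pulse is a train of short rectangular subpulses played while
gradient blips (idealised here as instantaneous) move the excitation
k-space location through a small symmetric set of points.  Channel weights
per point are found by regularised magnitude least squares (variable
exchange), targeting uniform in-brain flip angle over a water passband and
zero flip over a fat stopband.  The small-tip system matrix and a
hard-pulse Bloch simulator share all conventions so they agree to the
small-tip limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Grid3D
from .phantom import B1MapSet

__all__ = [
    "GAMMA_HZ_PER_T",
    "fat_water_shift_hz",
    "KTPointPulse",
    "SpectralTarget",
    "FlipAngleMap",
    "afi_flip_angle",
    "combine_hybrid_b1",
    "default_kt_locations",
    "build_system_matrix",
    "design_mls_pulse",
    "choose_lambda",
    "cp_mode_pulse",
    "scale_pulse_to_mean_fa",
    "bloch_simulate",
    "flip_angle_cov",
]

GAMMA_HZ_PER_T = 42.577e6  # gyromagnetic ratio of 1H, Hz/T
GAMMA_RAD_PER_S_PER_UT = 2 * np.pi * GAMMA_HZ_PER_T * 1e-6  # rad/s per microtesla


def fat_water_shift_hz(b0_tesla: float, ppm: float = 3.5) -> float:
    """Fat-water chemical-shift frequency offset (negative, Hz).

    At 10.5 T the 3.5-ppm shift evaluates to about -1565 Hz.
    """
    return -ppm * 1e-6 * GAMMA_HZ_PER_T * b0_tesla


@dataclass
class KTPointPulse:
    """Channel weights at each excitation-k-space point.

    weights : complex (n_tx, n_points), normalised drive units
    kt_locations : (n_points, 3) cycles/m
    subpulse_duration : s
    """

    weights: np.ndarray
    kt_locations: np.ndarray
    subpulse_duration: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, np.complex128)
        self.kt_locations = np.asarray(self.kt_locations, float)
        if self.weights.shape[1] != self.kt_locations.shape[0]:
            raise ValueError("weights and kt_locations disagree on n_points")

    @property
    def n_points(self) -> int:
        return int(self.kt_locations.shape[0])

    @property
    def n_tx(self) -> int:
        return int(self.weights.shape[0])

    @property
    def total_duration(self) -> float:
        return self.n_points * self.subpulse_duration

    @property
    def rf_power(self) -> float:
        return float(np.sum(np.abs(self.weights) ** 2))

    def subpulse_times(self) -> np.ndarray:
        """Impulse time of each subpulse, at the end of its interval (s)."""
        return (np.arange(self.n_points) + 1) * self.subpulse_duration


@dataclass
class SpectralTarget:
    """Target flip angle (deg) at each evaluated off-resonance frequency."""

    frequencies: np.ndarray
    target_fa: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, float)
        self.target_fa = np.asarray(self.target_fa, float)
        if self.frequencies.shape != self.target_fa.shape:
            raise ValueError("frequencies/target_fa length mismatch")
        if np.any(self.target_fa < 0):
            raise ValueError("target flip angles must be non-negative")

    @classmethod
    def water_fat(
        cls,
        nominal_fa_deg: float = 10.0,
        b0_tesla: float = 10.5,
        bandwidth_hz: float = 200.0,
        n_points: int = 3,
    ) -> "SpectralTarget":
        """Water passband at the nominal FA, fat stopband at zero.

        Each band holds ``n_points`` samples spanning ``bandwidth_hz``
        (default three points in 100-Hz steps), the passband centred at
        0 Hz and the stopband at the fat-water shift.
        """
        off = np.linspace(-bandwidth_hz / 2, bandwidth_hz / 2, n_points)
        fat = fat_water_shift_hz(b0_tesla)
        freqs = np.concatenate([off, fat + off])
        fa = np.concatenate([np.full(n_points, nominal_fa_deg), np.zeros(n_points)])
        return cls(freqs, fa)


@dataclass
class FlipAngleMap:
    """Flip angle in degrees per voxel (per evaluated frequency)."""

    fa: np.ndarray  # (...,) or (n_freq, ...) degrees
    mask: np.ndarray
    frequencies: np.ndarray | None = None
    valid: np.ndarray | None = None  # per-voxel validity (AFI domain check)


def afi_flip_angle(s1: np.ndarray, s2: np.ndarray, n: float) -> FlipAngleMap:
    """Actual flip-angle imaging: FA from the dual-TR signal ratio.

    With r = S2/S1 and TR ratio n = TR2/TR1, the AFI signal model gives
    ``cos(alpha) = (r*n - 1) / (n - r)``.  Voxels whose ratio falls outside
    the physical arccos domain are flagged invalid and masked out.
    """
    if n <= 1:
        raise ValueError("TR ratio n must exceed 1")
    s1 = np.asarray(s1, float)
    s2 = np.asarray(s2, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(s1 > 0, s2 / np.where(s1 > 0, s1, 1.0), np.nan)
        cosa = (r * n - 1.0) / (n - r)
    valid = np.isfinite(cosa) & (cosa >= -1.0) & (cosa <= 1.0) & (s1 > 0)
    fa = np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0)))
    fa = np.where(valid, fa, 0.0)
    return FlipAngleMap(fa=fa, mask=valid, valid=valid)


def combine_hybrid_b1(
    absolute_cp_map: np.ndarray,
    relative_maps: np.ndarray,
    cp_weights: np.ndarray,
    eps_rel: float = 1e-6,
) -> tuple[B1MapSet, int]:
    """Absolute per-channel B1+ maps from one absolute CP map + relative maps.

    ``absolute_c = relative_c * absolute_cp / |sum_c w_c relative_c|``
    voxelwise.  Voxels where the CP combination of the relative maps nearly
    vanishes are zeroed; their count is returned.
    """
    rel = np.asarray(relative_maps, np.complex128)
    w = np.asarray(cp_weights, np.complex128)
    if rel.shape[0] != w.shape[0]:
        raise ValueError("channel count mismatch")
    cp_sum = np.tensordot(w, rel, axes=(0, 0))
    thresh = eps_rel * np.max(np.abs(cp_sum))
    bad = np.abs(cp_sum) <= thresh
    denom = np.where(bad, 1.0, np.abs(cp_sum))
    scale = np.asarray(absolute_cp_map, float) / denom
    maps = rel * np.where(bad, 0.0, scale)[None]
    return B1MapSet(maps), int(bad.sum())


def default_kt_locations(
    fov_m: tuple[float, float, float], n_points: int = 24
) -> np.ndarray:
    """Fixed symmetric kT-point set on a small lattice within +/-2 cycles/FOV.

    Points come in +/- pairs (symmetric about the excitation k-space
    origin), ordered by decreasing |k| and ending with two DC points, the
    usual ordering that puts the dominant DC subpulses at the end of the
    train.
    """
    if n_points % 2 != 0:
        raise ValueError("n_points must be even (symmetric +/- pairs)")
    fov = np.asarray(fov_m, float)
    candidates = []
    for ix in (0, 1, 2):
        for iy in (0, 1, 2):
            for iz in (0, 1, 2):
                if ix == iy == iz == 0:
                    continue
                candidates.append(np.array([ix, iy, iz], float))
    candidates.sort(key=lambda v: (np.sum((v / 1.0) ** 2), tuple(v)))
    n_pairs = n_points // 2 - 1  # two DC points close the train
    locs = []
    for v in candidates[:n_pairs]:
        k = v / fov
        locs.append(+k)
        locs.append(-k)
    locs = sorted(locs, key=lambda k: -float(np.sum(k**2)))
    locs.append(np.zeros(3))
    locs.append(np.zeros(3))
    return np.asarray(locs)


def build_system_matrix(
    b1: B1MapSet,
    b0_hz: np.ndarray,
    mask: np.ndarray,
    kt_locations: np.ndarray,
    subpulse_times: np.ndarray,
    freqs,
    grid: Grid3D,
    drive_scale_ut: float = 1.0,
) -> np.ndarray:
    """Small-tip-angle system matrix of the kT-point pulse.

    Rows are (voxel in mask, frequency); columns are (channel, kT point);
    an entry is ``i * gamma * dt * B1_c(r) * exp(i 2 pi k . r)
    * exp(i 2 pi (f + b0(r)) (t_k - T))`` in radians of flip per unit
    drive, with voxel positions in metres and subpulse impulse times
    ``t_k`` relative to the pulse end ``T``.  ``drive_scale_ut`` converts
    the normalised B1 maps to microtesla per unit drive.
    """
    mask = np.asarray(mask, bool)
    freqs = np.atleast_1d(np.asarray(freqs, float))
    kt = np.asarray(kt_locations, float)
    tks = np.asarray(subpulse_times, float)
    if kt.shape[0] != tks.shape[0]:
        raise ValueError("kt_locations and subpulse_times length mismatch")
    if b1.maps.shape[1:] != mask.shape or np.asarray(b0_hz).shape != mask.shape:
        raise ValueError("B1/B0/mask shape mismatch")
    dt = float(tks[1] - tks[0]) if tks.size > 1 else float(tks[0])
    ax = grid.world_coordinates()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    r_m = np.stack([X[mask], Y[mask], Z[mask]], axis=1) * 1e-3  # mm -> m
    b0v = np.asarray(b0_hz, float)[mask]
    T = float(tks[-1])
    nv, nf = r_m.shape[0], freqs.size
    n_tx, n_kt = b1.n_tx, kt.shape[0]
    spatial = np.exp(2j * np.pi * (r_m @ kt.T))  # (nv, n_kt)
    b1v = b1.maps[:, mask].T * drive_scale_ut  # (nv, n_tx)
    A = np.empty((nv * nf, n_tx * n_kt), np.complex128)
    for fi, f in enumerate(freqs):
        spectral = np.exp(
            2j * np.pi * (f + b0v)[:, None] * (tks - T)[None, :]
        )  # (nv, n_kt)
        phase = spatial * spectral  # (nv, n_kt)
        block = (
            1j
            * GAMMA_RAD_PER_S_PER_UT
            * dt
            * b1v[:, :, None]
            * phase[:, None, :]
        ).reshape(nv, n_tx * n_kt)
        A[fi * nv : (fi + 1) * nv] = block
    return A


def _target_vector(target: SpectralTarget, n_vox: int) -> np.ndarray:
    """Row-ordered target magnitudes in radians: (freq-major, voxel-minor)."""
    return np.repeat(np.deg2rad(target.target_fa), n_vox)


def design_mls_pulse(
    A: np.ndarray,
    target: SpectralTarget,
    n_vox: int,
    n_tx: int,
    kt_locations: np.ndarray,
    subpulse_duration: float,
    lambda_power: float = 1e-2,
    n_iter: int = 40,
    init: str = "cp",
) -> tuple[KTPointPulse, dict]:
    """Regularised magnitude-least-squares design by variable exchange.

    Alternates (i) ``z <- exp(i arg(A b))`` and (ii) the regularised linear
    solve ``b <- argmin ||A b - m z||^2 + lambda ||b||^2``.  The cost is
    non-increasing across iterations; the best iterate is returned.
    """
    if lambda_power < 0:
        raise ValueError("lambda must be non-negative")
    m = _target_vector(target, n_vox)
    n_kt = np.asarray(kt_locations).shape[0]
    n_cols = A.shape[1]
    if n_cols != n_tx * n_kt:
        raise ValueError("system matrix columns != n_tx * n_kt")
    AhA = A.conj().T @ A
    reg = AhA + lambda_power * np.eye(n_cols)
    try:
        reg_solve = np.linalg.cholesky(reg)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "regularised normal matrix not positive definite"
        ) from exc

    def solve(rhs):
        yv = np.linalg.solve(reg_solve, rhs)
        return np.linalg.solve(reg_solve.conj().T, yv)

    if init == "cp":
        b = np.zeros(n_cols, np.complex128)
        w = np.exp(2j * np.pi * np.arange(n_tx) / n_tx) / np.sqrt(n_tx)
        b = np.repeat(w, n_kt) / n_kt
    elif init == "random":
        rng = np.random.default_rng(0)
        b = (rng.standard_normal(n_cols) + 1j * rng.standard_normal(n_cols)) / n_cols
    else:
        raise ValueError(f"unknown init {init!r}")

    def cost_of(bvec, z):
        return float(
            np.sum(np.abs(A @ bvec - m * z) ** 2)
            + lambda_power * np.sum(np.abs(bvec) ** 2)
        )

    costs = []
    best_b, best_cost = b, np.inf
    for _ in range(n_iter):
        Ab = A @ b
        z = np.where(np.abs(Ab) > 0, np.exp(1j * np.angle(Ab)), 1.0)
        b = solve(A.conj().T @ (m * z))
        c = cost_of(b, z)
        costs.append(c)
        if c < best_cost:
            best_cost, best_b = c, b
    pulse = KTPointPulse(
        weights=best_b.reshape(n_tx, n_kt),
        kt_locations=np.asarray(kt_locations, float),
        subpulse_duration=subpulse_duration,
    )
    resid = float(np.linalg.norm(np.abs(A @ best_b) - m) / (np.linalg.norm(m) or 1.0))
    history = {"cost": np.asarray(costs), "best_cost": best_cost, "mag_residual": resid}
    return pulse, history


def choose_lambda(
    A: np.ndarray,
    target: SpectralTarget,
    n_vox: int,
    n_tx: int,
    kt_locations,
    subpulse_duration: float,
    cp_power: float,
    power_factor: float = 4.0,
    n_iter: int = 25,
    grid_points: int = 10,
) -> float:
    """10-point logarithmic lambda sweep: smallest residual subject to
    ``||b||^2 <= power_factor * cp_power``. Deterministic."""
    scale = float(np.trace((A.conj().T @ A).real)) / A.shape[1]
    lams = scale * np.logspace(-6, 2, grid_points)
    best_lam, best_res = lams[-1], np.inf
    for lam in lams:
        pulse, hist = design_mls_pulse(
            A, target, n_vox, n_tx, kt_locations, subpulse_duration,
            lambda_power=lam, n_iter=n_iter,
        )
        if pulse.rf_power <= power_factor * cp_power and hist["mag_residual"] < best_res:
            best_res, best_lam = hist["mag_residual"], lam
    return float(best_lam)


def cp_mode_pulse(
    n_tx: int,
    kt_locations: np.ndarray,
    subpulse_duration: float,
    amplitude: float = 1.0,
) -> KTPointPulse:
    """CP-mode reference: a non-selective DC pulse with CP channel phases.

    All drive is placed on the DC kT points, so the spatial flip-angle
    profile is simply |CP-combined B1| -- the conventional birdcage-like
    excitation the pTx design is compared against.
    """
    kt = np.asarray(kt_locations, float)
    n_kt = kt.shape[0]
    dc = np.all(kt == 0, axis=1)
    if not np.any(dc):
        dc = np.zeros(n_kt, bool)
        dc[-1] = True
    w = np.exp(2j * np.pi * np.arange(n_tx) / n_tx) / np.sqrt(n_tx)
    weights = np.zeros((n_tx, n_kt), np.complex128)
    weights[:, dc] = (amplitude / dc.sum()) * w[:, None]
    return KTPointPulse(weights, kt, subpulse_duration)


def scale_pulse_to_mean_fa(
    pulse: KTPointPulse,
    b1: B1MapSet,
    b0_hz: np.ndarray,
    mask: np.ndarray,
    grid: Grid3D,
    target_mean_fa_deg: float,
    freq_hz: float = 0.0,
    drive_scale_ut: float = 1.0,
) -> KTPointPulse:
    """Rescale pulse weights so the Bloch mean FA over the mask matches."""
    fa = bloch_simulate(pulse, b1, b0_hz, [freq_hz], grid, drive_scale_ut)
    mean_fa = float(np.mean(fa.fa[0][np.asarray(mask, bool)]))
    if mean_fa <= 0:
        raise ValueError("cannot scale a zero-flip pulse")
    return KTPointPulse(
        pulse.weights * (target_mean_fa_deg / mean_fa),
        pulse.kt_locations,
        pulse.subpulse_duration,
    )


def bloch_simulate(
    pulse: KTPointPulse,
    b1: B1MapSet,
    b0_hz: np.ndarray,
    eval_freqs,
    grid: Grid3D | None = None,
    drive_scale_ut: float = 1.0,
) -> FlipAngleMap:
    """Hard-pulse Bloch simulation of the kT-point train.

    Alternates free precession over each subpulse interval with an
    instantaneous rotation by the net complex RF of that kT point
    (channel-combined B1 with the point's spatial phase).  Returns the
    angle of the final magnetisation from +z, in degrees, per frequency.
    """
    if b1.n_tx != pulse.n_tx:
        raise ValueError("pulse/channel count mismatch")
    shape = b1.maps.shape[1:]
    if grid is None:
        grid = Grid3D.centered(shape)
    freqs = np.atleast_1d(np.asarray(eval_freqs, float))
    ax = grid.world_coordinates()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    r_m = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1) * 1e-3
    b0v = np.asarray(b0_hz, float).ravel()
    b1v = b1.maps.reshape(b1.n_tx, -1).T * drive_scale_ut  # (nv, n_tx)
    kt = pulse.kt_locations
    dt = pulse.subpulse_duration
    spatial = np.exp(2j * np.pi * (r_m @ kt.T))  # (nv, n_kt)
    rf = (b1v @ pulse.weights) * spatial  # (nv, n_kt) net complex B1, uT units
    theta = GAMMA_RAD_PER_S_PER_UT * np.abs(rf) * dt  # rotation angle per point
    phi = np.angle(rf)
    out = np.empty((freqs.size,) + shape)
    nv = r_m.shape[0]
    for fi, f in enumerate(freqs):
        # transverse phase convention matches the system matrix: the
        # contribution of the impulse at t_k carries exp(+i 2 pi f (t_k - T)),
        # i.e. precession rotates the transverse plane by -2 pi f dt
        dpsi = -2 * np.pi * (f + b0v) * dt
        M = np.zeros((nv, 3))
        M[:, 2] = 1.0
        for k in range(pulse.n_points):
            # free precession about +z for dt, then the RF impulse
            c, s = np.cos(dpsi), np.sin(dpsi)
            mx = c * M[:, 0] - s * M[:, 1]
            my = s * M[:, 0] + c * M[:, 1]
            M[:, 0], M[:, 1] = mx, my
            th = theta[:, k]
            ph = phi[:, k]
            ux, uy = np.cos(ph), np.sin(ph)
            ct, st = np.cos(th), np.sin(th)
            dot = ux * M[:, 0] + uy * M[:, 1]
            cx = uy * M[:, 2]
            cy = -ux * M[:, 2]
            cz = ux * M[:, 1] - uy * M[:, 0]
            M = np.stack(
                [
                    ct * M[:, 0] + st * cx + (1 - ct) * dot * ux,
                    ct * M[:, 1] + st * cy + (1 - ct) * dot * uy,
                    ct * M[:, 2] + st * cz,
                ],
                axis=1,
            )
        out[fi] = np.degrees(np.arccos(np.clip(M[:, 2], -1, 1))).reshape(shape)
    return FlipAngleMap(fa=out, mask=np.ones(shape, bool), frequencies=freqs)


def flip_angle_cov(fa_map, mask: np.ndarray) -> float:
    """Coefficient of variation (population SD / mean) over mask voxels.

    For multi-frequency maps the first frequency (water, 0 Hz) is used.
    """
    mask = np.asarray(mask, bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    fa = fa_map.fa if isinstance(fa_map, FlipAngleMap) else np.asarray(fa_map, float)
    if fa.ndim == 4:
        fa = fa[0]
    vals = fa[mask]
    mean = float(np.mean(vals))
    if mean <= 0:
        raise ValueError("mean flip angle over mask must be positive")
    return float(np.std(vals) / mean)
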