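"""End-to-end synthetic sessions: simulate, track, reconstruct, evaluate.

A session emulates one resting-state run of the motion-robust 3D-EPI
protocol at desk scale:

* imaging volume 48 x 44 x 36 at 4 mm (12-fold 3 x 4 CAIPI undersampling,
  two shots per kz plane);
* embedded volumetric navigators sharing the imaging FOV (4 x 2 blipped
  CAIPI, eight lines per TR);
* a fully sampled reference scan that provides — exactly as in the real
  protocol — the coil-combination weights, the GRAPPA autocalibration data
  and a high-resolution anatomical reference;
* rigid-body motion and global + linear B0 drift, constant within a
  navigator frame.

Navigator k-space is the centre crop of the high-resolution object's
spectrum (the navigator shares the imaging FOV, so its samples coincide
with the low-k imaging lattice); the moving object is evaluated
analytically, so motion does not pass through any gridded interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Grid3D, RigidTransform
from .navigator import (
    FieldState,
    GrappaKernel,
    NavigatorFrame,
    combine_channels,
    compute_combination_weights,
    estimate_field_change,
    estimate_motion,
    grappa_calibrate,
    grappa_reconstruct,
    _centered_ifft3,
)
from .phantom import (
    FieldTrace,
    MotionTrace,
    PhantomSpec,
    make_coil_sensitivities,
    make_field_trace,
    make_motion_trace,
    make_phantom,
)
from .recon import (
    EncodingState,
    EPIOperator,
    KSpaceData,
    TimeSeries4D,
    reconstruct_series,
)
from .sampling import (
    NavigatorSchedule,
    SamplingPattern,
    build_caipi_pattern,
    build_navigator_schedule,
    caipi_mask,
)

__all__ = [
    "SessionConfig",
    "SyntheticSession",
    "simulate_session",
    "estimate_navigator_traces",
    "motion_rms_error",
]


def _centered_dft3(x: np.ndarray) -> np.ndarray:
    axes = (-3, -2, -1)
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes), axes=axes
    )


def _crop_center(k: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    sl = tuple(
        slice(n // 2 - m // 2, n // 2 - m // 2 + m)
        for n, m in zip(k.shape[-3:], shape)
    )
    return k[(..., *sl)]


@dataclass
class SessionConfig:
    """Study conditions of the desk-scale synthetic session."""

    matrix: tuple[int, int, int] = (48, 44, 36)
    voxel_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    n_channels: int = 16
    n_tissues: int = 3
    # phantom edge softness; None = 1.5 voxels (the object must be
    # resolvable on the simulation grid or interpolation model error
    # dominates every comparison)
    edge_mm: float | None = None
    # imaging acquisition (3 x 4 CAIPI, two shots per kz plane, TR 39 ms)
    accel: tuple[int, int] = (3, 4)
    caipi_shift: int = 1
    n_interleaves: int = 2
    tr_s: float = 0.039
    te_s: float = 0.021
    echo_spacing_s: float = 0.00047
    # navigator (4 x 2 blipped CAIPI, 8 lines per TR)
    nav_matrix: tuple[int, int, int] = (24, 16, 16)
    nav_accel: tuple[int, int] = (4, 2)
    nav_lines_per_tr: int = 8
    nav_echo_spacing_s: float = 0.00047
    nav_te_s: float = 0.010
    # motion / field trajectories (one state per navigator frame)
    n_frames: int = 20
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    max_g0_hz: float = 4.0
    max_grad_hz_per_mm: float = 0.02
    motion_style: str = "smooth_drift"
    resp_fraction: float = 0.0  # breathing-linked oscillation share
    resp_freq_hz: float = 0.3
    # noise: complex SD per k-space sample, relative to the RMS signal
    noise_rel: float = 0.02
    n_volumes: int = 0  # imaging volumes to simulate (0 = navigators only)
    # BOLD-like dynamics inside seeded parcels (percent of parcel baseline)
    bold_amplitude_percent: float = 2.0
    bold_band_hz: tuple[float, float] = (0.01, 0.08)
    n_parcels: int = 4
    volume_tr_override_s: float | None = None  # decouple BOLD timing from matrix
    seed: int = 0

    @property
    def grid(self) -> Grid3D:
        return Grid3D.centered(self.matrix, self.voxel_mm)

    @property
    def nav_grid(self) -> Grid3D:
        fov = self.grid.fov
        return Grid3D.centered(
            self.nav_matrix, tuple(f / n for f, n in zip(fov, self.nav_matrix))
        )

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        cfg = cls()
        for k, v in d.items():
            if not hasattr(cfg, k):
                raise KeyError(f"unknown session config key {k!r}")
            default = getattr(cfg, k)
            if isinstance(default, tuple):
                v = tuple(v)
            setattr(cfg, k, v)
        return cfg


@dataclass
class SyntheticSession:
    """All simulated artefacts of one run, plus ground truth."""

    config: SessionConfig
    phantom: np.ndarray
    mask: np.ndarray
    coils: np.ndarray  # (n_channels,) + matrix, imaging grid
    ref_kspace: np.ndarray  # fully sampled reference scan (imaging grid)
    nav_schedule: NavigatorSchedule
    nav_kspace: np.ndarray  # (n_frames, n_channels) + nav matrix, zero-filled
    motion_truth: MotionTrace
    field_truth: FieldTrace
    imaging_pattern: SamplingPattern | None = None
    volumes_kspace: list | None = None  # list of KSpaceData
    bold_truth: TimeSeries4D | None = None  # head-frame series, no motion
    parcel_labels: np.ndarray | None = None
    volume_tr: float | None = None

    @property
    def grid(self) -> Grid3D:
        return self.config.grid

    @property
    def nav_grid(self) -> Grid3D:
        return self.config.nav_grid

    def reference_object(self, reg: float = 1e-3) -> np.ndarray:
        """SENSE-combined object estimate from the reference scan."""
        imgs = _centered_ifft3(self.ref_kspace)
        ss = np.sum(np.abs(self.coils) ** 2, axis=0)
        return np.real(
            np.sum(np.conj(self.coils) * imgs, axis=0) / (ss + reg * ss.max())
        )

    def nav_acs(self) -> np.ndarray:
        """Navigator-matrix ACS block cropped from the reference scan."""
        return _crop_center(self.ref_kspace, self.config.nav_matrix)


def _nav_kspace_of(
    obj_hi: np.ndarray, coils: np.ndarray, nav_matrix
) -> np.ndarray:
    """Navigator-band multi-channel k-space of a high-res object."""
    return _crop_center(_centered_dft3(obj_hi[None] * coils), nav_matrix)


def simulate_session(config: SessionConfig) -> SyntheticSession:
    """Generate one synthetic run (navigators + optional imaging volumes)."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xE51]))
    grid = cfg.grid
    edge = cfg.edge_mm if cfg.edge_mm is not None else 1.5 * max(cfg.voxel_mm)
    spec = PhantomSpec(grid, cfg.n_tissues, seed=cfg.seed, edge_mm=edge)
    phantom_img, mask = make_phantom(spec)
    coils = make_coil_sensitivities(grid, cfg.n_channels, seed=cfg.seed + 1).maps

    schedule = build_navigator_schedule(
        cfg.nav_matrix,
        cfg.nav_accel,
        cfg.nav_lines_per_tr,
        cfg.nav_echo_spacing_s,
        cfg.tr_s,
        cfg.caipi_shift,
        nav_start_s=cfg.nav_te_s,
    )
    motion = make_motion_trace(
        cfg.n_frames,
        cfg.max_translation_mm,
        cfg.max_rotation_deg,
        cfg.motion_style,
        seed=cfg.seed + 2,
        frame_interval=schedule.frame_interval,
        resp_fraction=cfg.resp_fraction,
        resp_freq_hz=cfg.resp_freq_hz,
    )
    fieldtr = make_field_trace(
        cfg.n_frames,
        cfg.max_g0_hz,
        cfg.max_grad_hz_per_mm,
        seed=cfg.seed + 3,
        frame_interval=schedule.frame_interval,
    )

    # reference scan: fully sampled, motion-free
    ref_k = _centered_dft3(phantom_img[None] * coils)
    sig_rms = float(np.sqrt(np.mean(np.abs(ref_k) ** 2)))
    noise_sd = cfg.noise_rel * sig_rms

    def add_noise(k):
        if noise_sd <= 0:
            return k
        n = rng.normal(size=k.shape) + 1j * rng.normal(size=k.shape)
        return k + noise_sd / np.sqrt(2) * n

    ref_k = add_noise(ref_k)

    # navigators: analytic moving object, band-limited to the nav matrix,
    # field-state phase at the navigator echo, undersampled on the CAIPI mask
    nav_mask = caipi_mask(
        cfg.nav_matrix[1], cfg.nav_matrix[2], *cfg.nav_accel, cfg.caipi_shift
    )
    nav_grid = cfg.nav_grid
    ax = nav_grid.world_coordinates()
    Xn, Yn, Zn = np.meshgrid(*ax, indexing="ij")
    frames = np.empty(
        (cfg.n_frames, cfg.n_channels, *cfg.nav_matrix), np.complex128
    )
    for i in range(cfg.n_frames):
        moved, _ = make_phantom(spec, pose=motion.frames[i])
        fs = FieldState(
            fieldtr.g0[i], fieldtr.gx[i], fieldtr.gy[i], fieldtr.gz[i]
        )
        k = _nav_kspace_of(moved, coils, cfg.nav_matrix)
        if not fs.is_zero():
            # phase accrued at the navigator echo time (image-domain ramp:
            # the nav readout is short, so one phase per frame suffices)
            phase = np.exp(
                2j
                * np.pi
                * cfg.nav_te_s
                * (fs.g0 + fs.gx * Xn + fs.gy * Yn + fs.gz * Zn)
            )
            img = _centered_ifft3(k)
            k = _centered_dft3(img * phase[None])
        frames[i] = add_noise(k) * nav_mask[None, None, :, :]

    session = SyntheticSession(
        config=cfg,
        phantom=phantom_img,
        mask=mask,
        coils=coils,
        ref_kspace=ref_k,
        nav_schedule=schedule,
        nav_kspace=frames,
        motion_truth=motion,
        field_truth=fieldtr,
    )

    if cfg.n_volumes > 0:
        from .phantom import make_parcel_params, parcel_masks
        from .recon import states_from_traces

        pattern = build_caipi_pattern(
            cfg.matrix,
            *cfg.accel,
            cfg.caipi_shift,
            n_interleaves=cfg.n_interleaves,
            echo_spacing=cfg.echo_spacing_s,
            te=cfg.te_s,
            tr=cfg.tr_s,
        )
        nz_shots = (cfg.matrix[2] // cfg.accel[1]) * cfg.n_interleaves
        volume_tr = cfg.volume_tr_override_s or nz_shots * cfg.tr_s
        # BOLD-like dynamics: one seeded sinusoid per parcel, riding on the
        # moving head (parcels are defined in the head frame)
        rng_bold = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB07D]))
        params = make_parcel_params(cfg.n_parcels, rng_bold)
        labels0 = parcel_masks(grid, params, mask)
        freqs = rng_bold.uniform(*cfg.bold_band_hz, size=cfg.n_parcels)
        phases = rng_bold.uniform(0, 2 * np.pi, size=cfg.n_parcels)
        amps = np.array(
            [
                cfg.bold_amplitude_percent
                / 100.0
                * float(np.mean(phantom_img[labels0 == p + 1]))
                if np.any(labels0 == p + 1)
                else 0.0
                for p in range(cfg.n_parcels)
            ]
        )

        def wave(p, t_s):
            return amps[p] * np.sin(2 * np.pi * freqs[p] * t_s + phases[p])

        vols = []
        truth = np.empty((cfg.n_volumes,) + tuple(grid.shape))
        for v in range(cfg.n_volumes):
            t_v = v * volume_tr
            truth[v] = phantom_img.copy()
            for p in range(cfg.n_parcels):
                truth[v][labels0 == p + 1] += wave(p, t_v)
            state = states_from_traces(
                pattern,
                motion,
                fieldtr,
                schedule.frame_interval,
                volume_start_s=v * volume_tr,
            )
            op = EPIOperator(coils, grid, pattern, state)
            samples = np.zeros(op.sample_shape, np.complex128)
            # analytic per-shot evaluation of the moving, fluctuating object
            for s, lines in op._shot_lines.items():
                pose = state.transforms[s]
                moved, moved_mask = make_phantom(spec, pose=pose)
                if cfg.bold_amplitude_percent > 0:
                    posed_labels = parcel_masks(grid, params, moved_mask, pose)
                    for p in range(cfg.n_parcels):
                        moved[posed_labels == p + 1] += wave(p, t_v)
                sub = EncodingState(
                    [RigidTransform.identity()], [state.fields[s]]
                )
                shot_pattern = _pattern_subset(pattern, lines)
                sub_op = EPIOperator(coils, grid, shot_pattern, sub)
                samples[:, lines, :] = sub_op.forward(moved)
            samples = add_noise(samples)
            vols.append(KSpaceData(samples, pattern, noise_sd))
        session.imaging_pattern = pattern
        session.volumes_kspace = vols
        session.bold_truth = TimeSeries4D(truth, grid, volume_tr)
        session.parcel_labels = labels0
        session.volume_tr = volume_tr
    return session


def _pattern_subset(pattern: SamplingPattern, lines) -> SamplingPattern:
    """A pattern containing only the given lines, renumbered to one shot."""
    return SamplingPattern(
        matrix=pattern.matrix,
        accel=pattern.accel,
        caipi_shift=pattern.caipi_shift,
        ky_index=pattern.ky_index[lines],
        kz_index=pattern.kz_index[lines],
        shot_id=np.zeros(len(lines), np.int64),
        tr_index=pattern.tr_index[lines],
        time_s=pattern.time_s[lines],
        time_in_tr_s=pattern.time_in_tr_s[lines],
    )


def estimate_navigator_traces(
    session: SyntheticSession,
    tikhonov: float = 1e-3,
    pyramid_levels: int = 2,
) -> tuple[list, list, list]:
    """Run the navigator pipeline: GRAPPA, registration, field estimation.

    Returns (motion estimates, field estimates, navigator frames); frame 0
    of the run serves as the reference.
    """
    cfg = session.config
    acs = session.nav_acs()
    kernel = grappa_calibrate(
        acs, cfg.nav_accel, cfg.caipi_shift, tikhonov=tikhonov
    )
    nav_grid = session.nav_grid
    nav_mask = caipi_mask(
        cfg.nav_matrix[1], cfg.nav_matrix[2], *cfg.nav_accel, cfg.caipi_shift
    )
    # combination weights from the reference scan (phase-preserving)
    ref_imgs = _centered_ifft3(acs)
    weights = compute_combination_weights(ref_imgs)
    ref_hi = session.reference_object()
    frames = []
    for i in range(cfg.n_frames):
        frames.append(
            grappa_reconstruct(
                session.nav_kspace[i],
                kernel,
                nav_grid,
                weights,
                frame_index=i,
                time_s=i * session.nav_schedule.frame_interval,
            )
        )
    reference = frames[0]
    motion_est, field_est = [], []
    prev = None
    for i, frame in enumerate(frames):
        t = estimate_motion(
            frame,
            reference,
            nav_grid,
            pyramid_levels=pyramid_levels,
            init=prev,
            reference_model=(
                ref_hi, session.coils, session.grid, kernel, nav_mask,
            ),
        )
        prev = t
        f = estimate_field_change(
            frame,
            reference,
            _nav_mask(session),
            cfg.nav_te_s,
            motion=t,
            grid=nav_grid,
        )
        motion_est.append(t)
        field_est.append(f)
    return motion_est, field_est, frames


def _nav_mask(session: SyntheticSession) -> np.ndarray:
    """Object support at navigator resolution."""
    cfg = session.config
    edge = cfg.edge_mm if cfg.edge_mm is not None else 1.5 * max(cfg.voxel_mm)
    spec = PhantomSpec(
        session.nav_grid, cfg.n_tissues, seed=cfg.seed, edge_mm=edge
    )
    _, mask = make_phantom(spec)
    return mask


def reconstruct_session_series(
    session: SyntheticSession,
    mode: str = "corrected",
    motion=None,
    field=None,
    max_iter: int = 40,
) -> TimeSeries4D:
    """Reconstruct the session's imaging run (corrected or uncorrected).

    ``motion``/``field`` default to the session's ground-truth traces; pass
    the navigator estimates to run the full estimated pipeline.
    """
    if not session.volumes_kspace:
        raise ValueError("session holds no imaging volumes")
    cfg = session.config
    motion = motion if motion is not None else session.motion_truth
    field = field if field is not None else session.field_truth
    return reconstruct_series(
        session.volumes_kspace,
        session.coils,
        motion,
        field,
        mode=mode,
        grid=session.grid,
        volume_tr=session.volume_tr,
        frame_interval=session.nav_schedule.frame_interval,
        max_iter=max_iter,
    )


def moving_bold_config(seed: int = 0) -> SessionConfig:
    """Small moving-BOLD session for metric-level comparisons.

    A 24 x 20 x 16 matrix at 8 mm with 2 x 2 CAIPI keeps a full two-mode
    series reconstruction tractable; the volume TR is pinned to the
    protocol's 2.34 s so the resting-state band is resolvable.
    """
    return SessionConfig(
        matrix=(24, 20, 16),
        voxel_mm=(8.0, 8.0, 8.0),
        n_channels=8,
        accel=(2, 2),
        nav_matrix=(16, 16, 16),
        nav_accel=(4, 2),
        # navigator cadence here is 4 TRs x 39 ms; 608 frames span the
        # 40-volume run at the pinned 2.34-s volume TR
        n_frames=608,
        n_volumes=40,
        volume_tr_override_s=2.34,
        # translation-dominant motion: the translation encoding model is
        # exact (FFT phase), so reconstruction differences between modes
        # reflect the correction itself rather than interpolation error of
        # the rotation warp; a small rotational component is kept
        max_translation_mm=3.0,
        max_rotation_deg=0.4,
        resp_fraction=0.3,
        max_g0_hz=3.0,
        max_grad_hz_per_mm=0.01,
        noise_rel=0.02,
        seed=seed,
    )


def motion_rms_error(estimates, truth: MotionTrace) -> tuple[float, float]:
    """RMS error over frames and axes: (translations mm, rotations deg)."""
    est = np.stack([t.parameters for t in estimates])
    tru = truth.parameters()
    err = est - tru
    return (
        float(np.sqrt(np.mean(err[:, :3] ** 2))),
        float(np.sqrt(np.mean(err[:, 3:] ** 2))),
    )
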