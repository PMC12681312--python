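"""3D-EPI CAIPI sampling patterns, navigator schedules and protocol timing.

The readout (kx) direction is fully sampled on every echo; undersampling
happens on the ky-kz phase-encode plane. A 2D CAIPI lattice with
acceleration (Ry, Rz) and shift s samples kz planes at multiples of Rz and,
within the m-th sampled plane, the ky indices congruent to ``s*m mod Ry``.
k-space indices place DC at ``floor(N/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingPattern",
    "NavigatorSchedule",
    "ProtocolTiming",
    "build_caipi_pattern",
    "build_navigator_schedule",
    "volume_timing",
]


@dataclass
class SamplingPattern:
    """Sampled phase-encode lines of one volume with shot/time annotations.

    ``ky_index``/``kz_index`` are array indices into the (ny, nz) phase grid;
    every line covers all nx readout points.
    """

    matrix: tuple[int, int, int]
    accel: tuple[int, int]
    caipi_shift: int
    ky_index: np.ndarray
    kz_index: np.ndarray
    shot_id: np.ndarray
    tr_index: np.ndarray
    time_s: np.ndarray  # acquisition time of each line within the volume
    # echo time of each line within its own TR (time since that shot's
    # excitation) — off-resonance phase accrues on this clock
    time_in_tr_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.time_in_tr_s is None:
            self.time_in_tr_s = np.array(self.time_s, copy=True)

    @property
    def n_lines(self) -> int:
        return int(self.ky_index.size)

    @property
    def n_shots(self) -> int:
        return int(self.shot_id.max()) + 1 if self.n_lines else 0

    def mask(self) -> np.ndarray:
        """Boolean (ny, nz) sampled-line mask."""
        m = np.zeros(self.matrix[1:], dtype=bool)
        m[self.ky_index, self.kz_index] = True
        return m

    def validate(self) -> None:
        ny, nz = self.matrix[1], self.matrix[2]
        if np.any((self.ky_index < 0) | (self.ky_index >= ny)):
            raise ValueError("ky index out of bounds")
        if np.any((self.kz_index < 0) | (self.kz_index >= nz)):
            raise ValueError("kz index out of bounds")
        pairs = set(zip(self.ky_index.tolist(), self.kz_index.tolist()))
        if len(pairs) != self.n_lines:
            raise ValueError("duplicate (ky, kz) line within one volume")


@dataclass
class NavigatorSchedule:
    """Assignment of navigator phase-encode lines to successive TRs."""

    pattern: SamplingPattern
    lines_per_tr: int
    trs_per_volume: int
    echo_spacing: float
    tr: float
    nav_duration_per_tr: float
    frame_interval: float


@dataclass
class ProtocolTiming:
    """Timing of the kz-segmented multi-shot 3D-EPI protocol."""

    tr: float
    te: float | None
    echo_spacing: float | None
    n_interleaves: int
    n_kz_shots: int
    volume_tr: float


def caipi_mask(
    ny: int, nz: int, Ry: int, Rz: int, caipi_shift: int
) -> np.ndarray:
    """Boolean (ny, nz) mask of the CAIPI-shifted undersampling lattice."""
    ky = np.arange(ny)[:, None]
    kz = np.arange(nz)[None, :]
    on_kz = (kz % Rz) == 0
    on_ky = (ky % Ry) == ((caipi_shift * (kz // Rz)) % Ry)
    return on_kz & on_ky


def build_caipi_pattern(
    matrix: tuple[int, int, int],
    Ry: int,
    Rz: int,
    caipi_shift: int = 1,
    *,
    n_interleaves: int = 1,
    echo_spacing: float = 0.0,
    te: float = 0.0,
    tr: float = 0.0,
) -> SamplingPattern:
    """Build the sampled-line table of one CAIPI-undersampled volume.

    Shots follow the kz-segmented scheme: each sampled kz plane is split into
    ``n_interleaves`` shots (one shot per TR), lines ordered by increasing ky
    within a shot.  Line times are TE-centred within the shot's echo train
    and offset by the shot's TR slot, so they strictly increase within a TR.
    """
    nx, ny, nz = matrix
    if Ry < 1 or Rz < 1:
        raise ValueError("acceleration factors must be >= 1")
    if Ry > ny or Rz > nz:
        raise ValueError(f"acceleration ({Ry},{Rz}) exceeds matrix ({ny},{nz})")
    if caipi_shift < 0 or (Ry * Rz > 1 and caipi_shift >= max(Ry, Rz)):
        raise ValueError("caipi_shift must be smaller than the acceleration")
    mask = caipi_mask(ny, nz, Ry, Rz, caipi_shift)
    ky_all, kz_all = np.nonzero(mask)
    ky_idx, kz_idx, shot, trn, t, t_in_tr = [], [], [], [], [], []
    planes = np.unique(kz_all)
    shot_counter = 0
    for plane in planes:
        ky_plane = np.sort(ky_all[kz_all == plane])
        for il in range(n_interleaves):
            ky_shot = ky_plane[il::n_interleaves]
            n = ky_shot.size
            line_no = np.arange(n)
            times_in_tr = te + (line_no - (n - 1) / 2.0) * echo_spacing
            times = shot_counter * tr + times_in_tr
            t_in_tr.append(times_in_tr)
            ky_idx.append(ky_shot)
            kz_idx.append(np.full(n, plane))
            shot.append(np.full(n, shot_counter))
            trn.append(np.full(n, shot_counter))
            t.append(times)
            shot_counter += 1
    pat = SamplingPattern(
        matrix=tuple(matrix),
        accel=(Ry, Rz),
        caipi_shift=caipi_shift,
        ky_index=np.concatenate(ky_idx),
        kz_index=np.concatenate(kz_idx).astype(np.int64),
        shot_id=np.concatenate(shot).astype(np.int64),
        tr_index=np.concatenate(trn).astype(np.int64),
        time_s=np.concatenate(t),
        time_in_tr_s=np.concatenate(t_in_tr),
    )
    pat.validate()
    return pat


def build_navigator_schedule(
    nav_matrix: tuple[int, int, int],
    accel: tuple[int, int],
    lines_per_tr: int,
    echo_spacing: float,
    tr: float,
    caipi_shift: int = 1,
    nav_start_s: float = 0.0,
) -> NavigatorSchedule:
    """Distribute the navigator's CAIPI lines over successive TRs.

    ``nav_start_s`` is the time from excitation to the first navigator echo
    within a TR (the navigator sits between excitation and the BOLD readout).
    """
    nx, ny, nz = nav_matrix
    Ry, Rz = accel
    mask = caipi_mask(ny, nz, Ry, Rz, caipi_shift)
    ky_all, kz_all = np.nonzero(mask)
    order = np.lexsort((ky_all, kz_all))
    ky_all, kz_all = ky_all[order], kz_all[order]
    n_lines = ky_all.size
    if n_lines % lines_per_tr != 0:
        raise ValueError(
            f"{n_lines} sampled navigator lines not divisible by "
            f"{lines_per_tr} lines per TR (residue {n_lines % lines_per_tr})"
        )
    trs_per_volume = n_lines // lines_per_tr
    tr_slot = np.repeat(np.arange(trs_per_volume), lines_per_tr)
    line_in_tr = np.tile(np.arange(lines_per_tr), trs_per_volume)
    times_in_tr = nav_start_s + line_in_tr * echo_spacing
    times = tr_slot * tr + times_in_tr
    pat = SamplingPattern(
        matrix=tuple(nav_matrix),
        accel=(Ry, Rz),
        caipi_shift=caipi_shift,
        ky_index=ky_all,
        kz_index=kz_all,
        shot_id=tr_slot.astype(np.int64),
        tr_index=tr_slot.astype(np.int64),
        time_s=times,
        time_in_tr_s=times_in_tr,
    )
    pat.validate()
    return NavigatorSchedule(
        pattern=pat,
        lines_per_tr=lines_per_tr,
        trs_per_volume=trs_per_volume,
        echo_spacing=echo_spacing,
        tr=tr,
        nav_duration_per_tr=lines_per_tr * echo_spacing,
        frame_interval=trs_per_volume * tr,
    )


def volume_timing(
    matrix: tuple[int, int, int],
    Rz: int,
    n_interleaves: int,
    tr: float,
    te: float | None = None,
    echo_spacing: float | None = None,
) -> ProtocolTiming:
    """Volume TR of the kz-segmented scheme: (nz/Rz) * interleaves * TR."""
    nz = matrix[2]
    if nz % Rz != 0:
        raise ValueError(f"kz matrix {nz} not divisible by Rz={Rz}")
    n_kz_shots = nz // Rz
    return ProtocolTiming(
        tr=tr,
        te=te,
        echo_spacing=echo_spacing,
        n_interleaves=n_interleaves,
        n_kz_shots=n_kz_shots,
        volume_tr=n_kz_shots * n_interleaves * tr,
    )
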