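"""Resting-state fMRI evaluation metrics and denoising chain.

Implements the quantitative chain used to compare corrected and
uncorrected reconstructions: tSNR, Power-style framewise displacement,
DVARS with outlier flagging, 36P confound expansion, CompCor, zero-phase
Butterworth band-pass filtering, confound regression, ALFF, ReHo
(Kendall's coefficient of concordance) and parcelwise functional
connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

__all__ = [
    "MetricMap",
    "tsnr",
    "framewise_displacement",
    "dvars",
    "flag_motion_outliers",
    "expand_confounds",
    "expand_confounds_36p",
    "compcor",
    "bandpass_butterworth",
    "regress_confounds",
    "alff",
    "reho_kcc",
    "fc_matrix",
    "compare_fc",
]

BASE_9P = (
    "trans_x",
    "trans_y",
    "trans_z",
    "rot_x",
    "rot_y",
    "rot_z",
    "global_signal",
    "white_matter",
    "csf",
)


@dataclass
class MetricMap:
    """A voxelwise (or parcelwise) metric image."""

    values: np.ndarray
    name: str
    mask: np.ndarray | None = None
    flagged: np.ndarray | None = None  # degenerate voxels (e.g. zero SD)

    def mean(self) -> float:
        sel = self.mask if self.mask is not None else np.ones(self.values.shape, bool)
        return float(np.mean(self.values[sel]))


def _series_data(series) -> np.ndarray:
    if hasattr(series, "grid"):  # TimeSeries4D-like container
        return np.asarray(series.data, float)
    return np.asarray(series, float)


def tsnr(series, mask: np.ndarray | None = None) -> MetricMap:
    """Temporal SNR: mean over SD of each voxel's time series.

    Voxels with zero temporal SD get value 0 and are flagged.
    """
    data = _series_data(series)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    flagged = sd == 0
    vals = np.where(flagged, 0.0, mean / np.where(flagged, 1.0, sd))
    if mask is None:
        mask = np.ones(vals.shape, bool)
    return MetricMap(vals, "tsnr", np.asarray(mask, bool), flagged)


def framewise_displacement(motion_params, radius_mm: float = 50.0) -> np.ndarray:
    """Power's framewise displacement from 6 rigid parameters per frame.

    ``FD_t = sum |d trans| + radius * sum |d rot (rad)|``; FD of the first
    frame is 0.  ``motion_params`` is (n, 6) ordered translations (mm) then
    rotations (degrees), or a DataFrame with the canonical column names.
    """
    if isinstance(motion_params, pd.DataFrame):
        motion_params = motion_params[list(BASE_9P[:6])].to_numpy(float)
    p = np.asarray(motion_params, float)
    if p.ndim != 2 or p.shape[1] != 6 or p.shape[0] < 2:
        raise ValueError("motion parameters must be (n >= 2, 6)")
    d = np.abs(np.diff(p, axis=0))
    fd = d[:, :3].sum(axis=1) + radius_mm * np.deg2rad(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def dvars(series, mask: np.ndarray, standardize: bool = True) -> np.ndarray:
    """DVARS: RMS over masked voxels of the frame-to-frame difference.

    The standardised variant divides by the series' median raw DVARS (the
    first frame, defined as 0, is excluded from the median).
    """
    data = _series_data(series)
    mask = np.asarray(mask, bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    ts = data[:, mask]
    if ts.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    d = np.sqrt(np.mean(np.diff(ts, axis=0) ** 2, axis=1))
    out = np.concatenate([[0.0], d])
    if standardize:
        med = np.median(d)
        if med > 0:
            out = out / med
    return out


def flag_motion_outliers(
    fd_trace, std_dvars_trace, fd_thresh: float = 0.5, dvars_thresh: float = 1.5
) -> np.ndarray:
    """Frames exceeding the FD *or* standardised-DVARS threshold."""
    fd = np.asarray(fd_trace, float)
    dv = np.asarray(std_dvars_trace, float)
    if fd.shape != dv.shape:
        raise ValueError("trace length mismatch")
    return (fd > fd_thresh) | (dv > dvars_thresh)


def expand_confounds(base: pd.DataFrame) -> pd.DataFrame:
    """Derivatives + quadratic expansion of a base confound table.

    Output = base columns, their backward-difference derivatives (first row
    0), then squares of all of those, in stable order; 9 base columns give
    the 36P set, 6 give 24P.
    """
    out = base.copy()
    for c in base.columns:
        out[f"{c}_derivative1"] = np.concatenate([[0.0], np.diff(base[c].to_numpy())])
    for c in list(out.columns):
        out[f"{c}_power2"] = out[c] ** 2
    return out


def expand_confounds_36p(base: pd.DataFrame) -> pd.DataFrame:
    """36P nuisance set: 9 base signals (6 motion + global/WM/CSF means),
    their temporal derivatives, and squares of all 18."""
    missing = [c for c in BASE_9P if c not in base.columns]
    if missing or base.shape[1] != 9:
        raise ValueError(
            f"36P expansion needs exactly the 9 base columns {BASE_9P}; "
            f"got {list(base.columns)}"
        )
    return expand_confounds(base[list(BASE_9P)])


def _cosine_highpass(ts: np.ndarray, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Remove discrete-cosine drift components with periods above cutoff."""
    n = ts.shape[0]
    frame_times = np.arange(n) * tr_s
    k_max = int(np.floor(2 * n * tr_s / cutoff_s))
    if k_max < 1:
        return ts - ts.mean(axis=0)
    k = np.arange(1, k_max + 1)
    basis = np.cos(
        np.pi * np.outer(frame_times / (n * tr_s), k)
    )
    X = np.column_stack([np.ones(n), basis])
    beta, *_ = np.linalg.lstsq(X, ts, rcond=None)
    return ts - X @ beta


def compcor(
    series,
    mask: np.ndarray,
    variant: str = "temporal",
    variance_fraction: float = 0.5,
    top_voxel_fraction: float = 0.02,
    highpass_cutoff_s: float = 128.0,
    tr_s: float = 2.34,
) -> pd.DataFrame:
    """CompCor nuisance components.

    High-pass the series with a discrete-cosine filter (128-s cutoff), then
    take principal components of the voxels in the noise mask (temporal
    variant: the top ``top_voxel_fraction`` of voxels by temporal SD inside
    ``mask``; anatomical variant: ``mask`` itself).  The smallest number of
    components whose cumulative singular-value energy reaches
    ``variance_fraction`` is retained.
    """
    data = _series_data(series)
    mask = np.asarray(mask, bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    ts = data[:, mask]
    ts = _cosine_highpass(ts, tr_s, highpass_cutoff_s)
    if variant == "temporal":
        sd = ts.std(axis=0)
        k = int(np.ceil(top_voxel_fraction * ts.shape[1]))
        idx = np.argsort(sd)[::-1][:k]
        ts = ts[:, idx]
    elif variant != "anatomical":
        raise ValueError(f"unknown CompCor variant {variant!r}")
    ts = ts - ts.mean(axis=0)
    sdv = ts.std(axis=0)
    ts = ts / np.where(sdv > 0, sdv, 1.0)
    U, S, _ = np.linalg.svd(ts, full_matrices=False)
    energy = np.cumsum(S**2) / np.sum(S**2)
    n_keep = int(np.searchsorted(energy, variance_fraction) + 1)
    comps = U[:, :n_keep] * S[:n_keep]
    return pd.DataFrame(
        comps, columns=[f"{variant[0]}_comp_cor_{i:02d}" for i in range(n_keep)]
    )


def bandpass_butterworth(
    data,
    fs: float,
    low: float = 0.01,
    high: float = 0.08,
    order: int = 2,
    axis: int = 0,
):
    """Zero-phase (forward-backward) Butterworth band-pass along time.

    Accepts arrays (time on ``axis``) or DataFrames (time on rows); the
    identical filter is meant to be applied to both data and confounds.
    """
    nyq = fs / 2
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz outside (0, {nyq:.4f}) Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if isinstance(data, pd.DataFrame):
        vals = signal.sosfiltfilt(sos, data.to_numpy(float), axis=0)
        return pd.DataFrame(vals, columns=data.columns, index=data.index)
    return signal.sosfiltfilt(sos, np.asarray(data, float), axis=axis)


def regress_confounds(series, confounds) -> np.ndarray:
    """Voxelwise OLS removal of nuisance regressors (intercept included).

    Returns the residual series; residuals are orthogonal to every
    regressor.  Rank-deficient designs fall back to the pseudo-inverse.
    """
    data = _series_data(series)
    shape = data.shape
    Y = data.reshape(shape[0], -1)
    C = confounds.to_numpy(float) if isinstance(confounds, pd.DataFrame) else np.asarray(
        confounds, float
    )
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != shape[0]:
        raise ValueError("confound rows != number of volumes")
    if shape[0] <= C.shape[1]:
        raise ValueError("need more volumes than regressors")
    X = np.column_stack([np.ones(shape[0]), C])
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.reshape(shape)
    if hasattr(series, "grid"):
        from .recon import TimeSeries4D

        return TimeSeries4D(out, series.grid, series.tr_volume)
    return out


def alff(
    series,
    fs: float,
    band: tuple[float, float] = (0.01, 0.08),
    mask: np.ndarray | None = None,
) -> MetricMap:
    """Amplitude of low-frequency fluctuation.

    Per voxel: z-normalise the series, take the single-sided power spectrum
    ``|X_k|^2 / n``, average the square root of the power over the
    frequency bins inside ``band`` (inclusive), and multiply by the voxel's
    temporal SD to restore the original scaling.  Zero-SD voxels get 0 and
    are flagged.
    """
    data = _series_data(series)
    n = data.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if in_band.sum() < 2:
        raise ValueError("fewer than 2 frequency bins inside the band")
    sd = data.std(axis=0)
    flagged = sd == 0
    z = (data - data.mean(axis=0)) / np.where(flagged, 1.0, sd)
    X = np.fft.rfft(z, axis=0)
    power = np.abs(X) ** 2 / n
    vals = np.mean(np.sqrt(power[in_band]), axis=0) * sd
    vals = np.where(flagged, 0.0, vals)
    if mask is None:
        mask = np.ones(vals.shape, bool)
    return MetricMap(vals, "alff", np.asarray(mask, bool), flagged)


_NEIGHBORHOODS = {
    7: lambda d: d <= 1,  # faces
    19: lambda d: d <= 2,  # faces + edges
    27: lambda d: d <= 3,  # full cube
}


def kcc(ranks: np.ndarray, tie_terms: np.ndarray | None = None) -> float:
    """Kendall's W of pre-ranked series: ``ranks`` is (m, n) over time n."""
    m, n = ranks.shape
    R = ranks.sum(axis=0)
    S = np.sum((R - m * (n + 1) / 2.0) ** 2)
    T = float(np.sum(tie_terms)) if tie_terms is not None else 0.0
    denom = m**2 * (n**3 - n) / 12.0 - m * T / 12.0
    return float(S / denom) if denom > 0 else 0.0


def _tie_term(x: np.ndarray) -> float:
    """Standard tie correction sum_j (t_j^3 - t_j) for one series."""
    _, counts = np.unique(x, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def reho_kcc(
    series, mask: np.ndarray, neighborhood: int = 27
) -> MetricMap:
    """Regional homogeneity: Kendall's W over each voxel's neighbourhood.

    Time series are ranked over time (average ranks for ties); for each
    in-mask centre voxel W is computed over the neighbourhood series
    (27, 19 or 7 voxels), truncated at the mask edge to the voxels actually
    present.  W lies in [0, 1].
    """
    data = _series_data(series)
    mask = np.asarray(mask, bool)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 volumes")
    if neighborhood not in _NEIGHBORHOODS:
        raise ValueError("neighborhood must be one of 7, 19, 27")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if _NEIGHBORHOODS[neighborhood](abs(dx) + abs(dy) + abs(dz)):
                    offs.append((dx, dy, dz))
    ranks = stats.rankdata(data, axis=0)  # average ranks for ties
    ranks[:, ~mask] = 0.0
    tie = np.zeros(mask.shape)
    flat = data.reshape(n, -1)
    tsel = np.nonzero(mask.ravel())[0]
    tie_flat = np.zeros(flat.shape[1])
    for i in tsel:
        tie_flat[i] = _tie_term(flat[:, i])
    tie = tie_flat.reshape(mask.shape)

    # neighbour sums via shifted accumulation
    R_sum = np.zeros((n,) + mask.shape)
    m_count = np.zeros(mask.shape)
    tie_sum = np.zeros(mask.shape)
    fm = mask.astype(float)
    for dx, dy, dz in offs:
        shifted_mask = np.roll(fm, (dx, dy, dz), axis=(0, 1, 2))
        shifted_ranks = np.roll(ranks, (dx, dy, dz), axis=(1, 2, 3))
        shifted_tie = np.roll(tie, (dx, dy, dz), axis=(0, 1, 2))
        # zero out wrap-around
        edge = np.ones(mask.shape, bool)
        for ax_i, d in enumerate((dx, dy, dz)):
            sl = [slice(None)] * 3
            if d == 1:
                sl[ax_i] = slice(0, 1)
                edge[tuple(sl)] = False
            elif d == -1:
                sl[ax_i] = slice(-1, None)
                edge[tuple(sl)] = False
        valid = shifted_mask * edge
        m_count += valid
        R_sum += shifted_ranks * valid[None]
        tie_sum += shifted_tie * valid
    m_count = np.where(mask, m_count, 1.0)
    S = np.sum((R_sum - m_count[None] * (n + 1) / 2.0) ** 2, axis=0)
    denom = m_count**2 * (n**3 - n) / 12.0 - m_count * tie_sum / 12.0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(denom > 0, S / np.where(denom > 0, denom, 1.0), 0.0)
    W = np.where(mask, np.clip(W, 0.0, 1.0), 0.0)
    return MetricMap(W, "reho", mask)


def fc_matrix(series, parcel_labels: np.ndarray) -> np.ndarray:
    """Pearson functional-connectivity matrix of parcel-mean time series.

    Labels > 0 define parcels; constant parcel series produce NaN rows
    (flagged by the NaN itself).  The matrix is symmetric with unit
    diagonal.
    """
    data = _series_data(series)
    labels = np.asarray(parcel_labels)
    ids = np.unique(labels[labels > 0])
    if ids.size < 2:
        raise ValueError("need at least 2 parcels")
    means = np.stack([data[:, labels == i].mean(axis=1) for i in ids])
    sd = means.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(means)
    fc[np.isnan(fc) & ~np.isnan(fc.T)] = np.nan
    np.fill_diagonal(fc, 1.0)
    return fc


def compare_fc(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute difference of the off-diagonal connectivity entries."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("FC matrices must share a shape")
    off = ~np.eye(a.shape[0], dtype=bool)
    return float(np.nanmean(np.abs(a - b)[off]))
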