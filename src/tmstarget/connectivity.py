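"""BOLD time-series handling and lazy E-field-weighted seed maps.

The voxel-to-voxel correlation matrix is never materialized: for standardized
data Z (voxels x time, zero mean, unit population variance per row) and
sum-normalized weights w, the weighted average of correlation rows is

    S = Z (Z^T w) / T

which is exact (Pearson r(v, u) = z_v . z_u / T, including r(v, v) = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import signal

from .efield import EFieldWeights, GrayMatterMask

__all__ = [
    "TimeSeries",
    "BrainMap",
    "regress_nuisance",
    "bandpass",
    "concatenate_runs",
    "crop_duration",
    "standardize",
    "weighted_seed_map",
    "load_run",
    "effective_sample_size",
]

DEFAULT_TR = 0.72  # seconds; HCP-style acquisition


@dataclass
class TimeSeries:
    """In-mask voxels x timepoints matrix with its repetition time (s)."""

    data: np.ndarray
    tr_seconds: float = DEFAULT_TR

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("time series must be voxels x timepoints with >= 2 volumes")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class BrainMap:
    """One scalar per in-mask voxel, with a semantics tag."""

    values: np.ndarray
    tag: str = "seed"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("BrainMap values must be one scalar per voxel")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BrainMap values must be finite")

    def to_nifti(self, mask: GrayMatterMask) -> nib.Nifti1Image:
        return mask.to_nifti(self.values)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image | str | Path, mask: GrayMatterMask,
                   tag: str = "seed") -> "BrainMap":
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img))
        data = np.asarray(img.dataobj, dtype=float)
        return cls(values=data.reshape(-1)[mask.indices], tag=tag)


def load_run(path: str | Path, mask: GrayMatterMask,
             tr_seconds: float = DEFAULT_TR) -> TimeSeries:
    """Read a 4-D NIfTI run into mask-ordered voxels x timepoints."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D functional image")
    flat = data.reshape(-1, data.shape[3])
    return TimeSeries(data=flat[mask.indices].astype(np.float64), tr_seconds=tr_seconds)


def regress_nuisance(ts: TimeSeries, nuisance_signals: np.ndarray) -> TimeSeries:
    """Per-voxel OLS residuals against an [intercept | nuisance] design."""
    nuis = np.atleast_2d(np.asarray(nuisance_signals, dtype=float))
    if nuis.shape[1] != ts.n_volumes:
        raise ValueError("nuisance rows must match the number of timepoints")
    design = np.column_stack([np.ones(ts.n_volumes), nuis.T])
    # name collinear columns via rank-revealing QR on the centered design
    r_diag = np.abs(np.diag(np.linalg.qr(design, mode="r")))
    bad = np.flatnonzero(r_diag < 1e-10 * max(r_diag.max(), 1.0))
    if bad.size:
        names = ["intercept"] + [f"nuisance[{k}]" for k in range(nuis.shape[0])]
        raise ValueError(
            "rank-deficient nuisance design; collinear columns: "
            + ", ".join(names[b] for b in bad))
    beta, *_ = np.linalg.lstsq(design, ts.data.T, rcond=None)
    resid = ts.data - (design @ beta).T
    return TimeSeries(data=resid, tr_seconds=ts.tr_seconds)


def _band_sos(low_hz: float, high_hz: float, tr_seconds: float, order: int = 4):
    nyquist = 0.5 / tr_seconds
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for TR {tr_seconds} s "
            f"(Nyquist {nyquist:.4g} Hz)")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass",
                         fs=1.0 / tr_seconds, output="sos")


def bandpass(ts: TimeSeries, low_hz: float = 0.01, high_hz: float = 0.1) -> TimeSeries:
    """Zero-phase 4th-order Butterworth band-pass, applied per voxel.

    The reflect padding is sized to the low-frequency band edge (three
    periods) rather than scipy's default few samples, which is far too short
    for infra-slow cut-offs and would leave edge transients.
    """
    sos = _band_sos(low_hz, high_hz, ts.tr_seconds)
    padlen = min(ts.n_volumes - 2,
                 int(round(3.0 / (low_hz * ts.tr_seconds))))
    out = signal.sosfiltfilt(sos, ts.data, axis=1, padlen=max(padlen, 0))
    return TimeSeries(data=out, tr_seconds=ts.tr_seconds)


def concatenate_runs(runs: list[TimeSeries]) -> TimeSeries:
    """Concatenate runs along the time axis, in the given order."""
    if not runs:
        raise ValueError("no runs to concatenate")
    v0, tr0 = runs[0].n_voxels, runs[0].tr_seconds
    for r in runs[1:]:
        if r.n_voxels != v0:
            raise ValueError("runs have mismatched voxel counts")
        if abs(r.tr_seconds - tr0) > 1e-9:
            raise ValueError("runs have mismatched repetition times")
    if len(runs) == 1:
        return runs[0]
    return TimeSeries(data=np.concatenate([r.data for r in runs], axis=1), tr_seconds=tr0)


def crop_duration(ts: TimeSeries, minutes: float, offset_volumes: int = 0) -> TimeSeries:
    """Keep the first ``floor(minutes * 60 / tr)`` volumes (after ``offset_volumes``)."""
    n = int(np.floor(minutes * 60.0 / ts.tr_seconds))
    if n < 2:
        raise ValueError(f"requested duration {minutes} min yields {n} volumes")
    if offset_volumes + n > ts.n_volumes:
        raise ValueError(
            f"requested {n} volumes from offset {offset_volumes}, "
            f"only {ts.n_volumes} available")
    return TimeSeries(data=ts.data[:, offset_volumes:offset_volumes + n],
                      tr_seconds=ts.tr_seconds)


def standardize(ts: TimeSeries) -> tuple[TimeSeries, np.ndarray]:
    """Zero-mean, unit-population-variance rows; constant voxels flagged.

    Constant voxels are zeroed (and reported) so they contribute nothing to
    downstream correlation sums; all-constant input is an error.
    """
    data = ts.data.astype(np.float64, copy=True)
    data -= data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1)  # population sd, per voxel
    scale_ref = max(float(np.abs(ts.data).max()), 1.0)
    constant = np.flatnonzero(sd <= 1e-12 * scale_ref)
    if constant.size == ts.n_voxels:
        raise ValueError("all voxels are constant; nothing to standardize")
    ok = np.setdiff1d(np.arange(ts.n_voxels), constant)
    data[ok] /= sd[ok, None]
    data[constant] = 0.0
    return TimeSeries(data=data, tr_seconds=ts.tr_seconds), constant


def weighted_seed_map(ts_standardized: TimeSeries, weights: EFieldWeights,
                      tag: str = "seed") -> BrainMap:
    """E-field-weighted average of voxel correlation rows, computed lazily.

    Exactly equals ``sum_v w~_v r(v, .)`` with sum-normalized weights w~ and
    self-correlations r(v, v) = 1 included, without forming the V x V matrix.
    """
    Z = ts_standardized.data
    w = weights.dense(Z.shape[0])
    # support must consist of standardized (non-constant) voxels
    sup_var = np.einsum("ij,ij->i", Z[weights.support], Z[weights.support]) / Z.shape[1]
    live = sup_var > 0.5
    if not live.any():
        raise ValueError("E-field support contains no non-constant voxels")
    if not live.all():
        w = np.zeros_like(w)
        w[weights.support[live]] = weights.values[live]
    w = w / w.sum()
    seed = Z.T @ w
    values = (Z @ seed) / Z.shape[1]
    return BrainMap(values=values, tag=tag)


def effective_sample_size(x: np.ndarray, max_lag: int | None = None) -> float:
    """Effective number of independent samples of an autocorrelated series.

    Uses the Bartlett variance inflation for the sample correlation of two
    series sharing this autocorrelation: T_eff = T / sum_k rho(k)^2 over all
    lags (k = 0 counted once, others twice).
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    T = len(x)
    if max_lag is None:
        max_lag = min(T - 2, 300)
    denom = float(x @ x)
    if denom <= 0:
        raise ValueError("constant series has no effective sample size")
    rho = np.array([x[:T - k] @ x[k:] / denom for k in range(1, max_lag + 1)])
    inflation = 1.0 + 2.0 * float(np.sum(rho**2))
    return T / inflation
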