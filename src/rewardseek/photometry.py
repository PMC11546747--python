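"""Fiber-photometry dopamine-signal processing.

Turns a raw two-channel recording — a dopamine-sensitive channel (470 nm
excitation) plus an isosbestic reference channel (405 nm) that reports
motion and bleaching but not sensor binding — into artifact-corrected
ΔF/F traces, per-trial z-scored peri-event histograms (PSTHs), window
metrics (trapezoidal AUC, peak), and catalogs of spontaneous transients
selected by topographic peak prominence.

Processing conventions
----------------------
* Artifact removal: the isosbestic channel is scaled and offset by
  ordinary least squares onto the signal channel over the full session;
  ΔF/F = (signal − fitted_iso) / fitted_iso (a subtraction-only mode is
  available).
* Optional zero-phase Butterworth low-pass (default 6 Hz, order 6) before
  regression.
* PSTH z-scoring is per trial against that trial's own baseline window
  (default −4 to −2 s relative to cue onset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps


@dataclass
class PhotometryRecording:
    """Two aligned fluorescence channels with sampling rate.

    ``ground_truth`` carries planted-transient metadata when the recording
    comes from the synthetic generator; it is ignored by the processing
    stages.
    """

    signal_470: np.ndarray
    iso_405: np.ndarray
    fs: float
    t0: float = 0.0
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.signal_470 = np.asarray(self.signal_470, dtype=float)
        self.iso_405 = np.asarray(self.iso_405, dtype=float)
        if self.signal_470.shape != self.iso_405.shape:
            raise ValueError("channels must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.signal_470)) / self.fs

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("signal_470", data=self.signal_470)
            f.create_dataset("iso_405", data=self.iso_405)
            f.attrs["fs_hz"] = self.fs
            f.attrs["t0_s"] = self.t0

    @classmethod
    def from_hdf5(cls, path) -> "PhotometryRecording":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                signal_470=f["signal_470"][:],
                iso_405=f["iso_405"][:],
                fs=float(f.attrs["fs_hz"]),
                t0=float(f.attrs.get("t0_s", 0.0)),
            )


@dataclass(frozen=True)
class WindowSpec:
    """Half-open peri-event analysis windows, seconds relative to cue onset."""

    baseline: tuple[float, float] = (-4.0, -2.0)
    cue: tuple[float, float] = (0.0, 2.0)
    reward: tuple[float, float] = (2.0, 7.0)
    psth_span: tuple[float, float] = (-4.0, 8.0)

    def __post_init__(self) -> None:
        lo, hi = self.psth_span
        for name in ("baseline", "cue", "reward"):
            a, b = getattr(self, name)
            if not (a < b):
                raise ValueError(f"{name} window must have start < end")
            if a < lo or b > hi:
                raise ValueError(f"{name} window must lie within psth_span")
        if self.baseline[1] > self.cue[0]:
            raise ValueError("baseline window must precede the cue window")


@dataclass
class EventPSTH:
    """Trial × time matrix of per-trial baseline-z-scored signal."""

    z: np.ndarray  # (n_trials, n_samples)
    time: np.ndarray  # seconds relative to the aligning event
    baseline_mean: np.ndarray  # per trial, in trace units
    baseline_sd: np.ndarray
    event_times: np.ndarray  # session times of the retained events

    @property
    def mean_trace(self) -> np.ndarray:
        return self.z.mean(axis=0)


def lowpass(trace: np.ndarray, fs: float, cutoff: float = 6.0, order: int = 6) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward, no phase lag)."""
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def detrend_isosbestic(
    rec: PhotometryRecording,
    lowpass_hz: float | None = 6.0,
    filter_order: int = 6,
    mode: str = "ratio",
) -> np.ndarray:
    """Remove shared motion/bleaching artifact using the isosbestic channel.

    Fits ``iso_405`` onto ``signal_470`` by OLS over the full session and
    returns ΔF/F = (signal − fit) / fit (``mode="ratio"``) or the plain
    residual (``mode="subtract"``).  An optional zero-phase low-pass is
    applied to both channels first.

    Raises
    ------
    ValueError
        If the isosbestic channel has zero variance (degenerate regression).
    """
    sig = np.asarray(rec.signal_470, dtype=float)
    iso = np.asarray(rec.iso_405, dtype=float)
    if len(sig) < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(sig)) and np.all(np.isfinite(iso))):
        raise ValueError("channels must be finite")
    if lowpass_hz is not None:
        sig = lowpass(sig, rec.fs, lowpass_hz, filter_order)
        iso = lowpass(iso, rec.fs, lowpass_hz, filter_order)
    var = iso.var()
    if var == 0:
        raise ValueError("isosbestic channel is constant: degenerate regression")
    slope = np.cov(iso, sig, bias=True)[0, 1] / var
    intercept = sig.mean() - slope * iso.mean()
    fitted = slope * iso + intercept
    resid = sig - fitted
    if mode == "subtract":
        return resid
    if mode == "ratio":
        if np.any(fitted <= 0):
            warnings.warn(
                "fitted isosbestic baseline non-positive somewhere; "
                "ratio ΔF/F is unreliable there",
                stacklevel=2,
            )
        return resid / fitted
    raise ValueError(f"unknown mode {mode!r}")


def event_psth(
    trace: np.ndarray,
    fs: float,
    events: np.ndarray,
    windows: WindowSpec | None = None,
    t0: float = 0.0,
) -> EventPSTH:
    """Event-aligned PSTH, z-scored per trial against its baseline window.

    For each event time, samples in ``windows.psth_span`` are extracted and
    z-scored as (x − m)/s where m, s are the mean and SD of that trial's
    baseline-window samples.  Events without full span coverage are dropped
    with a warning.
    """
    windows = windows or WindowSpec()
    trace = np.asarray(trace, dtype=float)
    events = np.atleast_1d(np.asarray(events, dtype=float))
    lo, hi = windows.psth_span
    n_rel = int(round((hi - lo) * fs))
    rel = lo + np.arange(n_rel) / fs
    b0, b1 = windows.baseline
    bmask = (rel >= b0) & (rel < b1)

    rows, means, sds, kept = [], [], [], []
    for j, ev in enumerate(events):
        i0 = int(round((ev + lo - t0) * fs))
        if i0 < 0 or i0 + n_rel > len(trace):
            warnings.warn(f"event {j} at {ev:.3f}s lacks full PSTH span; dropped", stacklevel=2)
            continue
        seg = trace[i0 : i0 + n_rel]
        m = seg[bmask].mean()
        s = seg[bmask].std()
        if s == 0:
            raise ValueError(f"zero baseline variance for trial {j} (event at {ev:.3f}s)")
        rows.append((seg - m) / s)
        means.append(m)
        sds.append(s)
        kept.append(ev)
    if not rows:
        raise ValueError("no event had full PSTH span coverage")
    return EventPSTH(
        z=np.asarray(rows),
        time=rel,
        baseline_mean=np.asarray(means),
        baseline_sd=np.asarray(sds),
        event_times=np.asarray(kept),
    )


def trapezoid_window(time: np.ndarray, y: np.ndarray, window: tuple[float, float]) -> float:
    """Trapezoidal integral of ``y(time)`` over ``window``.

    Endpoints are included by linear interpolation so a constant trace of 1
    over a 2-s window integrates to exactly 2.0 regardless of bin phase.
    """
    a, b = window
    if not a < b:
        raise ValueError("window must have start < end")
    time = np.asarray(time, dtype=float)
    y = np.asarray(y, dtype=float)
    if a < time[0] - 1e-9 or b > time[-1] + 1e-9:
        raise ValueError(f"window {window} outside trace span [{time[0]}, {time[-1]}]")
    inner = (time > a) & (time < b)
    tt = np.concatenate(([a], time[inner], [b]))
    yy = np.concatenate(([np.interp(a, time, y)], y[inner], [np.interp(b, time, y)]))
    return float(np.trapezoid(yy, tt))


def window_metrics(psth: EventPSTH, window: tuple[float, float]) -> dict:
    """Trapezoidal AUC (z·s) and peak (z) of the trial-averaged trace."""
    mean = psth.mean_trace
    auc = trapezoid_window(psth.time, mean, window)
    a, b = window
    mask = (psth.time >= a) & (psth.time <= b)
    if not mask.any():
        raise ValueError("empty window")
    return {"auc": auc, "peak": float(mean[mask].max())}


def detect_transients(
    trace: np.ndarray,
    fs: float,
    min_prominence: float = 1.0,
    t0: float = 0.0,
) -> pd.DataFrame:
    """Catalog local maxima with topographic prominence ≥ ``min_prominence``.

    Units of the threshold follow the trace's units (% ΔF/F0 for
    spontaneous-transient analysis, z for PSTH-domain analysis).  Returns a
    DataFrame with columns ``time_s``, ``amplitude``, ``prominence``.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    idx, props = sps.find_peaks(trace, prominence=min_prominence)
    return pd.DataFrame(
        {
            "time_s": t0 + idx / fs,
            "amplitude": trace[idx],
            "prominence": props["prominences"],
        }
    )
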