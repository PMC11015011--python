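"""Fluorescence preprocessing: neuropil correction, QC, spikes, decay fits.

The chain turns raw ROI / local-neuropil fluorescence into a QC-filtered
binary raster: neuropil-normalized signal, PSNR-based ROI selection,
median->min->max moving filtering, AR(1) sparse nonnegative deconvolution,
and PSNR-proportional binarization.  A separate set of routines detects
calcium-transient decays and fits single-exponential decay constants,
splitting them by stimulus condition (spontaneous / right before the
suppressing stimulus / during it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import curve_fit

from .synthgen import Raster, StimulusSchedule, wrap_orientation_diff

NEUROPIL_EPS = 1e-6
# Lower bound for the binarization threshold.  The median->min->max filter is
# a morphological opening that flattens each transient peak into a plateau of
# one window length; exact AR(1) deconvolution of a plateau emits residual
# increments of order (1 - gamma) x fluorescence (~1.4% per frame at GCaMP6s
# kinetics).  The floor rejects those artifacts while staying an order of
# magnitude below a single-event amplitude.
EPSILON_FLOOR = 0.01


@dataclass
class TraceSet:
    """Per-ROI raw and neuropil fluorescence with a common frame clock."""

    f_roi: np.ndarray  # (n_rois, n_frames)
    f_neuropil: np.ndarray
    frame_period_s: float
    f_filtered: np.ndarray | None = None
    roi_positions: np.ndarray | None = None  # (n_rois, 3): x, y, plane

    def __post_init__(self) -> None:
        self.f_roi = np.atleast_2d(np.asarray(self.f_roi, dtype=float))
        self.f_neuropil = np.atleast_2d(np.asarray(self.f_neuropil, dtype=float))
        if self.f_roi.shape != self.f_neuropil.shape:
            raise ValueError("F_ROI and F_neuropil shapes differ")
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be positive")

    @property
    def n_rois(self) -> int:
        return self.f_roi.shape[0]

    @property
    def n_frames(self) -> int:
        return self.f_roi.shape[1]


@dataclass
class QCRecord:
    """Per-ROI PSNR, pass flag, and binarization threshold."""

    psnr_db: np.ndarray
    passed: np.ndarray
    threshold: np.ndarray
    psnr_min: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": np.arange(len(self.psnr_db)),
                "psnr_db": self.psnr_db,
                "passed": self.passed,
                "threshold": self.threshold,
            }
        )


@dataclass
class DecayFit:
    a: float
    tau_s: float
    fit_rmse: float
    window: tuple[int, int]
    at_bounds: bool = False


def neuropil_correct(f_roi: np.ndarray, f_neuropil: np.ndarray) -> np.ndarray:
    """Neuropil-normalized signal, (F_ROI - F_neuropil) / F_neuropil."""
    f_roi = np.asarray(f_roi, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_roi.shape != f_neuropil.shape:
        raise ValueError("series lengths differ")
    small = np.abs(f_neuropil) < NEUROPIL_EPS
    if small.any():
        bad = np.atleast_2d(small).any(axis=-1)
        rois = np.flatnonzero(np.atleast_1d(bad))
        raise ZeroDivisionError(
            f"neuropil signal within {NEUROPIL_EPS} of zero for ROI(s) {rois.tolist()}"
        )
    return (f_roi - f_neuropil) / f_neuropil


def compute_psnr(f_roi: np.ndarray, f_neuropil: np.ndarray) -> float:
    """Peak SNR in dB: 20 log10(max(F_ROI - F_neuropil) / std(F_neuropil)).

    A nonpositive peak difference yields -inf (the ROI then fails QC).
    """
    f_roi = np.asarray(f_roi, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    sd = float(np.std(f_neuropil))
    if sd == 0.0:
        raise ValueError("neuropil has zero variance; PSNR undefined")
    peak = float(np.max(f_roi - f_neuropil))
    if peak <= 0.0:
        return -np.inf
    return 20.0 * np.log10(peak / sd)


def binarization_threshold(psnr_db: float, epsilon_floor: float = EPSILON_FLOOR) -> float:
    """PSNR-proportional spike threshold, floored so it never reaches zero."""
    return max(0.04 - 0.002 * psnr_db, epsilon_floor)


def select_rois(
    traces: TraceSet, psnr_min: float = 10.0, strict: bool = True
) -> tuple[TraceSet, QCRecord]:
    """Keep ROIs whose PSNR exceeds ``psnr_min`` dB (strict > by default)."""
    psnr = np.array(
        [compute_psnr(traces.f_roi[i], traces.f_neuropil[i]) for i in range(traces.n_rois)]
    )
    passed = psnr > psnr_min if strict else psnr >= psnr_min
    threshold = np.array([binarization_threshold(p) if np.isfinite(p) else np.nan for p in psnr])
    record = QCRecord(psnr_db=psnr, passed=passed, threshold=threshold, psnr_min=psnr_min)
    if not passed.any():
        raise ValueError(f"no ROI exceeds {psnr_min} dB PSNR; empty cohort")
    kept = TraceSet(
        f_roi=traces.f_roi[passed],
        f_neuropil=traces.f_neuropil[passed],
        frame_period_s=traces.frame_period_s,
        roi_positions=None if traces.roi_positions is None else traces.roi_positions[passed],
    )
    return kept, record


def _odd_window_frames(window_s: float, frame_period_s: float) -> int:
    w = int(round(window_s / frame_period_s))
    return max(w + (w % 2 == 0), 1)


def _moving(x: np.ndarray, w: int, func) -> np.ndarray:
    """Centered moving statistic with window truncation at the edges."""
    half = w // 2
    padded = np.concatenate([np.full(half, np.nan), x, np.full(half, np.nan)])
    windows = sliding_window_view(padded, w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return func(windows, axis=-1)


def smooth_trace(
    f_filtered: np.ndarray, window_s: float = 0.5, frame_period_s: float = 0.081
) -> np.ndarray:
    """Sequential moving median, minimum, and maximum of the same window.

    The min-then-max pair is a morphological opening: it removes positive
    blips narrower than the window while leaving wider transients intact.
    Window length is rounded to an odd frame count; edges use truncated
    windows.  Accepts a single trace or a (n_rois, n_frames) array.
    """
    if window_s < frame_period_s:
        raise ValueError("window_s must be at least one frame period")
    x = np.asarray(f_filtered, dtype=float)
    if x.ndim == 1:
        return smooth_trace(x[None, :], window_s, frame_period_s)[0]
    w = _odd_window_frames(window_s, frame_period_s)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        y = _moving(x[i], w, np.nanmedian)
        y = _moving(y, w, np.nanmin)
        y = _moving(y, w, np.nanmax)
        out[i] = y
    return out


def infer_spikes(smoothed: np.ndarray, gamma: float, lam: float = 0.0) -> np.ndarray:
    """Sparse nonnegative deconvolution under an AR(1) calcium model.

    Solves  min_c 1/2 ||c - y||^2 + lam * sum(s)  subject to
    s_t = c_t - gamma c_{t-1} >= 0  (and s_0 = c_0 >= 0), via the
    pool-adjacent-violators style online algorithm: running pools carry the
    optimal constant-onset solution and are merged backwards whenever the
    nonnegativity constraint between adjacent pools is violated.
    Returns the spike series s >= 0.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    y = np.asarray(smoothed, dtype=float)
    if y.ndim == 2:
        return np.vstack([infer_spikes(row, gamma, lam) for row in y])
    T = y.size
    if T == 0:
        return y.copy()
    # L1 penalty folds into the target: each c_t carries weight (1-gamma),
    # except the last sample which carries weight 1.
    ytil = y - lam * (1.0 - gamma)
    ytil[-1] = y[-1] - lam

    # pools: [value, weight, start, length]
    v = np.empty(T)
    w = np.empty(T)
    start = np.empty(T, dtype=int)
    length = np.empty(T, dtype=int)
    n = 0
    for t in range(T):
        v[n], w[n], start[n], length[n] = ytil[t], 1.0, t, 1
        n += 1
        while n > 1 and v[n - 1] / w[n - 1] < (gamma ** length[n - 2]) * v[n - 2] / w[n - 2]:
            g = gamma ** length[n - 2]
            v[n - 2] += g * v[n - 1]
            w[n - 2] += g * g * w[n - 1]
            length[n - 2] += length[n - 1]
            n -= 1

    c = np.empty(T)
    for i in range(n):
        base = max(v[i] / w[i], 0.0)
        sl = slice(start[i], start[i] + length[i])
        c[sl] = base * gamma ** np.arange(length[i])
    s = np.empty(T)
    s[0] = c[0]
    s[1:] = c[1:] - gamma * c[:-1]
    return np.clip(s, 0.0, None)


def estimate_noise_sd(trace: np.ndarray, smoothed: np.ndarray | None = None) -> float:
    """Robust noise scale (MAD-based).

    With ``smoothed`` given, uses the high-pass residual trace - smoothed
    (the smoothing removes it, so the residual is essentially noise);
    otherwise falls back to first differences.
    """
    x = np.asarray(trace, dtype=float)
    if smoothed is not None:
        d = x - np.asarray(smoothed, dtype=float)
    else:
        d = np.diff(x) / np.sqrt(2.0)
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))) / 0.6745)


def binarize_spikes(
    spike_series: np.ndarray, psnr_db: float, epsilon_floor: float = EPSILON_FLOOR
) -> np.ndarray:
    """Binary events: spike rate above the PSNR-proportional threshold."""
    if not np.isfinite(psnr_db):
        raise ValueError("psnr_db must be finite")
    thr = binarization_threshold(psnr_db, epsilon_floor)
    return (np.asarray(spike_series, dtype=float) > thr).astype(np.uint8)


def build_raster(binary_rows: list[np.ndarray] | np.ndarray, frame_period_s: float) -> Raster:
    """Stack per-ROI binary series into an N x F raster."""
    rows = list(binary_rows)
    if len(rows) == 0:
        raise ValueError("no binary series supplied; cannot build a raster")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged series lengths {sorted(lengths)}")
    return Raster(np.vstack(rows), frame_period_s)


def preprocess(
    traces: TraceSet,
    psnr_min: float = 10.0,
    window_s: float = 0.5,
    tau_indicator_s: float = 5.8,
    lam_scale: float = 1.0,
) -> tuple[Raster, QCRecord, TraceSet]:
    """Full chain: correct -> QC -> smooth -> deconvolve -> binarize -> raster.

    gamma is exp(-frame_period / tau_indicator); the L1 weight is
    lam_scale x the per-trace MAD noise estimate of the smoothed signal.
    Returns the raster over passed ROIs, the QC record over all ROIs, and the
    QC-filtered TraceSet with ``f_filtered`` populated.
    """
    kept, qc = select_rois(traces, psnr_min=psnr_min)
    filt = neuropil_correct(kept.f_roi, kept.f_neuropil)
    kept.f_filtered = filt
    smoothed = smooth_trace(filt, window_s=window_s, frame_period_s=kept.frame_period_s)
    gamma = float(np.exp(-kept.frame_period_s / tau_indicator_s))
    psnr_passed = qc.psnr_db[qc.passed]
    rows = []
    guard = 2.0 * (1.0 - gamma)  # opening-plateau artifact level, per unit fluorescence
    for i in range(kept.n_rois):
        lam = lam_scale * estimate_noise_sd(filt[i], smoothed[i])
        s = infer_spikes(smoothed[i], gamma=gamma, lam=lam)
        # The min->max opening flattens each transient peak into a plateau
        # whose exact AR(1) deconvolution leaks (1 - gamma) x fluorescence
        # per frame; suppress increments at that artifact scale.
        s = np.where(s > guard * np.clip(smoothed[i], 0.0, None), s, 0.0)
        rows.append(binarize_spikes(s, psnr_passed[i]))
    return build_raster(rows, kept.frame_period_s), qc, kept


def fit_decay(
    trace: np.ndarray,
    window: tuple[int, int],
    frame_period_s: float,
    tau_bounds: tuple[float, float] = (0.05, 20.0),
) -> DecayFit:
    """Nonlinear least-squares fit of a * exp(-t / tau) on a windowed segment.

    t is measured from the window start.  A fit that lands on a tau bound is
    flagged via ``at_bounds`` rather than silently returned.
    """
    lo, hi = window
    seg = np.asarray(trace, dtype=float)[lo:hi]
    if seg.size < 3:
        raise ValueError("decay window must hold at least 3 samples")
    if seg[0] <= 0:
        raise ValueError("trace must be positive at the window start")
    t = np.arange(seg.size) * frame_period_s
    tau_min, tau_max = tau_bounds

    # log-linear start; fall back to a mid-range tau if the segment dips <= 0
    pos = seg > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(seg[pos]), 1)
        tau0 = np.clip(-1.0 / slope if slope < 0 else tau_max / 2, tau_min, tau_max)
        a0 = float(np.clip(np.exp(intercept), 1e-12, None))
    else:
        tau0, a0 = (tau_min + tau_max) / 2, max(seg[0], 1e-12)

    def model(tt, a, tau):
        return a * np.exp(-tt / tau)

    popt, _ = curve_fit(
        model,
        t,
        seg,
        p0=[a0, float(tau0)],
        bounds=([0.0, tau_min], [np.inf, tau_max]),
        maxfev=10000,
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    a, tau = float(popt[0]), float(popt[1])
    rmse = float(np.sqrt(np.mean((model(t, a, tau) - seg) ** 2)))
    rel = 1e-6 * (tau_max - tau_min)
    at_bounds = tau <= tau_min + rel or tau >= tau_max - rel
    return DecayFit(a=a, tau_s=tau, fit_rmse=rmse, window=(lo, hi), at_bounds=at_bounds)


def detect_decays(
    trace: np.ndarray,
    frame_period_s: float,
    k_mad: float = 3.0,
    min_decay_s: float = 0.5,
    max_window_s: float = 2.0,
    rise_tol: float = 0.05,
) -> list[tuple[int, int]]:
    """Candidate decay windows: peaks above k x MAD followed by a falling run.

    A peak qualifies if the signal exceeds median + k_mad x MAD and then stays
    non-increasing (within rise_tol x peak) for at least min_decay_s; the
    window runs from the peak to the next rise or max_window_s, whichever
    comes first.
    """
    x = np.asarray(trace, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med)) / 0.6745
    height = med + k_mad * (mad if mad > 0 else np.std(x) + 1e-12)
    min_frames = max(int(round(min_decay_s / frame_period_s)), 3)
    max_frames = int(round(max_window_s / frame_period_s))

    windows: list[tuple[int, int]] = []
    T = x.size
    t = 1
    while t < T - 1:
        if x[t] >= height and x[t] >= x[t - 1] and x[t] >= x[t + 1]:
            end = t + 1
            tol = rise_tol * x[t]
            while end < T and end - t < max_frames and x[end] <= x[end - 1] + tol:
                end += 1
            if end - t >= min_frames:
                windows.append((t, end))
                t = end
                continue
        t += 1
    return windows


def _classify_window(
    win: tuple[int, int], pref_trials: list[tuple[int, int]], stim_mask: np.ndarray
) -> tuple[str | None, tuple[int, int]]:
    """Assign a decay window to spontaneous / pre-onset / during conditions.

    Pre-onset: the peak precedes a suppressing-stimulus onset and the window
    is clipped to end at that onset.  During: the window lies fully inside a
    suppressing trial.  Spontaneous: no overlap with any stimulus.
    """
    lo, hi = win
    for onset, end in pref_trials:
        if lo >= onset and hi <= end:
            return "during", (lo, hi)
        if lo < onset < hi:
            return "pre_onset", (lo, onset)
    if not stim_mask[lo:hi].any():
        return "spontaneous", (lo, hi)
    return None, (lo, hi)


def decay_by_condition(
    traces: TraceSet,
    schedule: StimulusSchedule | None,
    suppressing_orientation_deg: np.ndarray,
    k_mad: float = 3.0,
    min_samples: int = 5,
    tau_bounds: tuple[float, float] = (0.05, 20.0),
) -> pd.DataFrame:
    """Per-neuron decay constants by condition for suppression analysis.

    ``suppressing_orientation_deg[i]`` is the orientation whose trials
    suppress neuron i (NaN when none, e.g. a neuron in no offsemble).
    Transients are detected on the neuropil-corrected trace, windows
    classified against that neuron's suppressing trials, and each decay
    fitted.  For suppressed neurons, trial onsets where the signal is already
    elevated and falling are also taken as "during" windows, since
    suppression accelerates an ongoing decay rather than creating a peak.

    Returns a tidy frame (neuron_id, condition, tau_s, a, rmse, n) of
    per-window fits; conditions with no detected transients are simply
    absent.
    """
    filt = traces.f_filtered
    if filt is None:
        filt = neuropil_correct(traces.f_roi, traces.f_neuropil)
    dt = traces.frame_period_s
    F = filt.shape[1]
    if schedule is not None:
        stim_mask = schedule.stimulus_mask()
    else:
        stim_mask = np.zeros(F, dtype=bool)

    rows = []
    for i in range(filt.shape[0]):
        x = filt[i]
        pref = suppressing_orientation_deg[i]
        pref_trials: list[tuple[int, int]] = []
        if schedule is not None and np.isfinite(pref):
            for tr in schedule.trials:
                if wrap_orientation_diff(tr.orientation_deg - pref) == 0.0:
                    pref_trials.append((tr.onset_frame, tr.onset_frame + tr.duration_frames))

        windows = [(w, None) for w in detect_decays(x, dt, k_mad=k_mad)]
        # Suppression-onset windows: elevated, falling signal at trial onset.
        med = np.median(x)
        mad = np.median(np.abs(x - med)) / 0.6745
        height = med + k_mad * (mad if mad > 0 else np.std(x) + 1e-12)
        for onset, end in pref_trials:
            if 0 < onset < F and x[onset] >= height and x[onset] <= x[onset - 1] * 1.05:
                windows.append(((onset, end), "during"))

        for (win, forced) in windows:
            cond, clipped = (forced, win) if forced else _classify_window(
                win, pref_trials, stim_mask
            )
            lo, hi = clipped
            if cond is None or hi - lo < min_samples or x[lo] <= 0:
                continue
            try:
                fit = fit_decay(x, (lo, hi), dt, tau_bounds=tau_bounds)
            except (ValueError, RuntimeError):
                continue
            if fit.at_bounds:
                continue
            rows.append(
                {
                    "neuron_id": i,
                    "condition": cond,
                    "tau_s": fit.tau_s,
                    "a": fit.a,
                    "rmse": fit.fit_rmse,
                    "n": hi - lo,
                }
            )
    return pd.DataFrame(rows, columns=["neuron_id", "condition", "tau_s", "a", "rmse", "n"])


def condition_means(decays: pd.DataFrame) -> pd.Series:
    """Cohort mean tau per condition (mean of per-neuron means)."""
    if decays.empty:
        return pd.Series(dtype=float)
    per_neuron = decays.groupby(["condition", "neuron_id"])["tau_s"].mean()
    return per_neuron.groupby("condition").mean()
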