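"""Trial responses, orientation selectivity, tuning curves, response timing.

Units can be single neurons (binary spiking), ensembles (binary occurrence
signals), or member groups (fraction of active members per frame).  A trial
response is the mean activity over the stimulus window, in [0, 1].
Orientation selectivity is 1 - circular variance with doubled angles;
significance comes from a one-sample Hotelling t2 test of the
response-weighted orientation vectors against zero; tuning width from a
bounded Gaussian fit with wrapped angular distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import f as f_dist
from scipy.stats import ttest_ind

from .synthgen import Raster, StimulusSchedule, wrap_orientation_diff

GROUP_ONSEMBLE = "onsemble"
GROUP_OFFSEMBLE = "offsemble"
GROUP_ENSEMBLE_DAGGER = "ensemble_dagger"
GROUP_NONPARTICIPANT_TUNED = "nonparticipant_tuned"


@dataclass
class TuningCurve:
    a: float
    theta_pref_deg: float
    sigma_deg: float
    fit_rss: float
    at_bounds: bool

    def __call__(self, theta_deg: np.ndarray | float) -> np.ndarray | float:
        d = wrap_orientation_diff(np.asarray(theta_deg) - self.theta_pref_deg)
        return self.a * np.exp(-(d**2) / (2.0 * self.sigma_deg**2))


@dataclass
class TuningResult:
    osi: float
    theta_pref_deg: float
    hotelling_p: float
    significant: bool
    curve: TuningCurve | None


def group_activity(
    raster: Raster,
    members: dict[str, np.ndarray],
    group: str,
) -> np.ndarray:
    """Fraction-of-members activity series for a participation group.

    For onsemble / offsemble / nonparticipant_tuned: the mean of the member
    binary signals per frame.  For ensemble_dagger: active onsemble members
    plus inactive offsemble members over the total on+off member count — the
    fraction of ensemble neurons participating in the pattern.
    """
    x = raster.spikes.astype(bool)
    if group == GROUP_ENSEMBLE_DAGGER:
        on = np.asarray(members[GROUP_ONSEMBLE], dtype=int)
        off = np.asarray(members[GROUP_OFFSEMBLE], dtype=int)
        if on.size + off.size == 0:
            raise ValueError("ensemble_dagger needs onsemble or offsemble members")
        active_on = x[on].sum(axis=0) if on.size else 0
        inactive_off = (~x[off]).sum(axis=0) if off.size else 0
        return (active_on + inactive_off) / (on.size + off.size)
    idx = np.asarray(members[group], dtype=int)
    if idx.size == 0:
        raise ValueError(f"group {group!r} is empty")
    return x[idx].mean(axis=0)


def trial_responses(activity: np.ndarray, schedule: StimulusSchedule) -> pd.DataFrame:
    """Mean activity over each trial's frames -> one record per trial."""
    act = np.asarray(activity, dtype=float)
    rows = []
    for i, tr in enumerate(schedule.trials):
        end = tr.onset_frame + tr.duration_frames
        if end > act.size:
            raise ValueError(f"trial {i} extends past the activity series")
        rows.append(
            {
                "trial": i,
                "direction_deg": tr.direction_deg,
                "orientation_deg": tr.orientation_deg,
                "response": float(act[tr.onset_frame : end].mean()),
            }
        )
    return pd.DataFrame(rows)


def orientation_selectivity(responses: pd.DataFrame) -> tuple[float, float]:
    """(1 - CirVar, preferred orientation) with angle doubling.

    osi = |sum_k R_k exp(2i theta_k)| / sum_k R_k over per-orientation mean
    responses; theta_pref is half the argument, mapped to [0, 180).  Returns
    (NaN, NaN) when every mean response is zero.
    """
    means = responses.groupby("orientation_deg")["response"].mean()
    total = means.sum()
    if total == 0:
        return np.nan, np.nan
    theta = np.deg2rad(means.index.to_numpy() * 2.0)
    vec = np.sum(means.to_numpy() * np.exp(1j * theta))
    osi = float(np.abs(vec) / total)
    theta_pref = float(np.rad2deg(np.angle(vec)) / 2.0 % 180.0)
    return osi, theta_pref


def hotelling_test(responses: pd.DataFrame, n_permutations: int = 999) -> float:
    """One-sample Hotelling t2 p-value for orientation tuning.

    Each trial maps to R_t * (cos 2theta_t, sin 2theta_t); the test asks
    whether the mean vector differs from (0, 0) (F reference distribution).
    Singular covariance (e.g. all-zero responses at some orientations on a
    perfectly selective unit) falls back to a deterministic permutation
    exceedance test on the mean-vector length.
    """
    n = len(responses)
    if n < 3:
        raise ValueError("Hotelling test needs >= 3 trials")
    theta = np.deg2rad(responses["orientation_deg"].to_numpy() * 2.0)
    r = responses["response"].to_numpy()
    X = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    mean = X.mean(axis=0)
    S = np.cov(X, rowvar=False)
    p_dim = 2
    det = np.linalg.det(S)
    if not np.isfinite(det) or det < 1e-24:
        if np.allclose(X, 0.0):
            return 1.0
        rng = np.random.default_rng(0)  # fixed: the test must be deterministic
        obs = np.linalg.norm(mean)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(theta)
            Xp = np.column_stack([r * np.cos(perm), r * np.sin(perm)])
            if np.linalg.norm(Xp.mean(axis=0)) >= obs:
                count += 1
        return (count + 1) / (n_permutations + 1)
    t2 = n * mean @ np.linalg.solve(S, mean)
    f_stat = (n - p_dim) / (p_dim * (n - 1)) * t2
    return float(f_dist.sf(f_stat, p_dim, n - p_dim))


def fit_tuning_curve(
    orientation_means: pd.Series | dict[float, float],
    bounds: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.0, -45.0, 1.0),
        (1.0, 180.0, 90.0),
    ),
) -> TuningCurve:
    """Bounded Gaussian fit of mean response vs orientation.

    The angular difference is wrapped to [-90, 90) so the curve respects the
    180-degree periodicity of orientation.  Multiple restarts over preferred
    angles and widths guard against local minima; a fit landing on the sigma
    or amplitude bounds is flagged.
    """
    if isinstance(orientation_means, dict):
        orientation_means = pd.Series(orientation_means)
    theta = orientation_means.index.to_numpy(dtype=float)
    resp = orientation_means.to_numpy(dtype=float)
    if theta.size < 4:
        raise ValueError("need >= 4 orientation means to fit the curve")
    lo, hi = np.asarray(bounds[0]), np.asarray(bounds[1])

    def model(t, a, theta_pref, sigma):
        d = wrap_orientation_diff(t - theta_pref)
        return a * np.exp(-(d**2) / (2.0 * sigma**2))

    best = None
    starts_theta = [float(theta[np.argmax(resp)]), float(theta[np.argmax(resp)]) - 45.0]
    for th0 in starts_theta:
        th0 = float(np.clip(th0, lo[1], hi[1]))
        for s0 in (10.0, 35.0, 70.0):
            p0 = [float(np.clip(resp.max(), lo[0] + 1e-9, hi[0])), th0, s0]
            try:
                popt, _ = curve_fit(
                    model, theta, resp, p0=p0, bounds=(lo, hi),
                    maxfev=5000, xtol=1e-14, ftol=1e-14,
                )
            except RuntimeError:
                continue
            rss = float(np.sum((model(theta, *popt) - resp) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt)
    if best is None:
        raise RuntimeError("tuning-curve fit failed from every start")
    rss, (a, th, sig) = best
    eps = 1e-6
    at_bounds = bool(
        a <= lo[0] + eps or a >= hi[0] - eps or sig <= lo[2] + eps or sig >= hi[2] - eps
    )
    return TuningCurve(float(a), float(th % 180.0), float(sig), rss, at_bounds)


def tune_unit(
    activity: np.ndarray,
    schedule: StimulusSchedule,
    alpha: float = 0.05,
    fit_curve: bool = True,
) -> TuningResult:
    """Selectivity + significance + optional Gaussian fit for one unit."""
    resp = trial_responses(activity, schedule)
    osi, theta_pref = orientation_selectivity(resp)
    if np.isnan(osi):
        return TuningResult(np.nan, np.nan, 1.0, False, None)
    p = hotelling_test(resp)
    curve = None
    if fit_curve:
        means = resp.groupby("orientation_deg")["response"].mean()
        curve = fit_tuning_curve(means)
    return TuningResult(osi, theta_pref, p, p < alpha, curve)


def _pref_trial_windows(
    schedule: StimulusSchedule, theta_pref_deg: float
) -> list[tuple[int, int]]:
    wins = [
        (t.onset_frame, t.onset_frame + t.duration_frames)
        for t in schedule.trials
        if wrap_orientation_diff(t.orientation_deg - theta_pref_deg) == 0.0
    ]
    if len(wins) < 2:
        raise ValueError("need >= 2 trials at the preferred orientation")
    return wins


def activation_probability(
    activity: np.ndarray,
    schedule: StimulusSchedule,
    theta_pref_deg: float,
    criterion: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Per-frame probability of activation across preferred-orientation trials.

    For binary units a frame counts as active when activity > 0; for group
    (fractional) units, when activity exceeds ``criterion`` (default: the
    series' session median).  Returns (probability curve over the stimulus
    window, max probability, latency of the max in seconds).
    """
    act = np.asarray(activity, dtype=float)
    wins = _pref_trial_windows(schedule, theta_pref_deg)
    if criterion is None:
        vals = np.unique(act)
        criterion = 0.0 if vals.size <= 2 else float(np.median(act))
    width = min(e - s for s, e in wins)
    snips = np.stack([act[s : s + width] > criterion for s, e in wins])
    prob = snips.mean(axis=0)
    i = int(np.argmax(prob))
    return prob, float(prob[i]), float(i * schedule.frame_period_s)


def evoked_duration(
    activity: np.ndarray,
    schedule: StimulusSchedule,
    theta_pref_deg: float,
    criterion: float | None = None,
) -> float:
    """Mean length (s) of the first activity run at/after preferred onsets.

    Per preferred trial: the first maximal run of supra-criterion activity
    starting at or after the onset, measured within the stimulus window;
    0 when the unit never activates in that trial.
    """
    act = np.asarray(activity, dtype=float)
    wins = _pref_trial_windows(schedule, theta_pref_deg)
    if criterion is None:
        vals = np.unique(act)
        criterion = 0.0 if vals.size <= 2 else float(np.median(act))
    durations = []
    for s, e in wins:
        active = act[s:e] > criterion
        idx = np.flatnonzero(active)
        if idx.size == 0:
            durations.append(0)
            continue
        start = idx[0]
        run = 1
        while start + run < active.size and active[start + run]:
            run += 1
        durations.append(run)
    return float(np.mean(durations) * schedule.frame_period_s)


def classify_cell_tuning(
    neuron_spikes: np.ndarray,
    schedule: StimulusSchedule,
    alpha: float = 0.05,
) -> tuple[str, float]:
    """Single-cell response class: tuned(theta) / unspecific / interstim / untuned.

    Orientation-significant neurons (Hotelling p < alpha) are tuned, with the
    preferred orientation snapped to the nearest presented one.  Otherwise a
    Welch two-sample t-test compares mean activity per stimulation period vs
    per interstimulus period: significantly higher during stimulation ->
    unspecific; during gaps -> interstim; neither -> untuned.
    Returns (class, theta_pref or NaN).
    """
    spikes = np.asarray(neuron_spikes, dtype=float)
    resp = trial_responses(spikes, schedule)
    if resp["response"].sum() > 0:
        p = hotelling_test(resp)
        if p < alpha:
            _, theta = orientation_selectivity(resp)
            oris = schedule.orientations
            snapped = oris[np.argmin(np.abs(wrap_orientation_diff(oris - theta)))]
            return "tuned", float(snapped)

    stim_means = resp["response"].to_numpy()
    mask = schedule.stimulus_mask()
    gap_bounds = _gaps(mask)
    gap_means = np.array([spikes[s:e].mean() for s, e in gap_bounds])
    if gap_means.size < 2 or stim_means.size < 2:
        raise ValueError("need both stimulation and interstimulus periods")
    tstat, p2 = ttest_ind(stim_means, gap_means, equal_var=False)
    if np.isfinite(p2) and p2 < alpha:
        return ("unspecific", np.nan) if tstat > 0 else ("interstim", np.nan)
    return "untuned", np.nan


def _gaps(stim_mask: np.ndarray) -> list[tuple[int, int]]:
    gap = ~np.asarray(stim_mask, dtype=bool)
    d = np.diff(np.concatenate([[0], gap.astype(np.int8), [0]]))
    return list(zip(np.flatnonzero(d == 1).tolist(), np.flatnonzero(d == -1).tolist()))


def ensemble_composition(
    participation: pd.DataFrame,
    cell_classes: list[tuple[str, float]],
    ensemble_orientations: dict[int, float],
) -> pd.DataFrame:
    """Member counts per (ensemble, participation group, single-cell class).

    Classes are pref (tuned to the ensemble's orientation), nonpref (tuned
    elsewhere), unspecific, interstim, untuned.  Shared-membership counts
    (neurons in >= 2 onsembles / >= 2 offsembles) are included as extra rows
    with class='shared'.
    """
    rows = []
    group_of = {"onsemble": "onsemble", "offsemble": "offsemble",
                "nonparticipant": "nonparticipant"}
    on_count = participation[participation["class"] == "onsemble"].groupby("neuron_id").size()
    off_count = participation[participation["class"] == "offsemble"].groupby("neuron_id").size()
    for e, theta_e in ensemble_orientations.items():
        sub = participation[participation["ensemble_id"] == e]
        for _, rec in sub.iterrows():
            n = int(rec["neuron_id"])
            cls, theta_n = cell_classes[n]
            if cls == "tuned":
                label = "pref" if wrap_orientation_diff(theta_n - theta_e) == 0.0 else "nonpref"
            else:
                label = cls
            rows.append({"ensemble_id": e, "group": group_of[rec["class"]], "cls": label})
    counts = (
        pd.DataFrame(rows).groupby(["ensemble_id", "group", "cls"]).size().rename("count")
        .reset_index()
    )
    shared = []
    for e in ensemble_orientations:
        sub = participation[participation["ensemble_id"] == e]
        on_ids = sub.loc[sub["class"] == "onsemble", "neuron_id"]
        off_ids = sub.loc[sub["class"] == "offsemble", "neuron_id"]
        shared.append({"ensemble_id": e, "group": "onsemble", "cls": "shared",
                       "count": int((on_count.reindex(on_ids).fillna(0) >= 2).sum())})
        shared.append({"ensemble_id": e, "group": "offsemble", "cls": "shared",
                       "count": int((off_count.reindex(off_ids).fillna(0) >= 2).sum())})
    return pd.concat([counts, pd.DataFrame(shared)], ignore_index=True)
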