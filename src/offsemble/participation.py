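"""Ensemble Participation Index, onsemble/offsemble classification, dynamics.

The EPI contrasts a neuron's firing rate during an ensemble's occurrences
with its rate outside them, as the normalized difference
(r_in - r_out) / (r_in + r_out), bounded in [-1, 1]: +1 means exclusively
active during ensemble events, -1 exclusively outside them (inactivated),
0 equal rates.  Participation significance comes from a two-sample Welch
t-test on per-epoch activity fractions (occurrence epochs vs length-matched
inactivity epochs); significant positive EPI -> onsemble member, significant
negative EPI -> offsemble member, otherwise nonparticipant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.stats import ttest_ind

from .ensembles import EnsembleModel
from .synthgen import Raster

ONSEMBLE, OFFSEMBLE, NONPARTICIPANT = "onsemble", "offsemble", "nonparticipant"


@dataclass
class OnsetProfile:
    """Group-averaged activity around ensemble onsets."""

    time_s: np.ndarray  # relative to onset
    fraction: dict[str, np.ndarray]  # per group, mean fraction of active members
    cumulative_onsemble: np.ndarray  # fraction of members active at least once since onset
    peak: dict[str, tuple[float, float]]  # group -> (value, latency_s)


def epi(
    neuron_spikes: np.ndarray,
    ensemble_signal: np.ndarray,
    frame_mask: np.ndarray | None = None,
) -> float:
    """Ensemble Participation Index; NaN when the neuron never spikes in-mask.

    EPI = (r_in - r_out) / (r_in + r_out), the normalized difference of the
    firing rate during ensemble occurrences (r_in) and outside them (r_out),
    both within ``frame_mask``.  +1: active exclusively during occurrences;
    -1: exclusively outside them; 0: equal rates.  When occurrence and
    non-occurrence frames are equally many (as in the anchor constructions)
    this coincides with 2 x (spikes inside / spikes total) - 1.
    """
    spikes = np.asarray(neuron_spikes, dtype=bool)
    signal = np.asarray(ensemble_signal, dtype=bool)
    if spikes.shape != signal.shape:
        raise ValueError("spike and signal series must have equal length")
    if frame_mask is not None:
        mask = np.asarray(frame_mask, dtype=bool)
        spikes, signal = spikes[mask], signal[mask]
    n_in = int(signal.sum())
    n_out = int((~signal).sum())
    if n_in == 0 or n_out == 0:
        return np.nan
    r_in = float((spikes & signal).sum()) / n_in
    r_out = float((spikes & ~signal).sum()) / n_out
    if r_in + r_out == 0.0:
        return np.nan
    return (r_in - r_out) / (r_in + r_out)


def _runs(binary: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals of maximal 1-runs."""
    b = np.asarray(binary, dtype=bool).astype(np.int8)
    d = np.diff(np.concatenate([[0], b, [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def classify_participation(
    raster: Raster,
    ensemble_signal: np.ndarray,
    alpha: float = 0.05,
    exclude_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-neuron EPI, p-value, and class for one ensemble.

    Sampling units for the t-test are epochs: one activity fraction per
    ensemble-occurrence run and one per complementary inactivity gap (Welch
    variant).  ``exclude_mask`` marks frames to drop from the gap epochs —
    typically the occurrences of *other* ensembles, so that "ensemble
    inactivity" means no ensemble is active and a neuron driven by a
    different ensemble is not mistaken for a suppressed one.  Neurons with
    undefined EPI (no spikes) or degenerate samples are nonparticipants with
    ``flagged=True``.
    """
    signal = np.asarray(ensemble_signal, dtype=bool)
    occ = _runs(signal)
    gap_ok = ~signal
    if exclude_mask is not None:
        gap_ok = gap_ok & ~np.asarray(exclude_mask, dtype=bool)
    if len(occ) < 2:
        raise ValueError("ensemble needs >= 2 occurrence epochs for the t-test")
    # Matched inactivity epochs: split the gaps into chunks of the median
    # occurrence length, so the two samples have comparable per-epoch
    # variance; sub-half-length remainders are dropped.
    med = max(int(np.median([e - s for s, e in occ])), 1)
    gaps: list[tuple[int, int]] = []
    for s, e in _runs(gap_ok):
        n_chunks = (e - s) // med
        gaps.extend((s + i * med, s + (i + 1) * med) for i in range(n_chunks))
        rem = (e - s) - n_chunks * med
        if rem >= max(med // 2, 1):
            gaps.append((s + n_chunks * med, e))
    if len(gaps) < 2:
        raise ValueError("ensemble needs >= 2 inactivity epochs for the t-test")
    x = raster.spikes.astype(bool)
    occ_frac = np.stack([x[:, s:e].mean(axis=1) for s, e in occ], axis=1)
    gap_frac = np.stack([x[:, s:e].mean(axis=1) for s, e in gaps], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = ttest_ind(occ_frac, gap_frac, axis=1, equal_var=False)

    # EPI over the same analysis mask the t-test sees (occurrences plus the
    # retained inactivity frames), so its sign reflects activation vs
    # inactivation during THIS ensemble rather than spiking concentration
    # relative to every other ensemble.  With a single ensemble and no
    # exclusions this reduces to the whole-session index.
    analysis_mask = signal | gap_ok

    rows = []
    for n in range(raster.n_neurons):
        e_val = epi(x[n], signal, frame_mask=analysis_mask)
        p = float(pval[n])
        t = float(tstat[n])
        flagged = not np.isfinite(e_val) or not np.isfinite(p)
        # The EPI sign and the epoch-comparison direction must agree: a
        # neuron shared between several ensembles can be activated during
        # this one (t > 0) yet spike mostly elsewhere (EPI < 0); such
        # neurons are neither onsemble nor offsemble members here.
        if flagged:
            cls = NONPARTICIPANT
        elif p < alpha and e_val > 0 and t > 0:
            cls = ONSEMBLE
        elif p < alpha and e_val < 0 and t < 0:
            cls = OFFSEMBLE
        else:
            cls = NONPARTICIPANT
        rows.append(
            {
                "neuron_id": n,
                "epi": e_val,
                "firing_rate_ensemble": float(x[n, signal].mean()) if signal.any() else np.nan,
                "firing_rate_total": float(x[n].mean()),
                "p_value": p,
                "class": cls,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def exclusion_mask(
    signal: np.ndarray,
    other_signals: list[np.ndarray],
    guard_frames: int = 3,
    min_gap_fraction: float = 0.25,
) -> np.ndarray | None:
    """Frames to exclude from the inactivity epochs of one ensemble's test.

    Other ensembles' occurrences (dilated by ``guard_frames``) are excluded so
    that "inactivity" means no ensemble active — but the inactivity baseline
    must retain at least ``min_gap_fraction`` of the complement.  Tonic,
    session-spanning ensembles (e.g. one tracking the interstimulus periods)
    would blanket the whole complement, so the largest-occupancy signals are
    released from the exclusion set until enough baseline remains.
    """
    signal = np.asarray(signal, dtype=bool)
    if not other_signals:
        return None
    others = sorted(
        (np.asarray(o, dtype=bool) for o in other_signals), key=lambda o: o.sum()
    )
    complement = int((~signal).sum())
    structure = np.ones(2 * guard_frames + 1, bool)
    while others:
        exclude = np.any(others, axis=0)
        if guard_frames:
            exclude = binary_dilation(exclude, structure)
        if int((~signal & ~exclude).sum()) >= min_gap_fraction * complement:
            return exclude
        others.pop()  # release the largest-occupancy signal
    return None


def participation_table(
    raster: Raster,
    model: EnsembleModel,
    alpha: float = 0.05,
    guard_frames: int = 3,
) -> pd.DataFrame:
    """EPI/class records for every (neuron, significant ensemble) pair.

    For each ensemble, the other ensembles' occurrence frames — dilated by
    ``guard_frames`` on each side, since the preprocessing cannot localize
    events more finely than the smoothing window — are excluded from the
    inactivity epochs of the t-test (occurrences are mutually exclusive, so
    "inactivity" means no ensemble active).
    """
    tables = []
    for e in model.ensemble_ids:
        signal = model.ensemble_signals[e].astype(bool)
        others = {o: model.ensemble_signals[o] for o in model.ensemble_ids if o != e}
        exclude = exclusion_mask(signal, list(others.values()), guard_frames)
        try:
            t = classify_participation(
                raster, model.ensemble_signals[e], alpha=alpha, exclude_mask=exclude
            )
        except ValueError as exc:  # e.g. a single contiguous occurrence run
            warnings.warn(f"skipping ensemble {e}: {exc}")
            continue
        t.insert(1, "ensemble_id", e)
        tables.append(t)
    if not tables:
        return pd.DataFrame(
            columns=["neuron_id", "ensemble_id", "epi", "firing_rate_ensemble",
                     "firing_rate_total", "p_value", "class", "flagged"]
        )
    return pd.concat(tables, ignore_index=True)


def onset_profile(
    raster: Raster,
    ensemble_signal: np.ndarray,
    classes: dict[str, np.ndarray],
    window_s: tuple[float, float] = (-2.0, 2.0),
) -> OnsetProfile:
    """Average member activity around ensemble onsets.

    Onsets are rising edges of the occurrence signal whose full window lies
    inside the session.  ``classes`` maps group name -> member neuron indices.
    The cumulative curve tracks the fraction of onsemble members active at
    least once since onset.
    """
    dt = raster.frame_period_s
    lo = int(round(window_s[0] / dt))
    hi = int(round(window_s[1] / dt))
    signal = np.asarray(ensemble_signal, dtype=bool)
    onsets = [s for s, _ in _runs(signal) if s + lo >= 0 and s + hi <= raster.n_frames]
    if not onsets:
        raise ValueError("no ensemble onset with a full analysis window")
    x = raster.spikes.astype(bool)
    rel = np.arange(lo, hi)
    time_s = rel * dt

    fraction: dict[str, np.ndarray] = {}
    peak: dict[str, tuple[float, float]] = {}
    cumulative = None
    for group, members in classes.items():
        members = np.asarray(members, dtype=int)
        if members.size == 0:
            continue
        snips = np.stack([x[np.ix_(members, onset + rel)] for onset in onsets])
        frac = snips.mean(axis=(0, 1))
        fraction[group] = frac
        post = rel >= 0
        if group == OFFSEMBLE:
            i = int(np.argmin(frac[post]))
        else:
            i = int(np.argmax(frac[post]))
        peak[group] = (float(frac[post][i]), float(time_s[post][i]))
        if group == ONSEMBLE:
            post_snips = snips[:, :, post]
            cum = np.maximum.accumulate(post_snips, axis=2).mean(axis=(0, 1))
            cumulative = np.concatenate([np.full(int((~post).sum()), np.nan), cum])
    if cumulative is None:
        cumulative = np.full(time_s.size, np.nan)
    return OnsetProfile(time_s=time_s, fraction=fraction,
                        cumulative_onsemble=cumulative, peak=peak)


def epi_by_locomotion(
    raster: Raster,
    ensemble_signal: np.ndarray,
    speed_cm_s: np.ndarray,
    run_threshold: float = 1.0,
    min_run_fraction: float = 0.05,
) -> pd.DataFrame:
    """Per-neuron EPI computed separately over still and running frames.

    Sessions with running occupying less than ``min_run_fraction`` of frames
    are flagged ineligible (EPIs still reported).  Neurons silent within a
    partition get a NaN EPI for that partition.
    """
    speed = np.asarray(speed_cm_s, dtype=float)
    if speed.size != raster.n_frames:
        raise ValueError("speed series not aligned to raster frames")
    running = speed > run_threshold
    eligible = bool(running.mean() >= min_run_fraction)
    x = raster.spikes.astype(bool)
    rows = []
    for n in range(raster.n_neurons):
        rows.append(
            {
                "neuron_id": n,
                "epi_still": epi(x[n], ensemble_signal, frame_mask=~running),
                "epi_running": epi(x[n], ensemble_signal, frame_mask=running),
                "eligible": eligible,
            }
        )
    return pd.DataFrame(rows)


def wakefulness_fraction(whisking_energy: np.ndarray, threshold: float) -> float:
    """Fraction of frames with whisking energy above threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    energy = np.asarray(whisking_energy, dtype=float)
    return float((energy > threshold).mean())
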