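"""Synthetic sessions: stimulus schedules, planted ensembles, spikes, calcium.

The generator emulates a head-fixed visual-stimulation session: drifting
gratings in 8 directions (4 orientations), a population of neurons carrying
planted ensemble structure (coactivated "onsemble" members, suppressed
"offsemble" members, uninvolved nonparticipants), GCaMP6s-like calcium
transients with condition-dependent decay constants, neuropil contamination,
and block-structured locomotion.  Every downstream stage of the pipeline is
testable against the planted ground truth with no external data.

All randomness flows from one root seed through named substreams
(schedule / membership / spikes / noise / behavior), so any stage can be
regenerated independently and deterministically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

ON, OFF, NON = 1, -1, 0  # membership codes, per (neuron, ensemble)

DEFAULT_DIRECTIONS = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)


class CapacityError(ValueError):
    """Requested schedule cannot fit in the session duration."""


class Trial(NamedTuple):
    onset_frame: int
    duration_frames: int
    direction_deg: float

    @property
    def orientation_deg(self) -> float:
        return self.direction_deg % 180.0


@dataclass
class StimulusSchedule:
    """Trial onsets/durations/directions over a fixed-rate frame clock.

    Frames are 0-based; a trial occupies the half-open frame interval
    [onset_frame, onset_frame + duration_frames).
    """

    trials: list[Trial]
    frame_period_s: float
    session_frames: int

    def __post_init__(self) -> None:
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be positive")
        prev_end = -1
        for t in self.trials:
            if t.onset_frame < prev_end:
                raise ValueError("trials overlap or are unsorted")
            prev_end = t.onset_frame + t.duration_frames
        if prev_end > self.session_frames:
            raise ValueError("trial extends past session end")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def orientations(self) -> np.ndarray:
        """Distinct orientations presented, sorted, in degrees."""
        return np.unique([t.orientation_deg for t in self.trials])

    def stimulus_mask(self) -> np.ndarray:
        """Boolean per frame: inside any trial."""
        mask = np.zeros(self.session_frames, dtype=bool)
        for t in self.trials:
            mask[t.onset_frame : t.onset_frame + t.duration_frames] = True
        return mask

    def frame_orientations(self) -> np.ndarray:
        """Per frame: orientation in degrees, or NaN outside trials."""
        ori = np.full(self.session_frames, np.nan)
        for t in self.trials:
            ori[t.onset_frame : t.onset_frame + t.duration_frames] = t.orientation_deg
        return ori


@dataclass
class BehaviorTrace:
    speed_cm_s: np.ndarray
    whisking_energy: np.ndarray

    def __post_init__(self) -> None:
        if len(self.speed_cm_s) != len(self.whisking_energy):
            raise ValueError("behavior series length mismatch")


@dataclass
class PopulationConfig:
    """Planted-population parameters.

    Fractions follow typical L2/3 visual-cortex composition: ~20% of neurons form
    each ensemble's onsemble and ~26% its offsemble; about half of onsemble
    members are shared with other onsembles; offsembles draw mostly from
    other ensembles' onsembles (cross-orientation suppression) and from
    interstimulus-preferring neurons.
    """

    n_neurons: int = 200
    orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    frac_onsemble: float = 0.20
    frac_offsemble: float = 0.26
    onsemble_overlap: float = 0.54
    off_from_other_onsembles: float = 0.47
    off_from_interstim: float = 0.38
    frac_interstim: float = 0.18
    tuning_width_deg: float = 35.0
    tau_decay_spont_s: float = 5.8
    tau_decay_suppressed_s: float = 2.5
    amplitude: float = 0.2

    def validate(self) -> None:
        if self.frac_onsemble + self.frac_offsemble > 1.0:
            raise ValueError("onsemble + offsemble fractions exceed 1")
        for name in ("frac_onsemble", "frac_offsemble", "onsemble_overlap",
                     "off_from_other_onsembles", "off_from_interstim",
                     "frac_interstim"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.off_from_other_onsembles + self.off_from_interstim > 1.0:
            raise ValueError("offsemble composition fractions exceed 1")
        if self.tau_decay_spont_s <= 0 or self.tau_decay_suppressed_s <= 0:
            raise ValueError("decay constants must be positive")
        if self.n_neurons < 1:
            raise ValueError("need at least one neuron")


@dataclass
class RateParams:
    """Per-frame Bernoulli spike probabilities for the planted dynamics."""

    baseline: float = 0.2
    evoked_gain: float = 2.9
    suppression: float = 0.4
    interstim_gain: float = 2.0

    def validate(self) -> None:
        if not 0.0 < self.baseline < 1.0:
            raise ValueError("baseline rate must lie in (0, 1)")
        if self.evoked_gain < 1.0:
            raise ValueError("evoked gain must be >= 1")
        if not 0.0 <= self.suppression <= 1.0:
            raise ValueError("suppression factor must lie in [0, 1]")
        if self.baseline * max(self.evoked_gain, self.interstim_gain) > 1.0:
            raise ValueError("evoked per-frame probability exceeds 1")


@dataclass
class SyntheticGroundTruth:
    """Planted memberships, tuning classes, and kinetics for one population.

    membership[n, e] is +1 (onsemble), -1 (offsemble) or 0 (nonparticipant);
    labels are mutually exclusive per ensemble but a neuron may hold different
    labels across ensembles.
    """

    membership: np.ndarray  # (n_neurons, n_ensembles) int8
    ensemble_orientations_deg: np.ndarray  # (n_ensembles,)
    neuron_class: list[str]  # 'tuned' | 'unspecific' | 'interstim' | 'untuned'
    neuron_pref_deg: np.ndarray  # preferred orientation, NaN if none
    tau_decay_spont_s: np.ndarray  # per neuron, seconds
    tau_decay_suppressed_s: np.ndarray
    amplitude: np.ndarray
    tuning_width_deg: float
    seed: int
    config: PopulationConfig = field(repr=False, default=None)

    @property
    def n_neurons(self) -> int:
        return self.membership.shape[0]

    @property
    def n_ensembles(self) -> int:
        return self.membership.shape[1]

    def members(self, e: int, role: int) -> np.ndarray:
        """Neuron indices holding `role` (ON/OFF/NON) in ensemble e."""
        return np.flatnonzero(self.membership[:, e] == role)


@dataclass
class Raster:
    """Binary spike matrix, neurons x frames."""

    spikes: np.ndarray
    frame_period_s: float

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 2:
            raise ValueError("raster must be 2-D (neurons x frames)")
        vals = np.unique(self.spikes)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("raster entries must be 0/1")
        self.spikes = self.spikes.astype(np.uint8)

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.spikes.shape[1]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of the root seed (schedule/spikes/noise/behavior...)."""
    key = zlib.crc32(name.encode("utf-8"))  # stable across processes
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def generate_stimulus_schedule(
    duration_s: float = 300.0,
    directions: Sequence[float] = DEFAULT_DIRECTIONS,
    reps_min: int = 6,
    stim_dur_s: float = 2.0,
    isi_min_s: float = 1.0,
    isi_max_s: float = 5.0,
    frame_period_s: float = 0.081,
    seed: int = 0,
) -> StimulusSchedule:
    """Randomized drifting-grating schedule.

    Directions are drawn in shuffled balanced blocks (each block one
    permutation of all directions), so repetition counts differ by at most
    one; inter-stimulus intervals are uniform on [isi_min_s, isi_max_s],
    rounded to whole frames.  Trials are packed until the session ends.
    Raises :class:`CapacityError` if the duration cannot hold ``reps_min``
    repetitions of every direction.
    """
    if isi_min_s > isi_max_s:
        raise ValueError("isi_min_s must not exceed isi_max_s")
    session_frames = int(round(duration_s / frame_period_s))
    if reps_min > 0 and duration_s < reps_min * len(directions) * (stim_dur_s + isi_min_s):
        raise CapacityError(
            f"{duration_s} s cannot hold {reps_min} reps of {len(directions)} "
            f"directions at >= {stim_dur_s + isi_min_s} s per trial"
        )
    if reps_min == 0:
        return StimulusSchedule([], frame_period_s, session_frames)

    rng = substream(seed, "schedule")
    dur_frames = int(round(stim_dur_s / frame_period_s))
    trials: list[Trial] = []
    order: list[float] = []
    t = float(rng.uniform(isi_min_s, isi_max_s))  # lead-in blank
    while True:
        if not order:
            order = list(rng.permutation(np.asarray(directions, dtype=float)))
        onset = int(round(t / frame_period_s))
        if onset + dur_frames > session_frames:
            break
        trials.append(Trial(onset, dur_frames, float(order.pop(0))))
        t = (onset + dur_frames) * frame_period_s + float(rng.uniform(isi_min_s, isi_max_s))

    counts = {d: 0 for d in directions}
    for tr in trials:
        counts[tr.direction_deg] += 1
    if min(counts.values()) < reps_min:
        raise CapacityError(
            f"only {min(counts.values())} repetitions fit for some direction; "
            f"{reps_min} required"
        )
    return StimulusSchedule(trials, frame_period_s, session_frames)


def _sample(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    k = min(k, pool.size)
    if k == 0:
        return np.empty(0, dtype=int)
    return rng.choice(pool, size=k, replace=False)


def generate_population(config: PopulationConfig, seed: int = 0) -> SyntheticGroundTruth:
    """Assign planted on/off/non membership per ensemble plus tuning classes.

    Ensemble 0's onsemble is drawn uniformly; each later onsemble draws
    ``onsemble_overlap`` of its members from earlier onsembles (shared
    members) and the rest from never-members.  Offsembles draw their
    configured fractions from other ensembles' onsembles and from the
    interstimulus pool, excluding the ensemble's own onsemble.
    """
    config.validate()
    rng = substream(seed, "membership")
    N = config.n_neurons
    n_ens = len(config.orientations_deg)
    n_on = int(round(config.frac_onsemble * N))
    n_off = int(round(config.frac_offsemble * N))
    if n_on + n_off > N:
        raise ValueError("onsemble + offsemble counts exceed population")

    membership = np.zeros((N, n_ens), dtype=np.int8)
    all_idx = np.arange(N)

    # Onsembles, with configured sharing across ensembles.  Shared members
    # are drawn from earlier onsembles with weights following the tuning
    # similarity of the two ensembles' orientations, so co-membership is
    # most common between adjacent orientations.
    oris_arr = np.asarray(config.orientations_deg, dtype=float)
    sigma = max(config.tuning_width_deg, 1e-6)
    onsets: list[np.ndarray] = []
    for e in range(n_ens):
        if e == 0:
            chosen = _sample(rng, all_idx, n_on)
        else:
            prior = np.unique(np.concatenate(onsets))
            weights = np.zeros(prior.size)
            for ep in range(e):
                d = wrap_orientation_diff(oris_arr[e] - oris_arr[ep])
                w = np.exp(-(d**2) / (2.0 * sigma**2)) + 1e-9
                weights += w * np.isin(prior, onsets[ep])
            n_shared = int(round(config.onsemble_overlap * n_on))
            n_shared = min(n_shared, prior.size)
            if n_shared and config.onsemble_overlap < 1.0:
                p = weights / weights.sum()
                shared = rng.choice(prior, size=n_shared, replace=False, p=p)
            else:
                shared = _sample(rng, prior, n_shared)
            fresh_pool = np.setdiff1d(all_idx, prior)
            fresh = _sample(rng, fresh_pool, n_on - shared.size)
            chosen = np.concatenate([shared, fresh])
            if chosen.size < n_on:  # fresh pool exhausted; top up from anywhere
                extra = _sample(rng, np.setdiff1d(all_idx, chosen), n_on - chosen.size)
                chosen = np.concatenate([chosen, extra])
        onsets.append(np.sort(chosen))
        membership[chosen, e] = ON

    ever_on = np.unique(np.concatenate(onsets)) if n_on else np.empty(0, int)

    # Interstimulus-preferring pool, outside every onsemble.
    n_interstim = int(round(config.frac_interstim * N))
    interstim = _sample(rng, np.setdiff1d(all_idx, ever_on), n_interstim)

    # Offsembles.
    for e in range(n_ens):
        own_on = onsets[e]
        q_on = int(round(config.off_from_other_onsembles * n_off))
        q_is = int(round(config.off_from_interstim * n_off))
        other_on = np.setdiff1d(ever_on, own_on)
        part1 = _sample(rng, other_on, q_on)
        part2 = _sample(rng, np.setdiff1d(interstim, own_on), q_is)
        chosen = np.unique(np.concatenate([part1, part2]))
        rest_pool = np.setdiff1d(all_idx, np.concatenate([own_on, chosen]))
        rest = _sample(rng, rest_pool, n_off - chosen.size)
        chosen = np.concatenate([chosen, rest])
        membership[chosen, e] = OFF  # overwrites nothing: own onsemble excluded

    # Derived single-cell classes.
    neuron_class: list[str] = []
    neuron_pref = np.full(N, np.nan)
    oris = np.asarray(config.orientations_deg, dtype=float)
    for n in range(N):
        on_of = np.flatnonzero(membership[n] == ON)
        if on_of.size == 1:
            neuron_class.append("tuned")
            neuron_pref[n] = oris[on_of[0]]
        elif on_of.size >= 2:
            neuron_class.append("unspecific")
        elif n in interstim:
            neuron_class.append("interstim")
        else:
            neuron_class.append("untuned")

    return SyntheticGroundTruth(
        membership=membership,
        ensemble_orientations_deg=oris,
        neuron_class=neuron_class,
        neuron_pref_deg=neuron_pref,
        tau_decay_spont_s=np.full(N, config.tau_decay_spont_s),
        tau_decay_suppressed_s=np.full(N, config.tau_decay_suppressed_s),
        amplitude=np.full(N, config.amplitude),
        tuning_width_deg=config.tuning_width_deg,
        seed=seed,
        config=config,
    )


def wrap_orientation_diff(delta_deg: np.ndarray | float) -> np.ndarray | float:
    """Map an orientation difference to [-90, 90) degrees."""
    return (np.asarray(delta_deg) + 90.0) % 180.0 - 90.0


def spike_probabilities(
    ground_truth: SyntheticGroundTruth,
    schedule: StimulusSchedule,
    rates: RateParams = RateParams(),
) -> np.ndarray:
    """Per-(neuron, frame) Bernoulli probability implied by the planted model.

    During a trial of orientation theta, onsemble members of the matching
    ensemble fire at baseline x gain scaled by a Gaussian of the orientation
    difference (tuning width); offsemble members of the exactly-matching
    ensemble are multiplied by the suppression factor; interstimulus-class
    neurons are elevated only between trials; everyone else stays at baseline.
    """
    rates.validate()
    N, F = ground_truth.n_neurons, schedule.session_frames
    sigma = ground_truth.tuning_width_deg
    drive = np.ones((N, F))
    supp = np.ones((N, F))
    for tr in schedule.trials:
        sl = slice(tr.onset_frame, tr.onset_frame + tr.duration_frames)
        for e, theta_e in enumerate(ground_truth.ensemble_orientations_deg):
            d = wrap_orientation_diff(tr.orientation_deg - theta_e)
            w = float(np.exp(-(d**2) / (2.0 * sigma**2)))
            on = ground_truth.members(e, ON)
            if on.size:
                factor = 1.0 + (rates.evoked_gain - 1.0) * w
                drive[on, sl] = np.maximum(drive[on, sl], factor)
            if d == 0.0:
                off = ground_truth.members(e, OFF)
                if off.size:
                    supp[off, sl] = rates.suppression
    isi = ~schedule.stimulus_mask()
    interstim = np.array([c == "interstim" for c in ground_truth.neuron_class])
    if interstim.any() and isi.any():
        drive[np.ix_(interstim, isi)] = rates.interstim_gain
    p = rates.baseline * drive * supp
    if p.max() > 1.0:
        raise ValueError("per-frame spike probability exceeds 1 after gain")
    return p


def simulate_raster(
    ground_truth: SyntheticGroundTruth,
    schedule: StimulusSchedule,
    rates: RateParams = RateParams(),
    seed: int = 0,
) -> Raster:
    """Bernoulli ground-truth spikes under the planted dynamics."""
    p = spike_probabilities(ground_truth, schedule, rates)
    rng = substream(seed, "spikes")
    spikes = (rng.random(p.shape) < p).astype(np.uint8)
    return Raster(spikes, schedule.frame_period_s)


def suppression_mask(
    ground_truth: SyntheticGroundTruth, schedule: StimulusSchedule
) -> np.ndarray:
    """Boolean (neuron, frame): the neuron's suppressing stimulus is on."""
    N, F = ground_truth.n_neurons, schedule.session_frames
    mask = np.zeros((N, F), dtype=bool)
    for tr in schedule.trials:
        sl = slice(tr.onset_frame, tr.onset_frame + tr.duration_frames)
        for e, theta_e in enumerate(ground_truth.ensemble_orientations_deg):
            if wrap_orientation_diff(tr.orientation_deg - theta_e) == 0.0:
                off = ground_truth.members(e, OFF)
                mask[off, sl] = True
    return mask


def synthesize_calcium(
    true_raster: Raster,
    ground_truth: SyntheticGroundTruth,
    schedule: StimulusSchedule | None = None,
    neuropil_level: float = 1.0,
    noise_sd: float = 0.02,
    seed: int = 0,
):
    """GCaMP-like fluorescence from a spike raster.

    Each spike adds an instantaneous-rise transient of per-neuron amplitude
    that decays exponentially; the decay constant switches from the
    spontaneous to the suppressed value during frames where the neuron's
    suppressing stimulus is shown (emulating faster decay under inhibition).
    F_ROI = calcium + neuropil_level x shared background + Gaussian noise;
    F_neuropil = shared background + independent Gaussian noise.

    Returns a :class:`offsemble.signals.TraceSet`.
    """
    from .signals import TraceSet  # local import to avoid a cycle

    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    spikes = true_raster.spikes.astype(float)
    N, F = spikes.shape
    dt = true_raster.frame_period_s
    if schedule is not None:
        supp = suppression_mask(ground_truth, schedule)
    else:
        supp = np.zeros((N, F), dtype=bool)

    decay_spont = np.exp(-dt / ground_truth.tau_decay_spont_s)[:, None]
    decay_supp = np.exp(-dt / ground_truth.tau_decay_suppressed_s)[:, None]
    decay = np.where(supp, decay_supp, decay_spont)

    c = np.zeros((N, F))
    amp = ground_truth.amplitude
    c[:, 0] = amp * spikes[:, 0]
    for t in range(1, F):  # time-varying AR(1); per-frame loop over all neurons
        c[:, t] = c[:, t - 1] * decay[:, t] + amp * spikes[:, t]

    tt = np.arange(F) * dt
    background = 1.0 + 0.05 * np.sin(2.0 * np.pi * tt / 60.0)  # slow shared drift
    rng = substream(seed, "noise")
    f_neuropil = background[None, :] + rng.normal(0.0, noise_sd, (N, F))
    f_roi = c + neuropil_level * background[None, :] + rng.normal(0.0, noise_sd, (N, F))
    return TraceSet(f_roi=f_roi, f_neuropil=f_neuropil, frame_period_s=dt)


def simulate_behavior(
    session_frames: int,
    run_fraction: float = 0.3,
    seed: int = 0,
    frame_period_s: float = 0.081,
    wake_fraction: float = 1.0,
) -> BehaviorTrace:
    """Block-structured running and whisking traces.

    Running comes in bouts of 2-8 s separated by still bouts sized so that
    running occupies ~run_fraction of frames (speed > 1 cm/s during bouts,
    < 1 cm/s otherwise).  Whisking energy is elevated during wakeful epochs.
    """
    if not 0.0 <= run_fraction <= 1.0:
        raise ValueError("run_fraction must lie in [0, 1]")
    rng = substream(seed, "behavior")
    running = np.zeros(session_frames, dtype=bool)
    if run_fraction >= 1.0:
        running[:] = True
    elif run_fraction > 0.0:
        t = 0
        while t < session_frames:
            run_len = int(round(rng.uniform(2.0, 8.0) / frame_period_s))
            still_len = int(round(run_len * (1.0 - run_fraction) / run_fraction))
            order = rng.random() < 0.5
            first, second = (run_len, still_len) if order else (still_len, run_len)
            if order:
                running[t : t + run_len] = True
            else:
                running[t + still_len : t + still_len + run_len] = True
            t += first + second

    speed = np.abs(rng.normal(0.15, 0.15, session_frames)).clip(max=0.9)
    speed[running] = rng.normal(8.0, 2.0, int(running.sum())).clip(min=1.5)

    wake = np.zeros(session_frames, dtype=bool)
    n_wake = int(round(wake_fraction * session_frames))
    wake[:n_wake] = True
    energy = np.abs(rng.normal(0.05, 0.05, session_frames))
    energy[wake] = np.abs(rng.normal(1.0, 0.3, int(wake.sum()))) + 0.2
    return BehaviorTrace(speed_cm_s=speed, whisking_energy=energy)
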