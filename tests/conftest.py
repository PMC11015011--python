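"""Shared fixtures: two synthetic sessions reused across the suite.

``clean_session`` is the well-posed recovery regime: disjoint onsembles,
narrow tuning (no cross-orientation spillover), no interstimulus pool, and
sparse high-contrast spiking, analysed directly on the true spike raster.
``realistic_session`` is the realistic regime — population size, composition,
sharing, and per-frame event rates set to realistic recorded statistics —
pushed through the full fluorescence chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

from offsemble.ensembles import EnsembleModel, detect_ensembles
from offsemble.participation import participation_table
from offsemble.signals import preprocess
from offsemble.synthgen import (
    PopulationConfig,
    RateParams,
    Raster,
    StimulusSchedule,
    SyntheticGroundTruth,
    generate_population,
    generate_stimulus_schedule,
    simulate_raster,
    synthesize_calcium,
)
from offsemble.tuning import classify_cell_tuning, tune_unit

CLEAN_SEED = 2
REALISTIC_SEED = 11

CLEAN_POP = PopulationConfig(
    n_neurons=200, onsemble_overlap=0.0, frac_interstim=0.0, tuning_width_deg=10.0
)
CLEAN_RATES = RateParams(
    baseline=0.02, evoked_gain=25.0, suppression=0.1, interstim_gain=1.0
)


@dataclass
class Session:
    schedule: StimulusSchedule
    ground_truth: SyntheticGroundTruth
    true_raster: Raster
    raster: Raster  # the raster the analysis runs on
    model: EnsembleModel
    participation: pd.DataFrame
    cell_classes: list | None = None

    def frame_truth(self) -> np.ndarray:
        """Planted orientation per frame (-1 outside trials)."""
        ori = self.schedule.frame_orientations()
        return np.where(np.isnan(ori), -1.0, ori)

    def ensemble_to_orientation(self) -> dict[int, float]:
        """Map each significant ensemble to its modal planted orientation."""
        truth = self.frame_truth()
        labels = self.model.labels_full(self.raster.n_frames)
        mapping = {}
        for e in self.model.ensemble_ids:
            vals, counts = np.unique(truth[labels == e], return_counts=True)
            mapping[e] = float(vals[np.argmax(counts)])
        return mapping


@pytest.fixture(scope="session")
def clean_session() -> Session:
    schedule = generate_stimulus_schedule(seed=CLEAN_SEED)
    gt = generate_population(CLEAN_POP, seed=CLEAN_SEED)
    raster = simulate_raster(gt, schedule, CLEAN_RATES, seed=CLEAN_SEED)
    model = detect_ensembles(raster, seed=CLEAN_SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        part = participation_table(raster, model)
    return Session(schedule, gt, raster, raster, model, part)


@pytest.fixture(scope="session")
def realistic_session() -> Session:
    schedule = generate_stimulus_schedule(seed=REALISTIC_SEED)
    gt = generate_population(PopulationConfig(n_neurons=538), seed=REALISTIC_SEED)
    true_raster = simulate_raster(gt, schedule, RateParams(), seed=REALISTIC_SEED)
    traces = synthesize_calcium(true_raster, gt, schedule, seed=REALISTIC_SEED)
    raster, _, _ = preprocess(traces)
    model = detect_ensembles(raster, seed=REALISTIC_SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        part = participation_table(raster, model)
    classes = [
        classify_cell_tuning(raster.spikes[n], schedule)
        for n in range(raster.n_neurons)
    ]
    return Session(schedule, gt, true_raster, raster, model, part, classes)


@pytest.fixture(scope="session")
def realistic_tuned_ensembles(realistic_session) -> dict[int, float]:
    """Significant, orientation-tuned ensembles -> snapped orientation."""
    s = realistic_session
    out = {}
    oris = s.schedule.orientations
    for e in sorted(set(s.participation.ensemble_id)):
        r = tune_unit(s.model.ensemble_signals[e], s.schedule, fit_curve=False)
        if r.significant:
            snapped = float(oris[np.argmin(np.abs((oris - r.theta_pref_deg + 90) % 180 - 90))])
            out[e] = snapped
    return out
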