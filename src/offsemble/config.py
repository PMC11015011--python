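"""Validated pipeline configuration (schema-versioned, unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScheduleConfig(_Strict):
    duration_s: float = 300.0
    directions_deg: list[float] = Field(
        default_factory=lambda: [0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0]
    )
    reps_min: int = 6
    stim_dur_s: float = 2.0
    isi_min_s: float = 1.0
    isi_max_s: float = 5.0
    frame_period_s: float = 0.081


class PopulationSection(_Strict):
    n_neurons: int = 200
    orientations_deg: list[float] = Field(default_factory=lambda: [0.0, 45.0, 90.0, 135.0])
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


class RatesSection(_Strict):
    baseline: float = 0.2
    evoked_gain: float = 2.9
    suppression: float = 0.4
    interstim_gain: float = 2.0


class CalciumSection(_Strict):
    neuropil_level: float = 1.0
    noise_sd: float = 0.02


class BehaviorSection(_Strict):
    run_fraction: float = 0.3
    run_threshold_cm_s: float = 1.0
    min_run_fraction: float = 0.05


class PreprocessSection(_Strict):
    psnr_min_db: float = 10.0
    window_s: float = 0.5
    tau_indicator_s: float = 5.8
    lam_scale: float = 1.0


class DetectSection(_Strict):
    n_surrogates: int = 1000
    alpha_network: float = 0.05
    k_min: int = 2
    k_max: int = 10
    n_iter: int = 1000
    alpha_ensemble: float = 0.05


class AnalysisSection(_Strict):
    alpha_participation: float = 0.05
    alpha_tuning: float = 0.05


class PipelineConfig(_Strict):
    schema_version: int = 1
    seed: int = 0
    outdir: str = "results/pipeline"
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    population: PopulationSection = Field(default_factory=PopulationSection)
    rates: RatesSection = Field(default_factory=RatesSection)
    calcium: CalciumSection = Field(default_factory=CalciumSection)
    behavior: BehaviorSection = Field(default_factory=BehaviorSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    detect: DetectSection = Field(default_factory=DetectSection)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Read a YAML config (all keys optional, unknown keys rejected)."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    return PipelineConfig(**data)
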