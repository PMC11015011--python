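"""Stage orchestration: simulate -> preprocess -> detect -> participate ->
tune -> decode, with provenance and per-stage structured logging.

Each stage reads its inputs from the run directory and writes its outputs
there, so stages can be run individually (the CLI exposes them as
subcommands) or chained with :func:`run_pipeline`.  Every run writes a
``provenance.json`` carrying the config hash, the seed, and stage counts;
reruns with the same config are byte-for-byte idempotent.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .config import PipelineConfig
from .decoding import decode_units, neuron_set_confusions, tuned_neuron_pools
from .ensembles import detect_ensembles
from .signals import preprocess
from .synthgen import (
    PopulationConfig,
    RateParams,
    generate_population,
    generate_stimulus_schedule,
    simulate_behavior,
    simulate_raster,
    synthesize_calcium,
)
from .tuning import classify_cell_tuning, group_activity, trial_responses, tune_unit

log = logging.getLogger("offsemble")

STAGES = ("simulate", "preprocess", "detect", "participate", "tune", "decode")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _provenance(config: PipelineConfig, out: Path, **counts) -> None:
    path = out / "provenance.json"
    prov = json.loads(path.read_text()) if path.exists() else {}
    prov.update({"config_hash": config.config_hash(), "seed": config.seed,
                 "schema_version": config.schema_version})
    prov.setdefault("counts", {}).update(counts)
    path.write_text(json.dumps(prov, indent=1, sort_keys=True))


def stage_simulate(config: PipelineConfig) -> Path:
    out = _outdir(config)
    sch = config.schedule
    schedule = generate_stimulus_schedule(
        duration_s=sch.duration_s,
        directions=tuple(sch.directions_deg),
        reps_min=sch.reps_min,
        stim_dur_s=sch.stim_dur_s,
        isi_min_s=sch.isi_min_s,
        isi_max_s=sch.isi_max_s,
        frame_period_s=sch.frame_period_s,
        seed=config.seed,
    )
    gt = generate_population(PopulationConfig(**config.population.model_dump()), seed=config.seed)
    rates = RateParams(**config.rates.model_dump())
    raster = simulate_raster(gt, schedule, rates, seed=config.seed)
    traces = synthesize_calcium(
        raster, gt, schedule,
        neuropil_level=config.calcium.neuropil_level,
        noise_sd=config.calcium.noise_sd,
        seed=config.seed,
    )
    behavior = simulate_behavior(
        schedule.session_frames, config.behavior.run_fraction,
        seed=config.seed, frame_period_s=sch.frame_period_s,
    )
    oio.write_traces(out / "traces.h5", traces)
    oio.write_schedule(out / "schedule.csv", schedule)
    oio.write_behavior(out / "behavior.csv", behavior)
    oio.write_ground_truth(out / "ground_truth.json", gt)
    oio.write_raster_csv(out / "true_raster.csv", raster)
    log.info("simulate: %d neurons, %d frames, %d trials",
             gt.n_neurons, schedule.session_frames, schedule.n_trials)
    _provenance(config, out, n_neurons=gt.n_neurons, n_trials=schedule.n_trials)
    return out


def stage_preprocess(config: PipelineConfig) -> Path:
    out = _outdir(config)
    traces = oio.load_traces(out / "traces.h5")
    raster, qc, _ = preprocess(
        traces,
        psnr_min=config.preprocess.psnr_min_db,
        window_s=config.preprocess.window_s,
        tau_indicator_s=config.preprocess.tau_indicator_s,
        lam_scale=config.preprocess.lam_scale,
    )
    oio.write_raster_csv(out / "raster.csv", raster)
    qc.to_frame().to_csv(out / "qc.csv", index=False)
    log.info("preprocess: %d/%d ROIs passed QC", int(qc.passed.sum()), len(qc.passed))
    _provenance(config, out, rois_passed=int(qc.passed.sum()))
    return out


def stage_detect(config: PipelineConfig) -> Path:
    out = _outdir(config)
    raster = oio.load_raster_csv(out / "raster.csv")
    d = config.detect
    model = detect_ensembles(
        raster, n_surrogates=d.n_surrogates, alpha_network=d.alpha_network,
        k_min=d.k_min, k_max=d.k_max, n_iter=d.n_iter,
        alpha_ensemble=d.alpha_ensemble, seed=config.seed,
    )
    labels = model.labels_full(raster.n_frames)
    pd.DataFrame(
        {
            "frame": np.arange(raster.n_frames),
            "cluster": labels,
            "is_ensemble": np.isin(labels, model.ensemble_ids),
        }
    ).to_csv(out / "frame_labels.csv", index=False)
    (out / "ensemble_pvalues.json").write_text(
        json.dumps({str(k): v for k, v in model.cluster_pvalues.items()})
    )
    sig = pd.DataFrame(model.ensemble_signals)
    sig.insert(0, "frame", np.arange(raster.n_frames))
    sig.to_csv(out / "ensemble_signals.csv", index=False)
    log.info("detect: k*=%d, %d significant ensembles", model.n_clusters,
             len(model.ensemble_ids))
    _provenance(config, out, k_star=model.n_clusters, n_ensembles=len(model.ensemble_ids))
    return out


def _load_model_signals(out: Path) -> dict[int, np.ndarray]:
    sig = pd.read_csv(out / "ensemble_signals.csv").drop(columns=["frame"])
    return {int(c): sig[c].to_numpy(np.uint8) for c in sig.columns}


def stage_participate(config: PipelineConfig) -> Path:
    out = _outdir(config)
    raster = oio.load_raster_csv(out / "raster.csv")
    signals = _load_model_signals(out)
    from .participation import classify_participation, exclusion_mask

    tables = []
    for e, sig in signals.items():
        others = [s for o, s in signals.items() if o != e]
        exclude = exclusion_mask(sig.astype(bool), others)
        try:
            t = classify_participation(
                raster, sig, alpha=config.analysis.alpha_participation,
                exclude_mask=exclude,
            )
        except ValueError as exc:  # e.g. a single contiguous occurrence run
            log.warning("skipping ensemble %s: %s", e, exc)
            continue
        t.insert(1, "ensemble_id", e)
        tables.append(t)
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    table.to_csv(out / "participation.csv", index=False)
    log.info("participate: %d records over %d ensembles", len(table), len(signals))
    _provenance(config, out, participation_records=len(table))
    return out


def stage_tune(config: PipelineConfig) -> Path:
    out = _outdir(config)
    raster = oio.load_raster_csv(out / "raster.csv")
    schedule = oio.load_schedule(out / "schedule.csv")
    signals = _load_model_signals(out)
    part = pd.read_csv(out / "participation.csv")
    alpha = config.analysis.alpha_tuning

    rows = []
    for e, sig in signals.items():
        res = tune_unit(sig, schedule, alpha=alpha)
        rows.append(
            {
                "unit_id": f"ensemble_{e}", "unit_kind": "ensemble", "osi": res.osi,
                "theta_pref_deg": res.theta_pref_deg, "p": res.hotelling_p,
                "significant": res.significant,
                "a": res.curve.a if res.curve else np.nan,
                "sigma_deg": res.curve.sigma_deg if res.curve else np.nan,
            }
        )
        sub = part[part["ensemble_id"] == e]
        members = {
            "onsemble": sub.loc[sub["class"] == "onsemble", "neuron_id"].to_numpy(int),
            "offsemble": sub.loc[sub["class"] == "offsemble", "neuron_id"].to_numpy(int),
        }
        for group in ("onsemble", "offsemble", "ensemble_dagger"):
            try:
                act = group_activity(raster, members, group)
            except (ValueError, KeyError):
                continue
            gres = tune_unit(act, schedule, alpha=alpha)
            rows.append(
                {
                    "unit_id": f"{group}_{e}", "unit_kind": group, "osi": gres.osi,
                    "theta_pref_deg": gres.theta_pref_deg, "p": gres.hotelling_p,
                    "significant": gres.significant,
                    "a": gres.curve.a if gres.curve else np.nan,
                    "sigma_deg": gres.curve.sigma_deg if gres.curve else np.nan,
                }
            )
    classes = [
        classify_cell_tuning(raster.spikes[n], schedule, alpha=alpha)
        for n in range(raster.n_neurons)
    ]
    pd.DataFrame(classes, columns=["cls", "theta_pref_deg"]).assign(
        neuron_id=np.arange(raster.n_neurons)
    ).to_csv(out / "cell_classes.csv", index=False)
    pd.DataFrame(rows).to_csv(out / "tuning.csv", index=False)
    n_tuned = sum(1 for c, _ in classes if c == "tuned")
    log.info("tune: %d tuned neurons, %d unit rows", n_tuned, len(rows))
    _provenance(config, out, tuned_neurons=n_tuned)
    return out


def stage_decode(config: PipelineConfig) -> Path:
    out = _outdir(config)
    raster = oio.load_raster_csv(out / "raster.csv")
    schedule = oio.load_schedule(out / "schedule.csv")
    signals = _load_model_signals(out)
    tuning = pd.read_csv(out / "tuning.csv")
    classes_df = pd.read_csv(out / "cell_classes.csv")
    cell_classes = list(zip(classes_df["cls"], classes_df["theta_pref_deg"]))
    trial_oris = np.array([t.orientation_deg for t in schedule.trials])

    summary: dict[str, float] = {}
    # Ensembles: one tuned ensemble per orientation, decoded jointly.
    ens = tuning[(tuning.unit_kind == "ensemble") & tuning.significant]
    chosen: dict[float, np.ndarray] = {}
    for _, row in ens.sort_values("osi", ascending=False).iterrows():
        o = float(row.theta_pref_deg)
        e = int(row.unit_id.split("_")[1])
        oris = schedule.orientations
        snapped = float(oris[np.argmin(np.abs((oris - o + 90) % 180 - 90))])
        if snapped not in chosen:
            chosen[snapped] = trial_responses(signals[e], schedule)["response"].to_numpy()
    if len(chosen) == 4:
        summary["accuracy_ensemble"] = decode_units(chosen, trial_oris, seed=config.seed).accuracy
    pools = tuned_neuron_pools(raster, schedule, cell_classes)
    if all(len(v) for v in pools.values()):
        rep = neuron_set_confusions(pools, trial_oris, seed=config.seed)
        summary["accuracy_neuron_sets"] = rep.accuracy
        summary["n_neuron_sets"] = rep.n_sets_averaged
        rep.matrix.to_csv(out / "confusion_neurons.csv")
    (out / "decode_summary.json").write_text(json.dumps(summary, indent=1))
    log.info("decode: %s", summary)
    _provenance(config, out, **{k: v for k, v in summary.items()})
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "detect": stage_detect,
    "participate": stage_participate,
    "tune": stage_tune,
    "decode": stage_decode,
}


def run_stage(name: str, config: PipelineConfig) -> Path:
    try:
        return _STAGE_FUNCS[name](config)
    except KeyError:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    except FileNotFoundError as exc:
        raise StageError(name, exc) from exc
    except Exception as exc:
        raise StageError(name, exc) from exc


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in order; halts with a stage-named error."""
    out = None
    for name in STAGES:
        out = run_stage(name, config)
    return out
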