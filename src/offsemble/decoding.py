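"""Orientation decoding via informedness-optimal thresholds and confusions.

Each unit (neuron, ensemble, or member group) is turned into a one-vs-rest
binary predictor of its assigned orientation by scanning all response
cutoffs in both inequality directions and keeping the operating point that
maximizes informedness (hit rate minus false-alarm rate).  Four predictors
(one per orientation) vote per trial; the 4x4 confusion matrix and its
accuracy (diagonal / total trials) summarize performance.  A removal control
re-runs ensemble detection after deleting offsemble members (or a matched
count of least-participating nonparticipants) to quantify how inactivation
contributes to orientation encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensembles import detect_ensembles
from .participation import participation_table
from .synthgen import Raster, StimulusSchedule, substream
from .tuning import trial_responses, tune_unit

GE, LE = ">=", "<="


@dataclass
class ThresholdedPredictor:
    orientation_deg: float
    threshold: float
    direction: str  # GE for responsive units, LE for anti-responsive ones
    informedness: float
    flagged: bool = False  # constant responses: no informative operating point

    def margin(self, responses: np.ndarray) -> np.ndarray:
        """Signed distance past the operating point (>= 0 means 'fires')."""
        r = np.asarray(responses, dtype=float)
        return r - self.threshold if self.direction == GE else self.threshold - r


@dataclass
class ConfusionReport:
    matrix: pd.DataFrame  # true orientation x predicted, trial counts
    accuracy: float
    n_sets_averaged: int = 1


def _informedness(pred_pos: np.ndarray, is_pos: np.ndarray) -> float:
    tpr = pred_pos[is_pos].mean() if is_pos.any() else 0.0
    fpr = pred_pos[~is_pos].mean() if (~is_pos).any() else 0.0
    return float(tpr - fpr)


def optimal_threshold(
    responses: np.ndarray,
    is_positive: np.ndarray,
    orientation_deg: float = np.nan,
) -> ThresholdedPredictor:
    """Informedness-maximal cutoff over all distinct responses x directions.

    Ties resolve to the lower threshold with the >= direction preferred, so
    the scan is deterministic.  Constant responses give informedness 0 and a
    flagged predictor.
    """
    r = np.asarray(responses, dtype=float)
    pos = np.asarray(is_positive, dtype=bool)
    if not pos.any() or pos.all():
        raise ValueError("need at least one positive and one negative trial")
    cutoffs = np.unique(r)
    if cutoffs.size == 1:
        return ThresholdedPredictor(orientation_deg, float(cutoffs[0]), GE, 0.0, flagged=True)
    best: ThresholdedPredictor | None = None
    for direction in (GE, LE):
        for c in cutoffs:
            fires = r >= c if direction == GE else r <= c
            j = _informedness(fires, pos)
            if best is None or j > best.informedness:
                best = ThresholdedPredictor(orientation_deg, float(c), direction, j)
    return best


def predict_trials(
    predictors: list[ThresholdedPredictor],
    responses: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Predicted orientation per trial from four one-vs-rest predictors.

    ``responses`` is (n_trials, 4), column i belonging to predictors[i].
    The winner is the predictor with the largest signed margin beyond its
    operating point (also resolving the none-fires and multiple-fire cases);
    exact margin ties break by a seeded uniform choice.
    """
    if len(predictors) != 4:
        raise ValueError("exactly four predictors required, one per orientation")
    resp = np.atleast_2d(np.asarray(responses, dtype=float))
    if resp.shape[1] != len(predictors):
        raise ValueError("responses must have one column per predictor")
    margins = np.column_stack([p.margin(resp[:, i]) for i, p in enumerate(predictors)])
    rng = substream(seed, "decode-ties")
    out = np.empty(resp.shape[0])
    oris = np.array([p.orientation_deg for p in predictors])
    for t in range(resp.shape[0]):
        m = margins[t]
        winners = np.flatnonzero(m == m.max())
        out[t] = oris[winners[0] if winners.size == 1 else rng.choice(winners)]
    return out


def confusion_and_accuracy(
    predicted: np.ndarray,
    true_orientations: np.ndarray,
    orientations: np.ndarray | None = None,
) -> ConfusionReport:
    """Orientation-by-orientation trial counts and trace accuracy."""
    pred = np.asarray(predicted, dtype=float)
    true = np.asarray(true_orientations, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("predicted and true vectors differ in length")
    if orientations is None:
        orientations = np.unique(true)
    mat = pd.DataFrame(0, index=orientations, columns=orientations, dtype=int)
    for t, p in zip(true, pred):
        mat.loc[t, p] += 1
    accuracy = float(np.trace(mat.to_numpy()) / len(true))
    return ConfusionReport(matrix=mat, accuracy=accuracy)


def decode_units(
    unit_responses: dict[float, np.ndarray],
    trial_orientations: np.ndarray,
    seed: int = 0,
) -> ConfusionReport:
    """One predictor per orientation from its unit's responses, then decode.

    ``unit_responses`` maps orientation -> that unit's per-trial responses
    (aligned with ``trial_orientations``).
    """
    oris = sorted(unit_responses)
    preds = [
        optimal_threshold(unit_responses[o], trial_orientations == o, orientation_deg=o)
        for o in oris
    ]
    resp = np.column_stack([unit_responses[o] for o in oris])
    predicted = predict_trials(preds, resp, seed=seed)
    return confusion_and_accuracy(predicted, trial_orientations, np.asarray(oris))


def neuron_set_confusions(
    tuned_pools: dict[float, list[np.ndarray]],
    trial_orientations: np.ndarray,
    seed: int = 0,
) -> ConfusionReport:
    """Average confusion over disjoint random quadruples of tuned neurons.

    ``tuned_pools`` maps orientation -> list of per-trial response vectors of
    neurons tuned to it.  Quadruples (one neuron per orientation) are drawn
    without replacement until the smallest pool is exhausted; matrices are
    averaged as counts.
    """
    oris = sorted(tuned_pools)
    if len(oris) != 4:
        raise ValueError("four orientation pools required")
    if any(len(tuned_pools[o]) == 0 for o in oris):
        raise ValueError("every orientation pool needs >= 1 tuned neuron")
    rng = substream(seed, "neuron-sets")
    n_sets = min(len(tuned_pools[o]) for o in oris)
    order = {o: rng.permutation(len(tuned_pools[o])) for o in oris}
    mats = []
    accs = []
    for s in range(n_sets):
        unit_resp = {o: tuned_pools[o][order[o][s]] for o in oris}
        rep = decode_units(unit_resp, trial_orientations, seed=seed + s)
        mats.append(rep.matrix)
        accs.append(rep.accuracy)
    avg = sum(m.to_numpy() for m in mats) / n_sets
    matrix = pd.DataFrame(avg, index=mats[0].index, columns=mats[0].columns)
    accuracy = float(np.trace(avg) / len(trial_orientations))
    return ConfusionReport(matrix=matrix, accuracy=accuracy, n_sets_averaged=n_sets)


def removal_control(
    raster: Raster,
    participation: pd.DataFrame,
    ensemble_orientations: dict[int, float],
    schedule: StimulusSchedule,
    mode: str,
    seed: int = 0,
    alpha: float = 0.05,
    n_patterns: int | None = None,
    detect_kwargs: dict | None = None,
) -> dict:
    """Re-run detection after removing offsemble (or matched control) neurons.

    mode='offsemble': remove the union of offsemble members of every
    orientation-encoding ensemble.  mode='nonparticipant': remove an equal
    count of neurons that participate in none of those ensembles, choosing
    the least participating (smallest mean |EPI|).  Detection re-runs with k
    forced to the original significant-ensemble count; the summary reports
    how many detected patterns remain orientation-tuned and their mean
    selectivity and tuning width.
    """
    if mode not in ("offsemble", "nonparticipant"):
        raise ValueError("mode must be 'offsemble' or 'nonparticipant'")
    ens_ids = list(ensemble_orientations)
    sub = participation[participation["ensemble_id"].isin(ens_ids)]
    off_union = np.unique(
        sub.loc[sub["class"] == "offsemble", "neuron_id"].to_numpy(dtype=int)
    )
    n_remove = off_union.size
    if n_remove >= raster.n_neurons:
        raise ValueError("removal would exceed the population")

    if mode == "offsemble":
        removed = off_union
    else:
        per_neuron = sub.groupby("neuron_id").agg(
            any_member=("class", lambda c: (c != "nonparticipant").any()),
            mean_abs_epi=("epi", lambda e: np.nanmean(np.abs(e))),
        )
        candidates = per_neuron[~per_neuron["any_member"]].sort_values("mean_abs_epi")
        removed = candidates.index.to_numpy(dtype=int)[:n_remove]
        if removed.size < n_remove:  # not enough strict nonparticipants: relax
            extra_pool = per_neuron.drop(index=removed).sort_values("mean_abs_epi")
            extra_pool = extra_pool[~extra_pool.index.isin(off_union)]
            removed = np.concatenate(
                [removed, extra_pool.index.to_numpy(dtype=int)[: n_remove - removed.size]]
            )

    keep = np.setdiff1d(np.arange(raster.n_neurons), removed)
    reduced = Raster(raster.spikes[keep], raster.frame_period_s)
    kwargs = dict(detect_kwargs or {})
    # Re-identify the same original number of activity patterns.
    kwargs["forced_k"] = n_patterns if n_patterns is not None else len(ens_ids)
    model = detect_ensembles(reduced, seed=seed, **kwargs)

    osis, sigmas, n_tuned = [], [], 0
    for e in model.ensemble_ids:
        res = tune_unit(model.ensemble_signals[e], schedule, alpha=alpha)
        if res.significant:
            n_tuned += 1
            osis.append(res.osi)
            sigmas.append(res.curve.sigma_deg)
    return {
        "mode": mode,
        "n_removed": int(n_remove),
        "removed": removed,
        "n_significant": len(model.ensemble_ids),
        "n_orientation_tuned": n_tuned,
        "mean_osi": float(np.mean(osis)) if osis else np.nan,
        "mean_sigma_deg": float(np.mean(sigmas)) if sigmas else np.nan,
    }


def tuned_neuron_pools(
    raster: Raster,
    schedule: StimulusSchedule,
    cell_classes: list[tuple[str, float]],
    neuron_ids: np.ndarray | None = None,
) -> dict[float, list[np.ndarray]]:
    """Per-orientation pools of trial-response vectors of tuned neurons."""
    if neuron_ids is None:
        neuron_ids = np.arange(raster.n_neurons)
    pools: dict[float, list[np.ndarray]] = {float(o): [] for o in schedule.orientations}
    for n in neuron_ids:
        cls, theta = cell_classes[n]
        if cls == "tuned":
            resp = trial_responses(raster.spikes[n], schedule)["response"].to_numpy()
            pools[float(theta)].append(resp)
    return pools
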