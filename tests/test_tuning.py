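"""Trial responses, selectivity, Hotelling test, Gaussian fits, cell classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from offsemble.synthgen import (
    PopulationConfig,
    RateParams,
    Raster,
    generate_population,
    generate_stimulus_schedule,
    simulate_raster,
    substream,
)
from offsemble.tuning import (
    activation_probability,
    classify_cell_tuning,
    ensemble_composition,
    evoked_duration,
    fit_tuning_curve,
    group_activity,
    hotelling_test,
    orientation_selectivity,
    trial_responses,
    tune_unit,
)

DT = 0.081
ORIS = [0.0, 45.0, 90.0, 135.0]


def _responses(values_by_ori, reps=6):
    rows = []
    i = 0
    for o, v in values_by_ori.items():
        vals = v if np.iterable(v) else [v] * reps
        for r in vals:
            rows.append({"trial": i, "orientation_deg": o, "response": float(r)})
            i += 1
    return pd.DataFrame(rows)


class TestGroupActivity:
    def test_fraction_counts_members(self):
        x = np.zeros((4, 3), np.uint8)
        x[:2, 0] = 1  # 2 of 4 active in frame 0
        x[:, 1] = 1
        raster = Raster(x, DT)
        act = group_activity(raster, {"onsemble": np.arange(4)}, "onsemble")
        assert act.tolist() == [0.5, 1.0, 0.0]

    def test_dagger_counts_active_on_plus_silent_off(self):
        x = np.zeros((4, 2), np.uint8)
        x[0, 0] = x[1, 0] = 1  # both onsemble members active, both off silent
        raster = Raster(x, DT)
        members = {"onsemble": np.array([0, 1]), "offsemble": np.array([2, 3])}
        act = group_activity(raster, members, "ensemble_dagger")
        assert act[0] == 1.0
        assert act[1] == 0.5  # on silent (0) + off silent (2) over 4

    def test_empty_group_rejected(self):
        raster = Raster(np.zeros((2, 2), np.uint8), DT)
        with pytest.raises(ValueError):
            group_activity(raster, {"onsemble": np.array([], int)}, "onsemble")


class TestTrialResponses:
    def test_mean_over_trial_window(self):
        sch = generate_stimulus_schedule(seed=0)
        act = np.zeros(sch.session_frames)
        t0 = sch.trials[0]
        half = t0.duration_frames // 2
        act[t0.onset_frame : t0.onset_frame + half] = 1.0
        resp = trial_responses(act, sch)
        assert resp.loc[0, "response"] == pytest.approx(half / t0.duration_frames)
        assert (resp.loc[1:, "response"] == 0).all()

    def test_activity_outside_trials_ignored(self):
        sch = generate_stimulus_schedule(seed=0)
        act = (~sch.stimulus_mask()).astype(float)  # active only between trials
        assert (trial_responses(act, sch)["response"] == 0).all()


class TestOrientationSelectivity:
    def test_single_orientation_response_fully_selective(self):
        osi, theta = orientation_selectivity(_responses({0.0: 1.0, 45.0: 0, 90.0: 0, 135.0: 0}))
        assert osi == pytest.approx(1.0)
        assert theta == pytest.approx(0.0)

    def test_flat_responses_unselective(self):
        osi, _ = orientation_selectivity(_responses({o: 0.5 for o in ORIS}))
        assert osi == pytest.approx(0.0, abs=1e-12)

    def test_half_selective_reference_point(self):
        osi, theta = orientation_selectivity(
            _responses({0.0: 1.0, 45.0: 0.5, 90.0: 0.0, 135.0: 0.5})
        )
        assert osi == pytest.approx(0.5)
        assert theta == pytest.approx(0.0)

    def test_all_zero_undefined(self):
        osi, theta = orientation_selectivity(_responses({o: 0.0 for o in ORIS}))
        assert np.isnan(osi) and np.isnan(theta)

    @given(st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=20)
    def test_scale_invariance(self, c):
        base = _responses({0.0: 1.0, 45.0: 0.3, 90.0: 0.1, 135.0: 0.2})
        scaled = base.assign(response=base["response"] * c)
        assert orientation_selectivity(base)[0] == pytest.approx(
            orientation_selectivity(scaled)[0]
        )

    @given(st.sampled_from([45.0, 90.0, 135.0]))
    @settings(deadline=None, max_examples=10)
    def test_preferred_orientation_equivariant_under_rotation(self, shift):
        base = _responses({0.0: 1.0, 45.0: 0.4, 90.0: 0.1, 135.0: 0.4})
        rotated = base.assign(orientation_deg=(base["orientation_deg"] + shift) % 180)
        t0 = orientation_selectivity(base)[1]
        t1 = orientation_selectivity(rotated)[1]
        assert t1 == pytest.approx((t0 + shift) % 180, abs=1e-9)


class TestHotelling:
    def test_strongly_tuned_unit_significant(self):
        rng = substream(0, "hot2")
        resp = _responses({0.0: rng.uniform(0.8, 1.0, 12), 45.0: rng.uniform(0, 0.05, 12),
                           90.0: rng.uniform(0, 0.05, 12), 135.0: rng.uniform(0, 0.05, 12)})
        assert hotelling_test(resp) < 0.01

    def test_null_rejection_rate_calibrated(self):
        """Under an i.i.d. null (orientation randomized per trial, so the
        doubled-angle vectors have mean zero) the rejection rate sits at the
        nominal level.  With a balanced fixed design the test is conservative
        by construction: the between-orientation spread inflates the trial
        covariance."""
        rng = substream(1, "hotnull2")
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            oris = rng.choice(ORIS, 24)
            resp = pd.DataFrame(
                {"orientation_deg": oris, "response": rng.random(24)}
            )
            rejections += hotelling_test(resp) < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 2 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01

    def test_all_zero_responses_degenerate(self):
        assert hotelling_test(_responses({o: 0.0 for o in ORIS})) == 1.0

    def test_matches_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = substream(2, "hotref")
        for _ in range(5):
            resp = _responses({o: rng.random(6) for o in ORIS})
            theta = np.deg2rad(resp["orientation_deg"].to_numpy() * 2)
            r = resp["response"].to_numpy()
            X = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            ref = pg.multivariate_ttest(X, Y=None).loc["hotelling", "pval"]
            assert hotelling_test(resp) == pytest.approx(ref, rel=1e-9)


class TestTuningCurve:
    def test_noiseless_gaussian_recovered(self):
        true = dict(a=0.8, theta=90.0, sigma=20.0)
        means = pd.Series(
            {o: true["a"] * np.exp(-(((o - true["theta"] + 90) % 180 - 90) ** 2)
                                   / (2 * true["sigma"] ** 2)) for o in ORIS}
        )
        curve = fit_tuning_curve(means)
        assert curve.a == pytest.approx(0.8, abs=1e-4)
        assert curve.theta_pref_deg == pytest.approx(90.0, abs=1e-3)
        assert curve.sigma_deg == pytest.approx(20.0, abs=1e-3)
        assert curve(90.0) == pytest.approx(curve.a)

    def test_flat_responses_peg_sigma_at_bound(self):
        curve = fit_tuning_curve(pd.Series({o: 0.5 for o in ORIS}))
        assert curve.at_bounds
        assert curve.sigma_deg == pytest.approx(90.0, rel=1e-3)

    def test_matches_degree_grid_search(self):
        rng = substream(3, "grid")
        means = pd.Series({o: float(rng.random() * 0.8) for o in ORIS})
        curve = fit_tuning_curve(means)
        thetas = means.index.to_numpy(float)
        resp = means.to_numpy()
        best = np.inf
        for a in np.linspace(0, 1, 51):
            for tp in np.arange(-45.0, 180.0, 1.0):
                for sg in np.arange(1.0, 91.0, 1.0):
                    d = (thetas - tp + 90) % 180 - 90
                    rss = np.sum((a * np.exp(-d**2 / (2 * sg**2)) - resp) ** 2)
                    best = min(best, rss)
        assert curve.fit_rss <= best + 1e-6


class TestResponseTiming:
    def _unit(self, seed=0, reliable=True):
        sch = generate_stimulus_schedule(seed=seed)
        act = np.zeros(sch.session_frames)
        for t in sch.trials:
            if t.orientation_deg == 0.0:
                act[t.onset_frame + 5] = 1.0
                if reliable:
                    act[t.onset_frame + 6 : t.onset_frame + 10] = 1.0
        return sch, act

    def test_always_active_unit_has_unit_probability(self):
        sch, act = self._unit()
        prob, peak, latency = activation_probability(act, sch, 0.0)
        assert peak == 1.0
        assert latency == pytest.approx(5 * DT, abs=1e-9)

    def test_silent_unit_flat_zero(self):
        sch, _ = self._unit()
        prob, peak, _ = activation_probability(np.zeros(sch.session_frames), sch, 0.0)
        assert peak == 0.0 and np.all(prob == 0)

    def test_partial_reliability_counted(self):
        sch = generate_stimulus_schedule(seed=1)
        act = np.zeros(sch.session_frames)
        pref = [t for t in sch.trials if t.orientation_deg == 0.0]
        for i, t in enumerate(pref):
            if i % 2 == 0:
                act[t.onset_frame + 3] = 1.0
        _, peak, _ = activation_probability(act, sch, 0.0)
        n = len(pref)
        assert peak == pytest.approx(np.ceil(n / 2) / n)

    def test_evoked_duration_full_window_and_frames(self):
        sch, act = self._unit()
        # activity spanning a full trial window
        full = np.zeros(sch.session_frames)
        for t in sch.trials:
            if t.orientation_deg == 0.0:
                full[t.onset_frame : t.onset_frame + t.duration_frames] = 1.0
        d = evoked_duration(full, sch, 0.0)
        dur = sch.trials[0].duration_frames
        assert d == pytest.approx(dur * DT)
        assert evoked_duration(np.zeros(sch.session_frames), sch, 0.0) == 0.0

    def test_ten_frames_is_810_ms(self):
        sch = generate_stimulus_schedule(seed=2, frame_period_s=0.081)
        act = np.zeros(sch.session_frames)
        for t in sch.trials:
            if t.orientation_deg == 45.0:
                act[t.onset_frame : t.onset_frame + 10] = 1.0
        assert evoked_duration(act, sch, 45.0) == pytest.approx(0.81)


class TestCellClassification:
    def test_planted_tuned_neurons_recovered(self):
        sch = generate_stimulus_schedule(seed=4)
        cfg = PopulationConfig(n_neurons=40, onsemble_overlap=0.0, frac_interstim=0.0,
                               tuning_width_deg=10.0)
        gt = generate_population(cfg, seed=4)
        rates = RateParams(baseline=0.02, evoked_gain=25.0, suppression=1.0,
                           interstim_gain=1.0)
        raster = simulate_raster(gt, sch, rates, seed=4)
        hits = total = 0
        for n in range(gt.n_neurons):
            if gt.neuron_class[n] == "tuned":
                total += 1
                cls, theta = classify_cell_tuning(raster.spikes[n], sch)
                hits += cls == "tuned" and theta == gt.neuron_pref_deg[n]
        assert total > 0
        assert hits / total >= 0.95

    def test_interstim_neuron_by_construction(self):
        sch = generate_stimulus_schedule(seed=5)
        rng = substream(5, "isi")
        isi = ~sch.stimulus_mask()
        spikes = ((rng.random(sch.session_frames) < 0.3) & isi).astype(np.uint8)
        cls, _ = classify_cell_tuning(spikes, sch)
        assert cls == "interstim"

    def test_homogeneous_neuron_usually_untuned(self):
        sch = generate_stimulus_schedule(seed=6)
        rng = substream(6, "hom")
        untuned = 0
        n_rep = 200
        for _ in range(n_rep):
            spikes = (rng.random(sch.session_frames) < 0.1).astype(np.uint8)
            cls, _ = classify_cell_tuning(spikes, sch)
            untuned += cls == "untuned"
        # two alpha=0.05 tests in sequence: expect ~(1 - alpha)^2
        assert 0.85 <= untuned / n_rep <= 0.99


class TestEnsembleComposition:
    def test_pref_counting_and_conservation(self):
        part = pd.DataFrame(
            {
                "neuron_id": [0, 1, 2, 3],
                "ensemble_id": [1, 1, 1, 1],
                "epi": [0.5, -0.5, 0.1, 0.6],
                "p_value": [0.01, 0.01, 0.5, 0.01],
                "class": ["onsemble", "offsemble", "nonparticipant", "onsemble"],
            }
        )
        cell_classes = [("tuned", 0.0), ("tuned", 90.0), ("untuned", np.nan),
                        ("interstim", np.nan)]
        comp = ensemble_composition(part, cell_classes, {1: 0.0})
        by = comp.set_index(["group", "cls"])["count"]
        assert by.loc[("onsemble", "pref")] == 1
        assert by.loc[("offsemble", "nonpref")] == 1
        assert by.loc[("onsemble", "interstim")] == 1
        non_shared = comp[comp.cls != "shared"]
        assert non_shared["count"].sum() == 4


def test_tune_unit_integrates_selectivity_and_fit():
    sch = generate_stimulus_schedule(seed=7)
    act = np.zeros(sch.session_frames)
    for t in sch.trials:
        if t.orientation_deg == 90.0:
            act[t.onset_frame : t.onset_frame + t.duration_frames] = 1.0
    res = tune_unit(act, sch)
    assert res.significant
    assert res.osi > 0.9
    assert abs(res.theta_pref_deg - 90.0) < 5.0
    assert res.curve.sigma_deg < 30.0
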