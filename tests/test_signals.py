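"""Preprocessing chain: correction, PSNR QC, smoothing, deconvolution, decays."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from offsemble.signals import (
    TraceSet,
    binarization_threshold,
    binarize_spikes,
    build_raster,
    compute_psnr,
    decay_by_condition,
    condition_means,
    fit_decay,
    infer_spikes,
    neuropil_correct,
    preprocess,
    select_rois,
    smooth_trace,
)
from offsemble.synthgen import (
    PopulationConfig,
    RateParams,
    Raster,
    StimulusSchedule,
    generate_population,
    generate_stimulus_schedule,
    simulate_raster,
    synthesize_calcium,
)

DT = 0.081


class TestNeuropilCorrection:
    @pytest.mark.parametrize(
        "roi, npil, expected",
        [
            (np.full(5, 2.0), np.full(5, 1.0), np.full(5, 1.0)),
            (np.full(5, 3.0), np.full(5, 3.0), np.zeros(5)),
            (np.array([3.0, 1.0]), np.array([2.0, 2.0]), np.array([0.5, -0.5])),
        ],
    )
    def test_closed_form(self, roi, npil, expected):
        assert np.allclose(neuropil_correct(roi, npil), expected)

    def test_near_zero_neuropil_raises_naming_roi(self):
        roi = np.ones((2, 4))
        npil = np.ones((2, 4))
        npil[1, 2] = 0.0
        with pytest.raises(ZeroDivisionError, match="1"):
            neuropil_correct(roi, npil)


class TestPSNR:
    def test_reference_points(self):
        npil = np.array([0.0, 1.0, -1.0, 1.0, -1.0])  # std = sqrt(0.8)
        sd = np.std(npil)
        assert compute_psnr(npil + np.array([0, 0, 0, 0, sd]), npil) == pytest.approx(0.0)
        assert compute_psnr(npil + np.array([0, 0, 0, 0, 10 * sd]), npil) == pytest.approx(20.0)
        assert compute_psnr(npil + np.array([0, 0, 0, 0, 10**0.5 * sd]), npil) == pytest.approx(10.0)

    def test_zero_variance_neuropil_rejected(self):
        with pytest.raises(ValueError):
            compute_psnr(np.ones(5), np.ones(5))

    def test_nonpositive_peak_fails_qc(self):
        npil = np.array([1.0, 2.0, 1.0, 2.0])
        assert compute_psnr(npil - 1.0, npil) == -np.inf


class TestSelectROIs:
    def _traces(self, peaks):
        rng = np.random.default_rng(0)
        npil = rng.normal(1.0, 0.1, (len(peaks), 500))
        roi = npil.copy()
        # peak = k x the measured neuropil std, so PSNR = 20 log10(k) exactly
        roi[:, 100] += np.asarray(peaks) * npil.std(axis=1)
        return TraceSet(f_roi=roi, f_neuropil=npil, frame_period_s=DT)

    def test_strictly_above_threshold_survives(self):
        # PSNRs (5, 10, 15) dB around the 10 dB cut; the comparison is strict,
        # so a ROI sitting exactly at the cut is dropped
        traces = self._traces([10**0.25, 10**0.5, 10**0.75])
        mid = compute_psnr(traces.f_roi[1], traces.f_neuropil[1])
        assert mid == pytest.approx(10.0, abs=1e-6)
        kept, qc = select_rois(traces, psnr_min=mid)
        assert int(qc.passed.sum()) == 1
        assert kept.n_rois == 1
        _, qc_loose = select_rois(traces, psnr_min=mid, strict=False)
        assert int(qc_loose.passed.sum()) == 2

    def test_everyone_survives_with_minus_infinite_cut(self):
        traces = self._traces([2.0, 5.0, 9.0])
        kept, _ = select_rois(traces, psnr_min=-np.inf)
        assert kept.n_rois == 3

    def test_survivors_monotone_in_threshold(self):
        traces = self._traces([1.5, 3.0, 6.0, 12.0])
        survivors = []
        for cut in (-np.inf, 0.0, 5.0, 10.0):
            _, qc = select_rois(traces, psnr_min=cut)
            survivors.append(int(qc.passed.sum()))
        assert survivors == sorted(survivors, reverse=True)

    def test_empty_cohort_raises(self):
        traces = self._traces([1.01, 1.02])
        with pytest.raises(ValueError, match="empty cohort"):
            select_rois(traces, psnr_min=60.0)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        x = np.full(100, 3.7)
        assert np.allclose(smooth_trace(x, 0.5, DT), x)

    def test_single_frame_blip_removed(self):
        x = np.zeros(60)
        x[30] = 5.0
        assert np.allclose(smooth_trace(x, 3 * DT, DT), 0.0)

    def test_wide_plateau_preserved(self):
        x = np.zeros(100)
        x[40:60] = 2.0  # plateau wider than the 7-frame window
        y = smooth_trace(x, 0.5, DT)
        assert np.allclose(y[43:57], 2.0)

    @given(
        hnp.arrays(np.float64, 50, elements=st.floats(-10, 10)),
        st.floats(-5, 5),
    )
    @settings(deadline=None, max_examples=30)
    def test_offset_equivariance(self, x, c):
        base = smooth_trace(x, 0.5, DT)
        shifted = smooth_trace(x + c, 0.5, DT)
        assert np.allclose(shifted, base + c, atol=1e-9)


class TestDeconvolution:
    def test_noiseless_ar1_transient_recovers_single_onset(self):
        gamma = np.exp(-DT / 5.8)
        c = np.zeros(300)
        for t in range(1, 300):
            c[t] = gamma * c[t - 1] + (1.0 if t == 80 else 0.0)
        s = infer_spikes(c, gamma=gamma, lam=0.0)
        nz = np.flatnonzero(s > 1e-9)
        assert list(nz) == [80]
        assert s[80] == pytest.approx(1.0)

    def test_flat_zero_trace_gives_zero_spikes(self):
        assert np.allclose(infer_spikes(np.zeros(100), gamma=0.95), 0.0)

    @given(hnp.arrays(np.float64, 80, elements=st.floats(-3, 3)))
    @settings(deadline=None, max_examples=30)
    def test_spikes_nonnegative_for_any_input(self, y):
        s = infer_spikes(y, gamma=0.9, lam=0.1)
        assert (s >= 0).all()

    def test_l1_penalty_shrinks_total_activity(self):
        rng = np.random.default_rng(0)
        y = np.abs(rng.normal(0, 1, 200))
        s0 = infer_spikes(y, gamma=0.9, lam=0.0).sum()
        s1 = infer_spikes(y, gamma=0.9, lam=1.0).sum()
        assert s1 <= s0


class TestBinarization:
    def test_threshold_from_psnr(self):
        assert binarization_threshold(10.0) == pytest.approx(0.02)
        s = np.array([0.01, 0.03])
        assert list(binarize_spikes(s, 10.0)) == [0, 1]

    def test_high_psnr_floors_threshold(self):
        assert binarization_threshold(20.0) == pytest.approx(0.01)

    def test_all_zero_series_stays_zero(self):
        assert binarize_spikes(np.zeros(10), 12.0).sum() == 0


class TestBuildRaster:
    def test_stacks_in_roi_order(self):
        rows = [np.zeros(100, dtype=np.uint8) for _ in range(3)]
        rows[1][5] = 1
        raster = build_raster(rows, DT)
        assert raster.spikes.shape == (3, 100)
        assert raster.spikes.sum(axis=1).tolist() == [0, 1, 0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_raster([], DT)

    def test_ragged_lengths_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_raster([np.zeros(10), np.zeros(11)], DT)


class TestDecayFit:
    def test_exact_exponential_recovered_to_1e6(self):
        t = np.arange(60) * DT
        trace = 1.0 * np.exp(-t / 2.5)
        fit = fit_decay(trace, (0, 60), DT)
        assert abs(fit.a - 1.0) < 1e-6
        assert abs(fit.tau_s - 2.5) < 1e-6
        assert not fit.at_bounds

    def test_constant_trace_pegs_tau_at_upper_bound(self):
        fit = fit_decay(np.full(40, 0.5), (0, 40), DT, tau_bounds=(0.05, 20.0))
        assert fit.at_bounds
        assert fit.tau_s == pytest.approx(20.0, rel=1e-3)

    def test_recovery_bias_small_at_moderate_noise(self):
        """tau bias < 5% at SNR 10 over 500 simulated decays."""
        rng = np.random.default_rng(0)
        t = np.arange(40) * DT
        taus = []
        for _ in range(500):
            trace = np.exp(-t / 2.0) + rng.normal(0, 0.1, t.size)
            try:
                fit = fit_decay(trace, (0, 40), DT)
            except ValueError:
                continue
            if not fit.at_bounds:
                taus.append(fit.tau_s)
        assert abs(np.mean(taus) - 2.0) / 2.0 < 0.05

    def test_log_linear_oracle_agreement_on_noiseless_data(self):
        t = np.arange(50) * DT
        trace = 0.7 * np.exp(-t / 4.2)
        slope, intercept = np.polyfit(t, np.log(trace), 1)
        fit = fit_decay(trace, (0, 50), DT)
        assert fit.tau_s == pytest.approx(-1.0 / slope, abs=1e-6)
        assert fit.a == pytest.approx(np.exp(intercept), abs=1e-6)


@pytest.fixture(scope="module")
def suppressed_cohort():
    sch = generate_stimulus_schedule(seed=3)
    cfg = PopulationConfig(
        n_neurons=40, frac_onsemble=0.0, frac_offsemble=0.5,
        off_from_other_onsembles=0.0, off_from_interstim=0.0,
        frac_interstim=0.0, tuning_width_deg=10.0, amplitude=1.0,
    )
    gt = generate_population(cfg, seed=3)
    rates = RateParams(baseline=0.008, evoked_gain=1.0, suppression=0.0,
                       interstim_gain=1.0)
    raster = simulate_raster(gt, sch, rates, seed=3)
    traces = synthesize_calcium(raster, gt, sch, noise_sd=0.005, seed=3)
    supp = np.full(gt.n_neurons, np.nan)
    for n in range(gt.n_neurons):
        offs = np.flatnonzero(gt.membership[n] == -1)
        if offs.size:
            supp[n] = gt.ensemble_orientations_deg[offs[0]]
    return traces, sch, supp


class TestDecayByCondition:
    def test_suppressed_decays_separate_from_preonset(self, suppressed_cohort):
        traces, sch, supp = suppressed_cohort
        means = condition_means(decay_by_condition(traces, sch, supp))
        assert means["during"] < means["pre_onset"]
        assert means["pre_onset"] / means["during"] > 2.0

    def test_no_stimulus_yields_only_spontaneous_condition(self, suppressed_cohort):
        traces, _, supp = suppressed_cohort
        df = decay_by_condition(traces, None, supp)
        assert set(df["condition"]) <= {"spontaneous"}
        assert len(df) > 0

    def test_uniform_kinetics_show_no_condition_difference(self):
        sch = generate_stimulus_schedule(seed=6)
        cfg = PopulationConfig(
            n_neurons=30, frac_onsemble=0.0, frac_offsemble=0.5,
            off_from_other_onsembles=0.0, off_from_interstim=0.0,
            frac_interstim=0.0, tau_decay_suppressed_s=5.8, amplitude=1.0,
        )
        gt = generate_population(cfg, seed=6)
        rates = RateParams(baseline=0.008, evoked_gain=1.0, suppression=1.0,
                           interstim_gain=1.0)
        raster = simulate_raster(gt, sch, rates, seed=6)
        traces = synthesize_calcium(raster, gt, sch, noise_sd=0.005, seed=6)
        supp = np.full(gt.n_neurons, np.nan)
        for n in range(gt.n_neurons):
            offs = np.flatnonzero(gt.membership[n] == -1)
            if offs.size:
                supp[n] = gt.ensemble_orientations_deg[offs[0]]
        means = condition_means(decay_by_condition(traces, sch, supp))
        if {"during", "pre_onset"} <= set(means.index):
            assert abs(means["during"] - means["pre_onset"]) / means["pre_onset"] < 0.35


def test_sparse_noiseless_chain_recovers_spike_frames():
    """Full preprocessing round trip: Jaccard >= 0.9 against the true raster."""
    cfg = PopulationConfig(n_neurons=50, frac_interstim=0.0)
    gt = generate_population(cfg, seed=4)
    sch = StimulusSchedule([], DT, 3000)
    rates = RateParams(baseline=0.02, evoked_gain=1.0, suppression=1.0, interstim_gain=1.0)
    raster = simulate_raster(gt, sch, rates, seed=4)
    traces = synthesize_calcium(raster, gt, schedule=None, noise_sd=0.0, seed=4)
    rec, qc, _ = preprocess(traces)
    a = rec.spikes.astype(bool)
    b = raster.spikes.astype(bool)
    assert (a & b).sum() / (a | b).sum() >= 0.9


def test_preprocessing_deterministic():
    gt = generate_population(PopulationConfig(n_neurons=10), seed=0)
    sch = StimulusSchedule([], DT, 800)
    raster = simulate_raster(gt, sch, RateParams(baseline=0.05, evoked_gain=1.0,
                                                 interstim_gain=1.0), seed=0)
    traces = synthesize_calcium(raster, gt, schedule=None, noise_sd=0.05, seed=0)
    r1, _, _ = preprocess(traces)
    r2, _, _ = preprocess(traces)
    assert np.array_equal(r1.spikes, r2.spikes)
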