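"""Synthetic-data generators: movies, tuning tables, chaining series."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from conftest import two_blob_truth
from songtune import synth
from songtune.behavior import chaining_index, summed_ci
from songtune.pipeline import run_behavior_pipeline
from songtune.segmentation import ROIMask, extract_traces
from songtune.stimulus import (PulseTrainSpec, make_intermittent_protocol,
                               make_ramp_protocol)
from songtune.traces import peak_dff, smooth_trace
from songtune.tuning import build_tuning


class TestTuningModels:
    def test_low_pass_saturates_above_35ms(self):
        m = synth.vpn1_like_model()
        r = m.response(np.array([15.0, 25.0, 35.0, 65.0, 95.0]))
        assert np.all(np.diff(r) > 0)            # monotone rise
        assert r[2] > 0.6 * m.r_max              # shoulder near 35 ms
        assert r[4] > 0.95 * m.r_max             # saturated at long IPI

    def test_band_pass_peaks_mid_band(self):
        m = synth.pc1_like_model()
        grid = synth.DEFAULT_IPI_GRID
        r = m.response(grid)
        assert grid[np.argmax(r)] in (35.0, 45.0, 55.0, 65.0)
        assert r[0] < 0.3 * r.max() and r[-1] < 0.3 * r.max()

    def test_kernel_peak_is_one_and_causal(self):
        k = synth.GCaMPKernel()
        t = np.linspace(-1.0, 5.0, 2000)
        v = k.evaluate(t)
        assert np.all(v[t < 0] == 0.0)
        assert v.max() == pytest.approx(1.0, abs=1e-4)

    def test_ground_truth_json_round_trip(self):
        truth = two_blob_truth(seed=9)
        back = synth.SyntheticGroundTruth.from_json(truth.to_json())
        assert back == truth


class TestSimulateMovie:
    def test_noise_free_pipeline_recovers_planted_amplitude(self):
        truth = synth.SyntheticGroundTruth(
            rois=[synth.BlobROI(20.0, 20.0, 3.0, 100.0)],
            tuning=synth.BandPassGaussian(r_max=0.8, center=50.0, width=15.0,
                                          baseline=0.0),
            noise_sd=0.0, seed=0)
        events = [{"onset": 3.0, "ipi_ms": 50.0}]
        movie = synth.simulate_movie(truth, events, duration_s=10.0,
                                     shape=(40, 40))
        mask = ROIMask(truth.roi_masks((40, 40)))
        trace = extract_traces(movie, mask)[0]
        resp = peak_dff(trace, 3.0)
        assert resp.peak_dff == pytest.approx(0.8, rel=0.01)

    def test_noise_sd_scales_trace_residual(self):
        base = dict(rois=[synth.BlobROI(20.0, 20.0, 3.0, 100.0)],
                    tuning=synth.pc1_like_model(), seed=0)
        sds = {}
        for noise_sd in (1.0, 2.0):
            truth = synth.SyntheticGroundTruth(noise_sd=noise_sd, **base)
            movie = synth.simulate_movie(truth, [], duration_s=8.0,
                                         shape=(40, 40), seed=5)
            trace = extract_traces(movie, ROIMask(truth.roi_masks((40, 40))))[0]
            sds[noise_sd] = trace.values.std()
        assert sds[2.0] / sds[1.0] == pytest.approx(2.0, rel=0.15)

    def test_no_events_movie_is_stationary(self):
        truth = two_blob_truth(seed=1)
        movie = synth.simulate_movie(truth, [], duration_s=5.0, shape=(48, 48))
        trace = extract_traces(movie, ROIMask(truth.roi_masks((48, 48))))[0]
        # only noise-level fluctuation around the static blob intensity
        assert trace.values.std() < 0.02 * trace.values.mean()

    def test_seed_determinism(self):
        truth = two_blob_truth(seed=2)
        ev = [{"onset": 2.0, "ipi_ms": 35.0}]
        a = synth.simulate_movie(truth, ev, 6.0, shape=(32, 32), seed=3)
        b = synth.simulate_movie(truth, ev, 6.0, shape=(32, 32), seed=3)
        np.testing.assert_array_equal(a.frames, b.frames)


class TestSimulateTuningTable:
    def test_single_subject_no_noise_matches_model(self):
        truth = synth.SyntheticGroundTruth(tuning=synth.pc1_like_model(),
                                           gain_sigma=0.0, seed=0)
        table = synth.simulate_tuning_table(truth, n_subjects=1, noise_sd=0.0)
        np.testing.assert_allclose(
            table["value"].to_numpy(),
            truth.tuning.response(synth.DEFAULT_IPI_GRID))

    def test_band_pass_group_argmax_in_mid_band(self):
        truth = synth.SyntheticGroundTruth(tuning=synth.pc1_like_model(), seed=4)
        table = synth.simulate_tuning_table(truth, n_subjects=12, seed=4)
        curve = build_tuning(table)
        assert curve.conditions[np.argmax(curve.mean)] in (35.0, 45.0, 55.0, 65.0)

    def test_gaussian_center_recovery(self):
        """Fitted band-pass center lands within 10 ms of truth (median over
        20 seeds, n = 12 subjects, 10% noise)."""
        def gauss(x, a, mu, sig, b):
            return b + a * np.exp(-(x - mu) ** 2 / (2 * sig ** 2))

        errs = []
        for seed in range(20):
            truth = synth.SyntheticGroundTruth(tuning=synth.pc1_like_model(),
                                               seed=seed)
            table = synth.simulate_tuning_table(truth, n_subjects=12,
                                                noise_sd=0.10, seed=seed)
            curve = build_tuning(table)
            popt, _ = curve_fit(gauss, curve.conditions, curve.mean,
                                p0=[1.0, 45.0, 20.0, 0.0], maxfev=10000)
            errs.append(abs(popt[1] - 50.0))
        assert np.median(errs) <= 10.0


class TestSimulateChaining:
    def test_saturated_probability_gives_max_ci(self):
        truth = synth.SyntheticGroundTruth(p_max=1.0, p_silence=1.0, seed=0)
        proto = make_ramp_protocol(PulseTrainSpec(), levels_db=[90.0])
        series = synth.simulate_chaining(truth, proto, n_groups=2)
        for s in series:
            assert chaining_index(s).ci_per_block.tolist() == [60, 60, 60]

    def test_silence_keeps_counts_near_zero(self):
        truth = synth.SyntheticGroundTruth(seed=1)
        proto = make_ramp_protocol(PulseTrainSpec(), levels_db=[60.0])
        series = synth.simulate_chaining(truth, proto, n_groups=4, seed=1)
        lead = [s.counts[:20].mean() for s in series]  # 60 s of silence
        assert np.mean(lead) < 0.5

    def test_ramp_recovers_planted_ec50(self):
        """Sigmoid fit of mean summed CI per level recovers the planted
        70.6 dB within 2 dB (median over 20 seeds, 14 groups)."""
        proto = make_ramp_protocol(PulseTrainSpec(ipi_ms=35.0))
        errs = []
        for seed in range(20):
            truth = synth.SyntheticGroundTruth(seed=seed)
            series = synth.simulate_chaining(truth, proto, n_groups=14,
                                             seed=seed)
            rep = run_behavior_pipeline(series, proto)
            errs.append(abs(rep["sigmoid_fit"].ec50 - truth.ec50_db))
        assert np.median(errs) <= 2.0

    def test_ipi_sweep_argmax_at_35ms(self):
        """With behavior weights planted to peak at 35 ms, the summed-CI
        argmax lands on the 35-ms grid cell in >= 80% of seeds."""
        grid = synth.DEFAULT_IPI_GRID
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            truth = synth.SyntheticGroundTruth(
                tuning=synth.BandPassGaussian(center=35.0, width=15.0,
                                              baseline=0.05),
                seed=seed)
            totals = []
            for ipi in grid:
                proto = make_intermittent_protocol(
                    PulseTrainSpec(ipi_ms=float(ipi)), lead_s=60.0,
                    total_song_s=120.0, tail_s=120.0)
                series = synth.simulate_chaining(truth, proto, n_groups=15,
                                                 seed=seed + 100 * int(ipi))
                window = tuple(proto.metadata["song_window"])
                totals.append(np.mean([summed_ci(chaining_index(s), window)
                                       for s in series]))
            if grid[np.argmax(totals)] == 35.0:
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_post_song_decay(self):
        truth = synth.SyntheticGroundTruth(seed=3, decay_tau_s=30.0)
        proto = make_intermittent_protocol(PulseTrainSpec(level_db=90.0))
        series = synth.simulate_chaining(truth, proto, n_groups=20, seed=3)
        counts = np.mean([s.counts for s in series], axis=0)
        t = series[0].sample_times
        song = counts[(t >= 60) & (t < 180)].mean()
        early_tail = counts[(t >= 180) & (t < 210)].mean()
        late_tail = counts[(t >= 270) & (t < 300)].mean()
        assert song > early_tail > late_tail

    def test_seed_determinism(self):
        truth = synth.SyntheticGroundTruth(seed=6)
        proto = make_ramp_protocol(PulseTrainSpec())
        a = synth.simulate_chaining(truth, proto, n_groups=3, seed=6)
        b = synth.simulate_chaining(truth, proto, n_groups=3, seed=6)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.counts, sb.counts)
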