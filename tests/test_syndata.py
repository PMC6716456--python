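"""Generator checks: VAR construction, simulation, hemodynamics, cohorts."""

import numpy as np
import pytest

from ecnet import syndata
from ecnet.types import ROITimeSeries


class TestMakeVarSpec:
    def test_planted_chain_lands_in_a1(self):
        spec = syndata.make_var_spec(2, 0.0, [(0, 1, 0.4)], seed=1, self_coupling=0.5)
        assert np.allclose(spec.A1, [[0.5, 0.4], [0.0, 0.5]])
        assert spec.spectral_radius() < 1

    def test_zero_weight_chain_equals_background_only(self):
        a = syndata.make_var_spec(5, 0.02, [(0, 1, 0.0)], seed=3)
        b = syndata.make_var_spec(5, 0.02, None, seed=3)
        b.A1[0, 1] = 0.0
        assert np.allclose(a.A1, b.A1)

    def test_deterministic_under_seed(self):
        a = syndata.make_var_spec(20, 0.05, [(0, 1, 0.3)], seed=11)
        b = syndata.make_var_spec(20, 0.05, [(0, 1, 0.3)], seed=11)
        assert np.array_equal(a.A1, b.A1)

    def test_unstable_spec_rejected_with_radius(self):
        # reciprocal strong coupling pushes an eigenvalue past 1
        with pytest.raises(ValueError, match="spectral radius"):
            syndata.make_var_spec(3, 0.0, [(0, 1, 0.6), (1, 0, 0.6)], self_coupling=0.8)

    def test_instantaneous_self_coupling_forbidden(self):
        A0 = np.eye(2) * 0.1
        with pytest.raises(ValueError, match="diagonal of A0"):
            syndata.VARSpec(k=2, A0=A0, A1=np.zeros((2, 2)))


class TestSimulateNeural:
    def test_uncoupled_noise_is_white(self):
        spec = syndata.make_var_spec(3, 0.0, None, self_coupling=0.0)
        ts = syndata.simulate_neural(spec, None, 4000, seed=0)
        x = ts.data
        T = x.shape[0]
        for j in range(3):
            r1 = np.corrcoef(x[:-1, j], x[1:, j])[0, 1]
            assert abs(r1) < 3.0 / np.sqrt(T)
        assert abs(np.corrcoef(x[:, 0], x[:, 1])[0, 1]) < 3.0 / np.sqrt(T)

    def test_ols_recovers_planted_coefficient(self):
        spec = syndata.make_var_spec(2, 0.0, [(0, 1, 0.4)], self_coupling=0.5)
        ts = syndata.simulate_neural(spec, None, 20000, seed=1)
        x = ts.data
        X = np.column_stack([x[:-1, 0], x[:-1, 1]])
        beta, *_ = np.linalg.lstsq(X, x[1:, 1], rcond=None)
        assert beta[0] == pytest.approx(0.4, abs=0.02)

    def test_windowed_ols_tracks_scheduled_step(self):
        spec = syndata.make_var_spec(2, 0.0, None, self_coupling=0.3)
        T = 8000
        sched = syndata.DynamicSchedule([
            syndata.EdgeModulation(0, 1, kind="step", before=0.0, after=0.8, switch_t=T // 2)
        ])
        x = syndata.simulate_neural(spec, sched, T, seed=2).data

        def ols(seg):
            X = np.column_stack([seg[:-1, 0], seg[:-1, 1]])
            return np.linalg.lstsq(X, seg[1:, 1], rcond=None)[0][0]

        assert abs(ols(x[: T // 2])) < 0.1
        assert ols(x[T // 2:]) == pytest.approx(0.8, abs=0.1)

    def test_short_series_rejected(self):
        spec = syndata.make_var_spec(5, 0.0, None)
        with pytest.raises(ValueError, match="too short"):
            syndata.simulate_neural(spec, None, 40)

    def test_unstable_schedule_rejected(self):
        spec = syndata.make_var_spec(2, 0.0, None, self_coupling=0.5)
        sched = syndata.DynamicSchedule([
            syndata.EdgeModulation(0, 1, kind="constant", mean=0.9),
            syndata.EdgeModulation(1, 0, kind="constant", mean=0.9),
        ])
        with pytest.raises(ValueError, match="unstable"):
            syndata.simulate_neural(spec, sched, 500, seed=0)


class TestHRF:
    def test_peak_lands_near_requested_time(self):
        h = syndata.hrf_double_gamma(peak_time=6.0, dt=0.6, duration=24.0)
        assert 5.4 <= np.argmax(h.samples) * h.dt <= 6.6
        assert h.samples.max() == pytest.approx(1.0)

    def test_cross_correlation_lag_matches_peak_offset(self):
        h5 = syndata.hrf_double_gamma(5.0, 15.0, dt=0.5)
        h7 = syndata.hrf_double_gamma(7.0, 17.0, dt=0.5)
        cc = np.correlate(h7.samples, h5.samples, "full")
        lag = (np.argmax(cc) - (h5.samples.size - 1)) * 0.5
        assert lag == pytest.approx(2.0, abs=0.5)

    def test_zero_undershoot_ratio_is_nonnegative(self):
        h = syndata.hrf_double_gamma(ratio=0.0, dt=0.5)
        assert np.all(h.samples >= 0)

    def test_bad_timing_rejected(self):
        with pytest.raises(ValueError):
            syndata.hrf_double_gamma(peak_time=30.0, dt=0.5, duration=24.0)


class TestConvolveBold:
    def test_delta_kernel_is_identity(self, rng):
        ts = ROITimeSeries(rng.normal(size=(200, 2)), tr=1.0)
        delta = syndata.HRFCurve(samples=np.r_[1.0, np.zeros(9)], dt=1.0)
        out = syndata.convolve_bold(ts, [delta, delta], obs_noise_sd=0.0)
        assert np.allclose(out.data, ts.data)

    def test_lagged_hrfs_delay_cross_correlation(self, rng):
        x = np.convolve(rng.normal(size=420), np.ones(3) / 3)[:400]
        ts = ROITimeSeries(np.column_stack([x, x]), tr=1.0)
        h5 = syndata.hrf_double_gamma(5.0, 15.0, dt=1.0)
        h7 = syndata.hrf_double_gamma(7.0, 17.0, dt=1.0)
        out = syndata.convolve_bold(ts, [h5, h7], obs_noise_sd=0.0)
        a = out.data[:, 0] - out.data[:, 0].mean()
        b = out.data[:, 1] - out.data[:, 1].mean()
        lag = np.argmax(np.correlate(b, a, "full")) - (a.size - 1)
        assert lag == pytest.approx(2, abs=1)

    def test_heavy_noise_decorrelates_regions(self, rng):
        x = rng.normal(size=300)
        ts = ROITimeSeries(np.column_stack([x, x]), tr=1.0)
        h = syndata.hrf_double_gamma(dt=1.0)
        out = syndata.convolve_bold(ts, [h, h], obs_noise_sd=500.0, seed=1)
        assert abs(np.corrcoef(out.data[:, 0], out.data[:, 1])[0, 1]) < 0.2

    def test_tr_mismatch_rejected(self, rng):
        ts = ROITimeSeries(rng.normal(size=(100, 1)), tr=2.0)
        h = syndata.hrf_double_gamma(dt=1.0)
        with pytest.raises(ValueError, match="dt"):
            syndata.convolve_bold(ts, [h])


def small_design(**kw):
    kw.setdefault("n_per_group", (3, 3, 3))
    kw.setdefault("k", 8)
    kw.setdefault("T", 300)
    chain = [
        syndata.PlantedEdge(0, 1, base_weight=0.35, variability_multipliers=(1.0, 0.5, 0.1),
                            mod_amplitude=0.3, mod_period=100.0),
        syndata.PlantedEdge(1, 2, base_weight=0.35, variability_multipliers=(1.0, 0.5, 0.1),
                            mod_amplitude=0.3, mod_period=100.0),
    ]
    kw.setdefault("planted_chain", chain)
    return syndata.CohortDesign(**kw)


class TestSimulateCohort:
    def test_generative_variability_strictly_decreases(self):
        cohort = syndata.simulate_cohort(small_design(n_per_group=(6, 6, 6), seed=4))
        by_group = {g: [] for g in syndata.GROUPS}
        for sid, rec in cohort.ground_truth["subjects"].items():
            v = np.mean([e["generative_dgc_variance"] for e in rec["edges"].values()])
            by_group[rec["group"]].append(v)
        means = [np.mean(by_group[g]) for g in syndata.GROUPS]
        assert means[0] > means[1] > means[2]

    def test_noise_free_behavior_reproduces_linear_map(self):
        models = [syndata.BehaviorModel("PCL5", intercept=10.0, variability_weight=-5.0,
                                        noise_sd=0.0)]
        cohort = syndata.simulate_cohort(small_design(behavior_models=models, seed=9))
        for s, row in zip(cohort.subjects, cohort.manifest.itertuples()):
            edges = cohort.ground_truth["subjects"][s.subject_id]["edges"]
            mean_v = np.mean([e["variability_multiplier"] for e in edges.values()])
            assert row.PCL5 == pytest.approx(10.0 - 5.0 * mean_v, abs=0.01)

    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        syndata.simulate_cohort(small_design(seed=7), out_dir=d1)
        syndata.simulate_cohort(small_design(seed=7), out_dir=d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_all_series_finite_and_bounded(self):
        cohort = syndata.simulate_cohort(small_design(seed=5))
        for s in cohort.subjects:
            assert np.all(np.isfinite(s.ts.data))
            assert np.max(np.abs(s.ts.data)) < syndata.OVERFLOW_GUARD

    def test_invalid_variability_grading_rejected(self):
        with pytest.raises(ValueError, match="variability multipliers"):
            syndata.PlantedEdge(0, 1, variability_multipliers=(0.5, 1.0, 0.3))

    def test_non_monotone_strength_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            syndata.PlantedEdge(0, 1, strength_multipliers=(1.0, 0.5, 0.8))


class TestLaggedHrfPair:
    def test_neural_identical_bold_lagged(self):
        bold, neural = syndata.lagged_hrf_pair(T=600, seed=3)
        assert np.array_equal(neural.data[:, 0], neural.data[:, 1])
        a = bold.data[:, 0] - bold.data[:, 0].mean()
        b = bold.data[:, 1] - bold.data[:, 1].mean()
        lag = np.argmax(np.correlate(b, a, "full")) - (a.size - 1)
        assert lag == 1  # 2 s at TR=2
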