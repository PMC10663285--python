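"""Referencing, filtering, EOG regression, epoching, and trial rejection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from reachdecode.eeg_preprocess import (
    EPOCH_SAMPLES,
    common_average_reference,
    design_bandpass,
    bandpass_lowfreq,
    downsample_eeg,
    epoch,
    preprocess_session,
    regress_out_eog,
    reject_trials,
)
from reachdecode.task_model import parse_condition_code


class TestCommonAverage:
    def test_two_channel_example(self):
        out = common_average_reference(np.array([[3.0], [1.0]]))
        assert np.array_equal(out, np.array([[1.0], [-1.0]]))

    def test_zero_mean_data_unchanged(self):
        x = np.array([[1.0, -2.0], [-1.0, 2.0]])
        assert np.allclose(common_average_reference(x), x)

    def test_random_matrix_column_means_vanish(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 500))
        out = common_average_reference(x)
        assert np.abs(out.mean(axis=0)).max() < 1e-12

    def test_eog_rows_excluded_from_average(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(32, 100))
        out = common_average_reference(x)
        assert np.abs(out[:30].mean(axis=0)).max() < 1e-12
        assert np.array_equal(out[30:], x[30:])

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            common_average_reference(np.ones((1, 10)))


@pytest.fixture(scope="module")
def kernel():
    return design_bandpass()


class TestBandpass:
    def _gain(self, kernel, freq, rate=500.0):
        w = np.exp(-2j * np.pi * freq / rate * np.arange(len(kernel)))
        return np.abs(np.sum(kernel * w))

    def test_passband_stopband_gains(self, kernel):
        assert self._gain(kernel, 1.0) > 0.95
        assert self._gain(kernel, 2.0) > 0.95
        assert self._gain(kernel, 10.0) < 0.05
        assert self._gain(kernel, 0.0) < 0.05  # DC removed

    def test_half_amplitude_at_band_edges(self, kernel):
        assert self._gain(kernel, 0.3) == pytest.approx(0.5, abs=0.1)
        assert self._gain(kernel, 4.0) == pytest.approx(0.5, abs=0.1)

    def test_zero_phase_on_passband_sinusoid(self, kernel):
        rate = 500.0
        t = np.arange(0, 40, 1 / rate)
        x = np.sin(2 * np.pi * 1.0 * t)
        y = bandpass_lowfreq(x, rate=rate, kernel=kernel)[0]
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        xc = np.correlate(y[mid], x[mid], mode="full")
        lag = np.argmax(xc) - (len(x[mid]) - 1)
        assert lag == 0

    def test_stopband_sinusoid_removed(self, kernel):
        rate = 500.0
        t = np.arange(0, 40, 1 / rate)
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass_lowfreq(x, rate=rate, kernel=kernel)[0]
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert y[mid].std() < 0.05 * x.std()

    def test_short_record_rejected(self, kernel):
        with pytest.raises(ValueError, match="shorter"):
            bandpass_lowfreq(np.zeros(100), kernel=kernel)


class TestDownsample:
    def test_factor_ten(self):
        assert downsample_eeg(np.zeros((2, 3000))).shape == (2, 300)

    def test_low_frequency_waveform_preserved(self):
        rate = 500.0
        t = np.arange(0, 10, 1 / rate)
        x = np.sin(2 * np.pi * 2.0 * t)
        y = downsample_eeg(x[None, :])[0]
        t50 = t[::10]
        ref = np.interp(t50, t, x)
        assert np.abs(y - ref).max() < 0.01 * np.abs(x).max()

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError, match="non-integer"):
            downsample_eeg(np.zeros((1, 100)), rate=500.0, out_rate=44.0)


class TestEogRegression:
    def test_known_coupling_recovered(self):
        rng = np.random.default_rng(7)
        n = 5000
        t = np.arange(n) / 500.0
        clean = np.stack([np.sin(2 * np.pi * 1.3 * t), np.cos(2 * np.pi * 0.7 * t)])
        veog = rng.normal(size=n)
        heog = rng.normal(size=n)
        contaminated = clean + 0.3 * veog
        out = regress_out_eog(contaminated, heog, veog)
        rms = np.sqrt(np.mean((out - clean) ** 2))
        assert rms < 0.05 * clean.std()

    def test_idempotent_when_no_coupling_remains(self):
        rng = np.random.default_rng(8)
        eeg = rng.normal(size=(3, 2000))
        h, v = rng.normal(size=2000), rng.normal(size=2000)
        once = regress_out_eog(eeg, h, v)
        twice = regress_out_eog(once, h, v)
        assert np.abs(twice - once).max() < 1e-10

    def test_residuals_orthogonal_to_regressors(self):
        rng = np.random.default_rng(9)
        eeg = rng.normal(size=(4, 3000))
        h, v = rng.normal(size=3000), rng.normal(size=3000)
        out = regress_out_eog(eeg, h, v)
        assert np.abs(out @ h).max() < 1e-7 * np.abs(eeg @ h).max() + 1e-8
        assert np.abs(out @ v).max() < 1e-7 * np.abs(eeg @ v).max() + 1e-8

    def test_degenerate_eog_skipped_with_warning(self):
        eeg = np.random.default_rng(0).normal(size=(2, 100))
        with pytest.warns(UserWarning, match="degenerate"):
            out = regress_out_eog(eeg, np.zeros(100), np.ones(100))
        assert np.array_equal(out, eeg)


class TestEpoching:
    def test_window_arithmetic(self):
        rate = 50.0
        data = np.tile(np.arange(1000.0), (30, 1))  # sample index as value
        conds = [parse_condition_code("LGL")]
        es = epoch(data, [10.0], conds, [0], alignment="task_cue")
        assert es.data.shape == (1, 30, EPOCH_SAMPLES)
        # epoch covers 9.0-12.0 s -> samples 450..600
        assert es.data[0, 0, 0] == 450
        assert es.data[0, 0, -1] == 599

    def test_out_of_bounds_trial_dropped(self):
        data = np.zeros((30, 200))
        conds = [parse_condition_code("LGL"), parse_condition_code("RGR")]
        with pytest.warns(UserWarning, match="outside record bounds"):
            es = epoch(data, [0.5, 2.0], conds, [0, 1], alignment="task_cue")
        assert len(es) == 1 and es.trial_ids.tolist() == [1]


class TestRejection:
    @pytest.mark.parametrize(
        "onset_rel_go, plan, execu",
        [
            (-0.6, True, True),   # moved before Go - 0.5: both datasets lose it
            (-0.5, False, True),  # boundary is kept for planning (strict <)
            (-0.2, False, True),  # pre-Go movement: execution only
            (0.3, False, False),  # normal trial
            (np.nan, False, True),  # never moved: execution only
        ],
    )
    def test_rules(self, onset_rel_go, plan, execu):
        go = np.array([10.0])
        onset = go + onset_rel_go
        rep = reject_trials(onset, go)
        assert rep.planning_reject[0] == plan
        assert rep.execution_reject[0] == execu

    @given(st.lists(st.one_of(st.none(), st.floats(-2, 2)), min_size=1, max_size=60))
    def test_execution_rejections_contain_planning(self, rel):
        go = np.full(len(rel), 5.0)
        onset = np.array([np.nan if r is None else 5.0 + r for r in rel])
        rep = reject_trials(onset, go)
        assert not np.any(rep.planning_reject & ~rep.execution_reject)


class TestFullPreprocess:
    def test_deterministic(self, small_session):
        a = preprocess_session(small_session)
        b = preprocess_session(small_session)
        assert np.array_equal(a.planning.data, b.planning.data)
        assert np.array_equal(a.execution.data, b.execution.data)

    def test_epoch_geometry_and_counts(self, small_pre, small_session):
        assert small_pre.planning.data.shape[1:] == (30, 150)
        assert len(small_pre.planning) == small_session.n_trials  # no rejections
        assert len(small_pre.execution) == small_session.n_trials
        assert small_pre.planning.alignment == "task_cue"
        assert small_pre.execution.alignment == "movement_onset"

    def test_no_move_trials_absent_from_execution_set(self):
        from reachdecode.synthetic_session import SynthConfig, simulate_session

        cfg = SynthConfig(n_blocks=1, no_move_frac=0.15, seed=31)
        ses = simulate_session(cfg)
        pre = preprocess_session(ses)
        n_nomove = int(ses.trial_table["t_onset"].isna().sum())
        assert n_nomove > 0
        assert len(pre.execution) == ses.n_trials - n_nomove
        assert len(pre.planning) == ses.n_trials

    def test_eog_regression_attenuates_leakage(self):
        """Leakage-corrupted channels recover the artifact-free signal."""
        from reachdecode.synthetic_session import SynthConfig, simulate_session

        base = dict(n_blocks=1, noise_sd=0.0, seed=55)
        with_eog = preprocess_session(
            simulate_session(SynthConfig(eog_amp=15.0, **base)), eog_mode="regress"
        )
        no_eog = preprocess_session(
            simulate_session(SynthConfig(eog_amp=0.0, **base)), eog_mode="none"
        )
        resid = with_eog.planning.data - no_eog.planning.data
        signal_sd = no_eog.planning.data.std()
        # residual artifact well below the neural signal after regression
        assert resid.std() < 0.25 * signal_sd
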