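"""Preprocessing stages: unit conversion, exclusions, filters, baseline, binning."""

import numpy as np
import pandas as pd
import pytest

from pupilgca.preprocess import (
    INTERPOLATED,
    OBSERVED,
    PipelineError,
    PreprocessConfig,
    REMOVED_MAD,
    REMOVED_RANGE,
    REMOVED_SD,
    apply_exclusions,
    baseline_correct,
    convert_au_to_mm,
    dilation_speed,
    extend_and_interpolate_blinks,
    filter_implausible_samples,
    mad_speed_filter,
    missingness_fraction,
    run_preprocessing,
    smooth_moving_average,
    window_and_bin,
    PupilPreprocessor,
)
from pupilgca.simulate import RawPupilSeries, simulate_dataset

from conftest import clean_spec, degenerate_spec


def make_series(pupil, valid=None, step=4.0, t0=-1000.0, unit="mm", participant=0, trial=1):
    pupil = np.asarray(pupil, dtype=float)
    if valid is None:
        valid = ~np.isnan(pupil)
    return RawPupilSeries(
        participant_id=participant,
        trial_id=trial,
        item_id=0,
        condition="filler",
        time_ms=t0 + step * np.arange(len(pupil)),
        pupil=pupil,
        valid=np.asarray(valid, dtype=bool),
        unit=unit,
    )


CFG = PreprocessConfig()


class TestConvert:
    def test_diameter_scale(self):
        s = make_series([4000.0, 5000.0], unit="au")
        out = convert_au_to_mm(s, PreprocessConfig(au_to_mm_scale=1000.0))
        np.testing.assert_allclose(out.pupil, [4.0, 5.0])
        assert out.unit == "mm"

    def test_identity_when_already_mm(self):
        s = make_series([4.0, 5.0])
        out = convert_au_to_mm(s, CFG)
        np.testing.assert_array_equal(out.pupil, s.pupil)

    def test_monotone(self):
        s = make_series(np.linspace(3000, 6000, 10), unit="au")
        out = convert_au_to_mm(s, CFG)
        assert (np.diff(out.pupil) > 0).all()

    def test_area_mode(self):
        # area a maps to 2*sqrt(a / (scale*pi)); a 4 mm diameter pupil has
        # area pi*2^2 = 4pi mm^2 = 4000pi au at 1000 au/mm^2
        s = make_series([4000 * np.pi], unit="au")
        out = convert_au_to_mm(s, PreprocessConfig(au_mode="area", au_to_mm_scale=1000.0))
        np.testing.assert_allclose(out.pupil, [4.0])

    def test_rejects_bad_scale(self):
        with pytest.raises(ValueError):
            convert_au_to_mm(make_series([1.0], unit="au"), PreprocessConfig(au_to_mm_scale=0))


class TestMissingness:
    def test_fractions(self):
        assert missingness_fraction(make_series([1.0] * 10)) == 0.0
        v = np.ones(1300, bool)
        v[:650] = False
        s = make_series(np.ones(1300), valid=v)
        assert missingness_fraction(s) == 0.5

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            missingness_fraction(make_series([]))

    def test_boundary_is_strictly_greater(self):
        """A trial at exactly 30% missing is retained; 31% is dropped."""
        n = 100

        def trial(frac_missing, participant, trial_id):
            v = np.ones(n, bool)
            v[: int(n * frac_missing)] = False
            return make_series(np.where(v, 5.0, np.nan), valid=v,
                               participant=participant, trial=trial_id)

        # pair each probe trial with a clean one so the participant rule stays quiet
        trials = [
            trial(0.30, 0, 1), trial(0.0, 0, 2),
            trial(0.31, 1, 1), trial(0.0, 1, 2),
        ]
        kept, report = apply_exclusions(trials, CFG)
        assert report.participants_excluded == []
        assert report.trials_excluded_missing == 1
        assert [(t.participant_id, t.trial_id) for t in kept] == [(0, 1), (0, 2), (1, 2)]


class TestApplyExclusions:
    def test_clean_dataset_unchanged(self):
        trials = [make_series(np.ones(50), participant=p, trial=t) for p in (0, 1) for t in (1, 2)]
        kept, report = apply_exclusions(trials, CFG)
        assert len(kept) == 4
        assert report.trials_excluded_missing == 0
        assert report.participants_excluded == []

    def test_participant_over_threshold_fully_dropped(self):
        """A participant at 40% overall missing loses all their trials."""
        bad = []
        for t, frac in enumerate([0.80, 0.10, 0.70, 0.10], start=1):
            v = np.ones(100, bool)
            v[: int(100 * frac)] = False
            pupil = np.where(v, 5.0, np.nan)
            bad.append(make_series(pupil, valid=v, participant=0, trial=t))
        # hand-computed participant fraction: (80+10+70+10)/400 = 42.5% > 30%
        keeper = [make_series(np.full(100, 5.0), participant=1, trial=1)]
        kept, report = apply_exclusions(bad + keeper, CFG)
        assert report.participants_excluded == [0]
        assert report.trials_excluded_with_participants == 4
        assert [t.participant_id for t in kept] == [1]

    def test_one_bad_trial_dropped_counted(self):
        v = np.ones(100, bool)
        v[:31] = False  # 31% missing
        bad = make_series(np.where(v, 5.0, np.nan), valid=v, participant=0, trial=1)
        good = make_series(np.full(100, 5.0), participant=0, trial=2)
        clean = [make_series(np.full(100, 5.0), participant=1, trial=t) for t in (1, 2)]
        kept, report = apply_exclusions([bad, good] + clean, CFG)
        # participant 0's overall fraction 15.5% keeps them; only the trial goes
        assert report.participants_excluded == []
        assert report.trials_excluded_missing == 1
        assert len(kept) == 3

    def test_all_excluded_raises_with_report(self):
        v = np.zeros(10, bool)
        trials = [make_series(np.full(10, np.nan), valid=v)]
        with pytest.raises(PipelineError) as err:
            apply_exclusions(trials, CFG)
        report = err.value.report
        assert report.trials_excluded_missing + report.trials_excluded_with_participants == 1


class TestImplausibleFilter:
    def test_out_of_range_removed(self):
        s = make_series([1.9, 5.0, 5.0, 5.0, 8.1])
        prov = np.zeros(5, dtype=np.int8)
        out = filter_implausible_samples(s, CFG, prov)
        assert not out.valid[0] and not out.valid[4]
        assert prov[0] == REMOVED_RANGE and prov[4] == REMOVED_RANGE

    def test_constant_trial_untouched(self):
        s = make_series(np.full(100, 5.0))
        out = filter_implausible_samples(s, CFG)
        assert out.valid.all()

    def test_three_sd_outlier_removed_with_bruteforce_oracle(self, rng):
        base = 5.0 + 0.1 * rng.standard_normal(500)
        base[250] = base.mean() + 3.5 * base.std()
        s = make_series(base.copy())
        prov = np.zeros(500, dtype=np.int8)
        out = filter_implausible_samples(s, CFG, prov)
        # oracle: recompute mean/SD on the (range-clean) series directly
        m, sd = base.mean(), base.std()
        expect_removed = np.abs(base - m) > 3 * sd
        np.testing.assert_array_equal(~out.valid, expect_removed)
        assert prov[250] == REMOVED_SD


class TestBlinkInterpolation:
    def test_pad_width_at_250hz(self):
        """100 ms of padding at 250 Hz widens a blink by 25 samples per side."""
        n = 300
        v = np.ones(n, bool)
        v[100:130] = False
        pupil = np.full(n, 5.0)
        pupil[~v] = np.nan
        s = make_series(pupil, valid=v)
        prov = np.zeros(n, dtype=np.int8)
        out = extend_and_interpolate_blinks(s, CFG, prov)
        assert out.valid.all()
        assert not np.isnan(out.pupil).any()
        assert int((prov == INTERPOLATED).sum()) == 30 + 2 * 25

    def test_linear_interpolation_values(self):
        s = make_series([1.0, np.nan, np.nan, 4.0], step=1.0)
        out = extend_and_interpolate_blinks(s, PreprocessConfig(blink_pad_ms=0.0))
        np.testing.assert_allclose(out.pupil, [1.0, 2.0, 3.0, 4.0])

    def test_edge_gap_nearest_value_extension(self):
        s = make_series([np.nan, np.nan, 3.0, 4.0, np.nan], step=1.0)
        out = extend_and_interpolate_blinks(s, PreprocessConfig(blink_pad_ms=0.0))
        np.testing.assert_allclose(out.pupil, [3.0, 3.0, 3.0, 4.0, 4.0])


class TestMadSpeedFilter:
    def test_constant_series_untouched(self):
        s = make_series(np.full(100, 5.0))
        out = mad_speed_filter(s, CFG)
        np.testing.assert_array_equal(out.pupil, s.pupil)

    def test_isolated_spike_removed(self):
        pupil = np.full(200, 5.0)
        pupil[100] += 1.0
        s = make_series(pupil)
        prov = np.zeros(200, dtype=np.int8)
        out = mad_speed_filter(s, CFG, prov)
        # MAD of speeds is 0, threshold = 0 < spike speed -> removed, refilled
        np.testing.assert_allclose(out.pupil, 5.0)
        assert prov[100] == REMOVED_MAD

    def test_threshold_matches_bruteforce(self, rng):
        pupil = 5.0 + 0.2 * rng.standard_normal(400)
        s = make_series(pupil.copy())
        out = mad_speed_filter(s, CFG)
        # oracle: direct formula evaluation
        t = s.time_ms
        slope = np.abs(np.diff(pupil)) / np.diff(t)
        d = np.zeros(len(pupil))
        d[0], d[-1] = slope[0], slope[-1]
        d[1:-1] = np.maximum(slope[:-1], slope[1:])
        thr = np.median(d) + CFG.mad_multiplier * np.median(np.abs(d - np.median(d)))
        changed = out.pupil != pupil
        assert set(np.flatnonzero(changed)) <= set(np.flatnonzero(d > thr))
        np.testing.assert_array_equal(dilation_speed(pupil, t), d)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            mad_speed_filter(make_series([1.0, 2.0]), CFG)


class TestSmoothing:
    def test_constant_unchanged(self):
        s = make_series(np.full(50, 4.4))
        np.testing.assert_array_equal(smooth_moving_average(s, CFG).pupil, s.pupil)

    def test_impulse_response(self):
        pupil = np.zeros(50)
        pupil[25] = 1.0
        out = smooth_moving_average(make_series(pupil), CFG)
        np.testing.assert_allclose(out.pupil[23:28], 0.2)
        assert out.pupil[22] == 0 and out.pupil[28] == 0

    def test_shrinking_edge_window(self):
        pupil = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        out = smooth_moving_average(make_series(pupil), CFG)
        assert out.pupil[0] == pytest.approx(np.mean(pupil[:3]))
        assert out.pupil[-1] == pytest.approx(np.mean(pupil[-3:]))

    def test_window_larger_than_series_rejected(self):
        with pytest.raises(ValueError):
            smooth_moving_average(make_series([1.0, 2.0]), CFG)


class TestBaseline:
    def test_constant_trial_corrects_to_zero(self):
        s = make_series(np.full(400, 5.0))
        clean = baseline_correct(s, CFG)
        np.testing.assert_array_equal(clean.pupil_mm, 0.0)
        assert clean.baseline_mm == 5.0

    def test_median_of_baseline_window(self):
        # three baseline samples at -500, -300, -100 ms; onset sample at 0
        s = make_series([4.0, 4.2, 4.4, 5.0], step=200.0, t0=-600.0)
        # window [-500, 0) covers the 4.2 and 4.4 samples only; median 4.3
        clean = baseline_correct(s, CFG)
        assert clean.baseline_mm == pytest.approx(np.median([4.2, 4.4]))
        # samples at -500, -333.3, -166.7, 0: the onset sample is outside [-500, 0)
        s2 = make_series([4.0, 4.2, 4.4, 5.0], step=500.0 / 3, t0=-500.0)
        clean2 = baseline_correct(s2, CFG)
        assert clean2.baseline_mm == pytest.approx(4.2)  # median of {4.0,4.2,4.4}
        assert clean2.pupil_mm[-1] == pytest.approx(0.8)

    def test_level_shift_invariance(self, rng):
        pupil = 5.0 + 0.1 * rng.standard_normal(400)
        a = baseline_correct(make_series(pupil), CFG)
        b = baseline_correct(make_series(pupil + 1.23), CFG)
        np.testing.assert_allclose(a.pupil_mm, b.pupil_mm, atol=1e-12)

    def test_missing_baseline_raises(self):
        pupil = np.full(400, np.nan)
        pupil[300:] = 5.0  # valid only after onset
        s = make_series(pupil)
        with pytest.raises(PipelineError):
            baseline_correct(s, CFG)


class TestWindowAndBin:
    def test_full_length_trial_has_21_bins(self):
        s = make_series(np.full(1300, 5.0))
        clean = baseline_correct(s, CFG)
        bins = window_and_bin(clean, CFG)
        assert len(bins) == 21
        assert bins.time_ms.iloc[0] == 100.0  # bin midpoint = start + bin/2
        assert (bins.pupil == 0).all()

    def test_truncated_trial_keeps_only_covered_bins(self):
        # 1000 ms fixation + 1000 ms of post-onset data -> bins 0-4 only
        s = make_series(np.full(500, 5.0))
        clean = baseline_correct(s, CFG)
        bins = window_and_bin(clean, CFG)
        assert list(bins.bin) == [0, 1, 2, 3, 4]

    def test_bin_means(self):
        s = make_series(np.full(1300, 5.0))
        clean = baseline_correct(s, CFG)
        clean.pupil_mm = clean.time_ms.copy()  # value = time -> bin mean = mean time
        bins = window_and_bin(clean, CFG)
        sel = (clean.time_ms >= 0) & (clean.time_ms < 200)
        assert bins.pupil.iloc[0] == pytest.approx(clean.time_ms[sel].mean())


class TestFullPipeline:
    def test_degenerate_dataset_exact(self, degenerate_experiment):
        """Noise-, artifact- and random-effect-free data pass through exactly."""
        binned, report = run_preprocessing(degenerate_experiment.pupil)
        truth = degenerate_experiment.binned_truth()
        m = binned.merge(truth, on=["participant", "trial", "bin"], suffixes=("", "_t"))
        assert len(m) == len(binned) == len(truth)
        assert np.abs(m.pupil - m.pupil_t).max() < 1e-9
        assert sum(report.samples_removed_by_rule.values()) == 0
        assert report.interpolated_samples == 0

    def test_provenance_conservation(self):
        spec = clean_spec()
        spec.artifact_rates.blink_rate_per_s = 0.3
        spec.artifact_rates.spike_rate_per_s = 0.5
        spec.artifact_rates.dropout_prob = 0.002
        exp = simulate_dataset(spec)
        binned, report = run_preprocessing(exp.pupil)
        total = sum(len(t.pupil) for t in exp.pupil if True)
        accounted = (
            report.observed_samples
            + report.interpolated_samples
            + sum(report.samples_removed_by_rule.values())
        )
        # every sample of every *surviving* trial is accounted for exactly once
        surviving = report.n_trials_out
        assert accounted == surviving * len(exp.pupil[0].pupil)
        assert surviving <= len(exp.pupil)

    def test_blink_accounting_matches_injection(self):
        spec = clean_spec(n_participants=2)
        spec.artifact_rates.blink_rate_per_s = 0.3
        exp = simulate_dataset(spec)
        injected = sum(int((~s.valid).sum()) for s in exp.pupil)
        binned, report = run_preprocessing(exp.pupil)
        pad = int(CFG.blink_pad_ms / 4.0)
        n_runs = sum(len(s.artifacts["blink_runs"]) for s in exp.pupil)
        assert report.interpolated_samples >= injected
        assert report.interpolated_samples <= injected + 2 * pad * max(n_runs, 1) + 100

    def test_order_matters_smoothing_vs_baseline(self):
        """Baseline correction and smoothing only commute for flat baselines.

        The pipeline smooths first, as published; on a series whose
        baseline epoch is sloped the two orders subtract different
        medians, so the order genuinely matters.
        """
        pupil = np.full(1300, 5.0)
        # alternating values in the baseline window [-500, 0): the raw median
        # is the lower level, the smoothed median is an average of the two
        pupil[125:250] = np.where(np.arange(125) % 2 == 0, 4.0, 5.0)
        s = make_series(pupil)
        baseline_smooth_first = baseline_correct(smooth_moving_average(s, CFG), CFG).baseline_mm
        baseline_raw = baseline_correct(s, CFG).baseline_mm
        assert baseline_smooth_first != pytest.approx(baseline_raw, abs=1e-9)

    def test_transformer_wrapper_equivalent(self, degenerate_experiment):
        pp = PupilPreprocessor()
        binned = pp.fit(degenerate_experiment.pupil).transform(degenerate_experiment.pupil)
        direct, report = run_preprocessing(degenerate_experiment.pupil)
        pd.testing.assert_frame_equal(binned, direct)
        assert pp.report_.n_trials_out == report.n_trials_out

    def test_sklearn_params_roundtrip(self):
        pp = PupilPreprocessor(bin_ms=100.0)
        params = pp.get_params()
        assert params["bin_ms"] == 100.0
        pp2 = PupilPreprocessor().set_params(**params)
        assert pp2.bin_ms == 100.0
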