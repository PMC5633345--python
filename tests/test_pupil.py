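import numpy as np
import pandas as pd
import pytest

from infobias import pupil
from infobias.pupil import (
    CleanTrace,
    apply_exclusions,
    clean_trace,
    difference_timeseries,
    exclude_participant,
    extract_epochs,
    interpolate_blinks,
    lowpass_filter,
    z_transform,
)

FS = 500.0


class TestInterpolateBlinks:
    def test_single_gap_linear_midpoint(self):
        x = np.array([2.0, 0.0, 4.0])
        valid = np.array([1, 0, 1])
        filled, flags = interpolate_blinks(x, valid)
        np.testing.assert_allclose(filled, [2.0, 3.0, 4.0])
        assert flags.tolist() == [False, True, False]

    def test_no_gaps_is_identity(self):
        x = np.arange(10, dtype=float)
        filled, flags = interpolate_blinks(x, np.ones(10))
        np.testing.assert_array_equal(filled, x)
        assert not flags.any()

    def test_three_sample_gap(self):
        x = np.array([0.0, -1, -1, -1, 4.0])
        valid = np.array([1, 0, 0, 0, 1])
        filled, _ = interpolate_blinks(x, valid)
        np.testing.assert_allclose(filled, [0, 1, 2, 3, 4])

    def test_edges_take_nearest_valid(self):
        x = np.array([0.0, 0.0, 5.0, 7.0, 0.0])
        valid = np.array([0, 0, 1, 1, 0])
        filled, _ = interpolate_blinks(x, valid)
        np.testing.assert_allclose(filled, [5, 5, 5, 7, 7])

    def test_all_invalid_raises(self):
        with pytest.raises(ValueError):
            interpolate_blinks(np.zeros(5), np.zeros(5))


class TestLowpassFilter:
    @staticmethod
    def _attenuation(freq):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * freq * t)
        y = lowpass_filter(x, fs=FS)
        core = slice(int(2 * FS), int(18 * FS))  # avoid edge transients
        return np.ptp(y[core]) / np.ptp(x[core])

    def test_constant_unchanged(self):
        x = np.full(1000, 3.7)
        np.testing.assert_allclose(lowpass_filter(x, fs=FS), x, atol=1e-9)

    def test_passband_keeps_slow_oscillation(self):
        assert self._attenuation(0.5) >= 0.95

    def test_stopband_kills_fast_oscillation(self):
        assert self._attenuation(10.0) <= 0.10

    def test_invalid_cutoff_raises(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(100), cutoff=300.0, fs=FS)


class TestZTransform:
    def test_standardises(self):
        rng = np.random.default_rng(0)
        z = z_transform(rng.normal(3, 7, 5000))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        np.testing.assert_allclose(
            z_transform(5.0 * x - 2.0), z_transform(x), atol=1e-10
        )

    def test_two_point_population_convention(self):
        np.testing.assert_allclose(z_transform(np.array([1.0, 3.0])), [-1, 1])

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            z_transform(np.ones(10))

    def test_filter_and_z_commute_up_to_scale(self):
        rng = np.random.default_rng(2)
        x = rng.normal(2.0, 3.0, int(10 * FS))
        a = z_transform(lowpass_filter(x, fs=FS))
        b = z_transform(lowpass_filter(z_transform(x), fs=FS))
        np.testing.assert_allclose(a, b, atol=1e-9)


def _markers(samples, block=1, start_trial=1):
    return pd.DataFrame(
        {
            "block": block,
            "trial": np.arange(start_trial, start_trial + len(samples)),
            "event_sample": samples,
            "win_obtained": 1,
            "loss_obtained": 0,
        }
    )


class TestExtractEpochs:
    def test_constant_trace_gives_zero_epochs(self):
        clean = CleanTrace(np.full(int(10 * FS), 1.3), np.zeros(int(10 * FS), bool))
        ep = extract_epochs(clean, _markers([int(2 * FS)]))
        np.testing.assert_allclose(ep.data[0], 0.0, atol=1e-12)
        assert len(ep.meta) == 2  # one win + one loss epoch per trial

    def test_step_response_equals_step_size(self):
        n = int(10 * FS)
        onset = int(3 * FS)
        sig = np.full(n, 2.0)
        sig[onset:] += 0.7
        clean = CleanTrace(sig, np.zeros(n, bool))
        ep = extract_epochs(clean, _markers([onset]))
        np.testing.assert_allclose(ep.data[0], 0.7, atol=1e-12)

    def test_baseline_correction_uses_own_window(self):
        rng = np.random.default_rng(3)
        n = int(12 * FS)
        sig = rng.normal(size=n)
        clean = CleanTrace(sig, np.zeros(n, bool))
        onset = int(4 * FS)
        ep = extract_epochs(clean, _markers([onset]))
        base = sig[onset - int(FS) : onset].mean()
        np.testing.assert_allclose(
            ep.data[0], sig[onset : onset + int(6 * FS)] - base, atol=1e-12
        )

    def test_marker_near_edge_flagged(self):
        clean = CleanTrace(np.zeros(int(3 * FS)), np.zeros(int(3 * FS), bool))
        ep = extract_epochs(clean, _markers([int(2.5 * FS)]))
        assert not ep.meta["included"].any()
        assert (ep.meta["reason"] == "edge").all()

    def test_fraction_interpolated_over_post_window(self):
        n = int(10 * FS)
        onset = int(2 * FS)
        interp = np.zeros(n, bool)
        interp[onset : onset + int(3 * FS)] = True  # half the 6 s window
        clean = CleanTrace(np.zeros(n), interp)
        ep = extract_epochs(clean, _markers([onset]))
        assert ep.meta["fraction_interpolated"].iloc[0] == pytest.approx(0.5)


class TestExclusions:
    @staticmethod
    def _epochs(fracs, trials=None, block=1):
        n = len(fracs)
        meta = pd.DataFrame(
            {
                "block": block,
                "trial": trials if trials is not None else np.arange(11, 11 + n),
                "valence": "win",
                "obtained": True,
                "fraction_interpolated": fracs,
                "included": True,
                "reason": "",
            }
        )
        return pupil.PupilEpochs(data=np.zeros((n, 10)), meta=meta)

    def test_majority_interpolated_epoch_dropped(self):
        ep = apply_exclusions(self._epochs([0.6]))
        assert not ep.meta["included"].iloc[0]
        assert ep.meta["reason"].iloc[0] == "interpolation"

    def test_exactly_half_interpolated_retained(self):
        ep = apply_exclusions(self._epochs([0.5]))
        assert ep.meta["included"].iloc[0]

    def test_first_ten_trials_dropped_eleventh_kept(self):
        ep = apply_exclusions(self._epochs([0.0, 0.0], trials=[10, 11]))
        assert not ep.meta["included"].iloc[0]
        assert ep.meta["reason"].iloc[0] == "adaptation"
        assert ep.meta["included"].iloc[1]

    def test_participant_exclusion_thresholds(self):
        n = 200
        for frac, expected in [(0.995, True), (0.07, False), (0.0, False)]:
            k = int(round(n * frac))
            meta = pd.DataFrame(
                {
                    "block": 1,
                    "trial": np.arange(1, n + 1),
                    "valence": "win",
                    "obtained": True,
                    "fraction_interpolated": 0.0,
                    "included": [False] * k + [True] * (n - k),
                    "reason": "",
                }
            )
            ep = pupil.PupilEpochs(data=np.zeros((n, 10)), meta=meta)
            assert exclude_participant(ep) is expected


class TestDifferenceTimeseries:
    @staticmethod
    def _epochs(obtained_vals, unobtained_vals, n_samples=3000):
        rows, data = [], []
        trial = 11
        for v in obtained_vals:
            rows.append(dict(block=2, trial=trial, valence="loss",
                             obtained=True, fraction_interpolated=0.0,
                             included=True, reason=""))
            data.append(np.full(n_samples, v))
            trial += 1
        for v in unobtained_vals:
            rows.append(dict(block=2, trial=trial, valence="loss",
                             obtained=False, fraction_interpolated=0.0,
                             included=True, reason=""))
            data.append(np.full(n_samples, v))
            trial += 1
        return pupil.PupilEpochs(
            data=np.array(data), meta=pd.DataFrame(rows)
        )

    def test_identical_sides_give_zero(self):
        bd = difference_timeseries(self._epochs([1.0, 1.0], [1.0]))
        np.testing.assert_allclose(bd.bins["difference"], 0.0, atol=1e-12)

    def test_constant_offset_appears_in_every_bin(self):
        bd = difference_timeseries(self._epochs([2.0, 2.0], [1.5, 1.5]))
        np.testing.assert_allclose(bd.bins["difference"], 0.5, atol=1e-12)
        assert bd.mean6s["mean6s"].iloc[0] == pytest.approx(0.5)
        assert len(bd.bins) == 6

    def test_empty_side_flagged_missing(self):
        bd = difference_timeseries(self._epochs([1.0], []))
        assert bd.missing == [(2, "loss")]
        assert bd.bins["difference"].isna().all()


class TestPipelineAccounting:
    def test_every_sample_flagged_or_used(self):
        rng = np.random.default_rng(4)
        n = int(20 * FS)
        x = rng.normal(5, 1, n)
        valid = np.ones(n)
        valid[1000:1400] = 0
        clean = clean_trace(x, valid, fs=FS)
        assert clean.interpolated.sum() == 400
        assert clean.interpolated.size == n
        # z-transform contract holds on the cleaned signal
        assert clean.signal.mean() == pytest.approx(0.0, abs=1e-6)
        assert clean.signal.std(ddof=0) == pytest.approx(1.0, abs=1e-6)
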