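import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rarlab import (
    DailyProfile,
    interdaily_stability,
    intradaily_variability,
    l5_m10,
    nonparam_summary,
    relative_amplitude,
)
from rarlab.errors import DegenerateInputError, ParameterError

from conftest import make_series, model_series
from rarlab import CosinorParams


def brute_force_window(values, w):
    """Naive double-loop circular window search: (min_mean, min_start,
    max_mean, max_start)."""
    n = len(values)
    best_min, best_max = None, None
    for start in range(n):
        total = 0.0
        for k in range(w):
            total += values[(start + k) % n]
        mean = total / w
        if best_min is None or mean < best_min[0] - 1e-15:
            best_min = (mean, start)
        if best_max is None or mean > best_max[0] + 1e-15:
            best_max = (mean, start)
    return best_min, best_max


class TestInterdailyStability:
    def test_identical_days_give_one(self):
        day = np.random.default_rng(1).random(24) * 100
        for d in (2, 3, 7):
            assert interdaily_stability(np.tile(day, d), 24) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_two_day_hand_oracle(self):
        # numerator 8 * 1, denominator 4 * 4
        x = np.array([1, 3, 1, 3, 2, 2, 2, 2], dtype=float)
        assert interdaily_stability(x, 4) == pytest.approx(0.5)

    def test_long_noise_near_zero(self):
        rng = np.random.default_rng(42)
        x = rng.normal(10, 3, size=1000 * 24)
        assert interdaily_stability(x, 24) < 0.01

    def test_noise_expectation_is_one_over_days(self):
        # finite-sample E[IS] ~ 1/d for i.i.d. noise
        rng = np.random.default_rng(5)
        d = 7
        vals = [
            interdaily_stability(rng.normal(size=d * 24), 24)
            for _ in range(500)
        ]
        mean = np.mean(vals)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(mean - 1 / d) < 3 * se

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            interdaily_stability(np.full(48, 5.0), 24)

    @given(
        day=arrays(
            float, 24, elements=st.floats(0, 1000, allow_nan=False)
        ),
        a=st.floats(0.1, 10),
        b=st.floats(-5, 50),
    )
    @settings(max_examples=50)
    def test_affine_invariance(self, day, a, b):
        x = np.tile(day, 3) + np.arange(72) % 7  # break constancy
        if np.std(x) == 0:
            return
        base = interdaily_stability(x, 24)
        scaled = interdaily_stability(a * x + b, 24)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestIntradailyVariability:
    def test_sine_wave_near_zero(self):
        t = np.arange(7 * 24)
        x = 50 + 40 * np.sin(2 * np.pi * t / 24)
        assert intradaily_variability(x) < 0.1

    def test_hand_oracle(self):
        # 4*3 / (3*1)
        assert intradaily_variability(np.array([0.0, 1, 0, 1])) == 4.0

    def test_gaussian_noise_near_two(self):
        rng = np.random.default_rng(9)
        vals = [
            intradaily_variability(rng.normal(size=168)) for _ in range(100)
        ]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.1)

    def test_invalid_bins_use_pairwise_deletion(self):
        x = np.array([0.0, 1, np.nan, 0, 1])
        # diffs used: (1-0), (1-0); n = 4 valid
        mean = 0.5
        num = 4 * (1 + 1)
        den = 3 * np.nansum((x - mean) ** 2)
        assert intradaily_variability(x) == pytest.approx(num / den)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            intradaily_variability(np.full(24, 3.0))


class TestL5M10:
    def test_constant_profile_ties_to_zero_onset(self):
        prof = DailyProfile(resolution=3600, values=np.full(24, 5.0))
        l5, m10, l5_on, m10_on = l5_m10(prof)
        assert l5 == m10 == 5.0
        assert l5_on == m10_on == 0.0

    def test_square_profile(self):
        values = np.zeros(24)
        values[8:20] = 100.0  # active 08:00-20:00
        prof = DailyProfile(resolution=3600, values=values)
        l5, m10, l5_on, m10_on = l5_m10(prof)
        assert m10 == 100.0 and l5 == 0.0
        assert 8 <= m10_on <= 10
        assert l5_on >= 20 or l5_on <= 3

    @pytest.mark.parametrize("resolution", [3600, 1800])
    def test_matches_brute_force_oracle(self, resolution):
        rng = np.random.default_rng(11)
        bins = 86400 // resolution
        w5 = 5 * 3600 // resolution
        w10 = 10 * 3600 // resolution
        for _ in range(200):
            values = rng.random(bins) * 100
            prof = DailyProfile(resolution=resolution, values=values)
            l5, m10, l5_on, m10_on = l5_m10(prof)
            (bmin, imin), (bmax, imax) = brute_force_window(values, w5)[0], \
                brute_force_window(values, w10)[1]
            assert l5 == pytest.approx(bmin)
            assert m10 == pytest.approx(bmax)
            assert l5_on == pytest.approx(imin * resolution / 3600)
            assert m10_on == pytest.approx(imax * resolution / 3600)

    def test_resolution_coarser_than_window_rejected(self):
        # 12 h bins: a 5 h window is narrower than a single bin
        with pytest.raises(ParameterError):
            l5_m10(DailyProfile(resolution=43200, values=np.ones(2)))

    def test_m10_and_l5_bracket_daily_mean(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            values = rng.gamma(1.0, 30.0, size=24)
            prof = DailyProfile(resolution=3600, values=values)
            l5, m10, *_ = l5_m10(prof)
            assert l5 - 1e-12 <= values.mean() <= m10 + 1e-12


class TestRelativeAmplitude:
    @pytest.mark.parametrize(
        "m10,l5,expected", [(100, 0, 1.0), (50, 50, 0.0), (150, 50, 0.5)]
    )
    def test_formula(self, m10, l5, expected):
        assert relative_amplitude(l5, m10) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(DegenerateInputError):
            relative_amplitude(0.0, 0.0)

    def test_scale_invariant_not_shift_invariant(self):
        assert relative_amplitude(20.0, 80.0) == pytest.approx(
            relative_amplitude(60.0, 240.0)
        )
        assert relative_amplitude(20.0, 80.0) != pytest.approx(
            relative_amplitude(30.0, 90.0)
        )


class TestNonparamSummary:
    def test_consolidated_rhythm(self):
        params = CosinorParams(
            minimum=0.5, amplitude=100, acrophase=14, alpha=0.0, beta=4
        )
        s = model_series(params, days=7, epoch_length=60)
        res = nonparam_summary(s)
        assert res.IS == pytest.approx(1.0, abs=1e-9)
        assert res.IV < 0.15
        assert res.RA > 0.9
        assert res.n_days == 7

    def test_pure_noise_subject(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(20):
            counts = rng.gamma(1.0, 30.0, size=7 * 1440)
            s = make_series(counts, epoch_length=60)
            res = nonparam_summary(s)
            vals.append((res.IS, res.IV, res.RA))
        is_m, iv_m, ra_m = np.mean(vals, axis=0)
        assert is_m < 0.3  # ~1/d at hourly bins
        # IV at hourly bins: each bin averages 60 noise epochs -> still iid
        assert iv_m == pytest.approx(2.0, abs=0.4)
        assert ra_m < 0.5

    def test_error_carries_subject_context(self):
        s = make_series(
            np.full(3 * 1440, 4.0), epoch_length=60, subject_id="S99", wave=8
        )
        with pytest.raises(DegenerateInputError, match="S99"):
            nonparam_summary(s)
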