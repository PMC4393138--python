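"""Abundance-structure statistics against hand and simulation oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleosel.series_stats import (
    PowerSpectrum,
    abundance_skewness,
    averaged_cv,
    hurst_exponent,
    local_cv2,
    lomb_periodogram,
    mean_abundance,
    spectral_exponent,
    taylor_fit,
)
from paleosel.synth import colored_noise

from .conftest import make_record, make_series


class TestMeanAbundance:
    def test_single_count(self):
        assert mean_abundance(make_record([3])) == 3.0

    def test_zeros_excluded(self):
        assert mean_abundance(make_record([2, 0, 4, 0, 6])) == 4.0

    def test_pools_across_cores(self, rng):
        lists = [list(rng.integers(0, 6, size=10)) for _ in range(3)]
        lists[0][0] = 1  # ensure an occurrence
        rec = make_record(*lists)
        pos = [v for lst in lists for v in lst if v > 0]
        assert mean_abundance(rec) == pytest.approx(sum(pos) / len(pos))


class TestLocalCV2:
    def test_equal_values(self):
        assert local_cv2(5, 5) == 0.0

    def test_hand_value_and_symmetry(self):
        # sd = |2-4|/sqrt(2) = sqrt(2), mean = 3
        assert local_cv2(2, 4) == pytest.approx(0.47140, abs=1e-4)
        assert local_cv2(4, 2) == local_cv2(2, 4)

    @pytest.mark.parametrize("pair", [(0, 3), (3, 0), (-1, 2)])
    def test_nonpositive_raises(self, pair):
        with pytest.raises(ValueError):
            local_cv2(*pair)


class TestAveragedCV:
    def test_single_pair_equals_local(self):
        assert averaged_cv(make_record([2, 4])) == pytest.approx(local_cv2(2, 4))

    def test_zeros_skipped_when_pairing(self):
        # positives subsequence is (2, 4): one pair despite the gap
        assert averaged_cv(make_record([2, 0, 0, 4])) == pytest.approx(local_cv2(2, 4))

    def test_grand_mean_over_cores(self):
        rec = make_record([2, 4], [10, 30])
        expected = (local_cv2(2, 4) + local_cv2(10, 30)) / 2
        assert averaged_cv(rec) == pytest.approx(expected)

    def test_all_equal_positives(self):
        assert averaged_cv(make_record([3, 3, 0, 3])) == 0.0

    def test_no_pair_is_nan(self):
        assert math.isnan(averaged_cv(make_record([2, 0, 0, 0], [0, 3, 0, 0])))

    @given(
        st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=12),
        st.integers(min_value=2, max_value=7),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, values, factor):
        base = averaged_cv(make_record(values))
        scaled = averaged_cv(make_record([v * factor for v in values]))
        assert scaled == pytest.approx(base, rel=1e-9)


class TestHurstExponent:
    def test_hand_oracle(self):
        # cumulative demeaned sums (-1.5, -2, -1.5, 0): R=2, S_T=sqrt(1.25)
        assert hurst_exponent(make_series([1, 2, 3, 4])) == pytest.approx(0.4195, abs=2e-4)

    def test_constant_is_nan(self):
        assert math.isnan(hurst_exponent(make_series([5, 5, 5, 5])))

    def test_too_short_is_nan(self):
        assert math.isnan(hurst_exponent(make_series([1, 2])))

    @given(st.lists(st.integers(min_value=0, max_value=9), min_size=3, max_size=25))
    @settings(max_examples=100, deadline=None)
    def test_reversal_symmetry(self, values):
        h = hurst_exponent(make_series(values))
        h_rev = hurst_exponent(make_series(values[::-1]))
        assert (math.isnan(h) and math.isnan(h_rev)) or h == pytest.approx(h_rev)

    def test_shift_invariance(self):
        a = hurst_exponent(make_series([1, 4, 2, 8, 3]))
        b = hurst_exponent(make_series([11, 14, 12, 18, 13]))
        assert a == pytest.approx(b)


class TestLombPeriodogram:
    def test_sinusoid_peak_at_generating_frequency(self, rng):
        f0 = 0.1  # cycles per meter
        t = np.sort(rng.uniform(0, 100, size=60))  # uneven "time" since oldest
        y = np.round(20 + 10 * np.sin(2 * np.pi * f0 * t)).astype(int)
        depths = tuple(300.0 - tt for tt in t)  # deepest (oldest) first
        series = make_series(list(y), depths=depths)
        spec = lomb_periodogram(series, oversample=4)
        peak = spec.frequencies[np.argmax(spec.powers)]
        step = spec.frequencies[1] - spec.frequencies[0]
        assert abs(peak - f0) <= step + 1e-12

    def test_matches_least_squares_sinusoid_oracle(self, rng):
        """Lomb ordinates equal the LS sum-of-squares reduction / 2σ².

        Independent oracle: at each grid frequency, regress the demeaned
        series on cos/sin via lstsq; the RSS drop over the constant model,
        divided by 2·var, is the classical normalized Lomb power.
        """
        n = 24
        counts = (20 + 6 * rng.normal(size=n)).clip(1).round().astype(int)
        depths = tuple(float(200 - 1.37 * i) for i in range(n))
        series = make_series(list(counts), depths=depths)
        spec = lomb_periodogram(series)
        y = np.asarray(counts, float)
        yc = y - y.mean()
        t = depths[0] - np.asarray(depths)
        for f, power in zip(spec.frequencies, spec.powers):
            design = np.column_stack(
                [np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)]
            )
            coef, *_ = np.linalg.lstsq(design, yc, rcond=None)
            rss = ((yc - design @ coef) ** 2).sum()
            oracle = ((yc**2).sum() - rss) / (2 * y.var(ddof=1))
            assert power == pytest.approx(oracle, rel=1e-8, abs=1e-10)

    def test_white_noise_flat_on_average(self):
        n = 48
        acc = None
        for seed in range(200):
            rng = np.random.default_rng(seed)
            counts = rng.poisson(20, size=n) + 1
            series = make_series(
                list(counts), depths=tuple(float(300 - 1.5 * i) for i in range(n))
            )
            spec = lomb_periodogram(series)
            acc = spec.powers if acc is None else acc + spec.powers
        mean_power = acc / 200
        lo, hi = mean_power[: len(mean_power) // 3].mean(), mean_power[-len(mean_power) // 3 :].mean()
        assert 0.6 < lo / hi < 1.67  # no systematic tilt

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            lomb_periodogram(make_series([3, 3, 3, 3, 3]))


class TestSpectralExponent:
    def test_flat_spectrum_is_zero(self):
        spec = PowerSpectrum(np.array([0.1, 0.2, 0.3, 0.4]), np.full(4, 2.0))
        assert spectral_exponent(spec) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_closed_form(self):
        # ln(f+1) = (1, 2), ln(P+1) = (2, 1): slope −1, ν = 1
        e = math.e
        spec = PowerSpectrum(
            np.array([e - 1, e**2 - 1]), np.array([e**2 - 1, e - 1])
        )
        assert spectral_exponent(spec) == pytest.approx(1.0, rel=1e-9)

    def test_red_exceeds_white(self):
        nus = {0.0: [], 2.0: []}
        n = 40
        for nu_gen in nus:
            for seed in range(100):
                rng = np.random.default_rng(seed + 10_000)
                noise = colored_noise(n, nu_gen, rng)
                counts = np.clip(np.round(20 + 6 * noise), 1, None).astype(int)
                series = make_series(
                    list(counts), depths=tuple(float(300 - 1.5 * i) for i in range(n))
                )
                nus[nu_gen].append(
                    spectral_exponent(lomb_periodogram(series))
                )
        assert np.mean(nus[2.0]) > np.mean(nus[0.0])

    def test_invariance_asymmetry(self):
        """H and ν respond differently to data transforms.

        With a demeaned, variance-normalized spectrum, shifting all
        counts leaves ν unchanged (like H).  But ν is not invariant to
        the depth scale: the +1-before-log rule acts on frequency in
        cycles per meter, so relabelling depths in different units
        changes ν while H is untouched.
        """
        values = [3, 9, 2, 14, 5, 8, 1, 12, 6, 4]
        base = make_series(values)
        shifted = make_series([v + 50 for v in values])
        assert spectral_exponent(lomb_periodogram(base)) == pytest.approx(
            spectral_exponent(lomb_periodogram(shifted)), abs=1e-9
        )
        assert hurst_exponent(base) == pytest.approx(hurst_exponent(shifted))
        squeezed = make_series(
            values, depths=tuple(d / 10 for d in base.depths)
        )  # same series, depth in different units
        nu_a = spectral_exponent(lomb_periodogram(base))
        nu_b = spectral_exponent(lomb_periodogram(squeezed))
        assert nu_a != pytest.approx(nu_b, abs=1e-6)
        assert hurst_exponent(base) == pytest.approx(hurst_exponent(squeezed))


class TestAbundanceSkewness:
    def test_hand_oracle(self):
        assert abundance_skewness(make_record([1, 1, 1, 10])) == pytest.approx(2.0, abs=1e-9)

    def test_symmetric_sample_is_zero(self):
        assert abundance_skewness(make_record([1, 2, 3])) == pytest.approx(0.0, abs=1e-12)

    def test_zeros_excluded(self):
        assert abundance_skewness(make_record([1, 0, 1, 0, 1, 10])) == pytest.approx(2.0)

    def test_mirror_antisymmetry(self):
        a = abundance_skewness(make_record([1, 2, 3, 10]))
        b = abundance_skewness(make_record([10, 9, 8, 1]))  # mirror about 5.5
        assert a == pytest.approx(-b, rel=1e-9)

    def test_insufficient_n_is_nan(self):
        assert math.isnan(abundance_skewness(make_record([2, 5])))

    def test_unadjusted_option(self):
        g1 = abundance_skewness(make_record([1, 1, 1, 10]), adjusted=False)
        assert g1 == pytest.approx(2.0 / (math.sqrt(12) / 2), rel=1e-6)


class TestTaylorFit:
    def test_exact_power_law_recovery(self):
        # geometric series: every 3-window has var = c·mean² exactly
        values = [1, 2, 4, 8, 16, 32, 64]
        fit = taylor_fit(make_series(values), window=3)
        w = np.array([1.0, 2.0, 4.0])
        c_true = w.var(ddof=1) / w.mean() ** 2
        assert fit.exponent == pytest.approx(2.0, abs=1e-9)
        assert fit.prefactor == pytest.approx(c_true, rel=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-9)

    def test_identical_windows_raise(self):
        with pytest.raises(ValueError):
            taylor_fit(make_series([2, 3, 2, 3, 2, 3, 2, 3]), window=2)

    def test_matches_independent_ols(self, rng):
        counts = 1 + rng.negative_binomial(2, 0.25, size=40)
        series = make_series(list(counts))
        fit = taylor_fit(series, window=3)
        # independent oracle: explicit normal-equations OLS over the windows
        pos = np.array([v for v in counts if v > 0], float)
        means, variances = [], []
        for i in range(len(pos) - 2):
            w = pos[i : i + 3]
            if w.var(ddof=1) > 0:
                means.append(w.mean())
                variances.append(w.var(ddof=1))
        x, y = np.log(means), np.log(variances)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert fit.exponent == pytest.approx(slope, abs=1e-9)
        assert fit.n == len(x)

    def test_too_few_positive_samples(self):
        with pytest.raises(ValueError):
            taylor_fit(make_series([2, 3, 4]), window=3)
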