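import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvreact import (NNSegment, SpectrumEstimate, WelchSettings, band_powers,
                      compute_all, poincare, resample_tachogram, time_domain,
                      welch_psd)
from hrvreact.errors import InsufficientDataError

from conftest import make_segment, random_segments
from oracles import poincare_loop, time_domain_loop


# ---------------------------------------------------------------- time domain

def test_constant_segment_time_domain():
    seg = make_segment([1000.0] * 300)
    mean_nn, mean_hr, sdnn, pnn50 = time_domain(seg)
    assert (mean_nn, mean_hr, sdnn, pnn50) == (1000.0, 60.0, 0.0, 0.0)


def test_hand_computed_segment_uses_strict_pnn50_inequality():
    seg = make_segment([1000.0, 1060.0, 1010.0])
    mean_nn, mean_hr, sdnn, pnn50 = time_domain(seg)
    # diffs are +60 and -50; only 60 exceeds 50 ms strictly
    assert pnn50 == pytest.approx(50.0)
    assert mean_nn == pytest.approx(1023.3333333333333)
    assert sdnn == pytest.approx(32.14550253664318)
    assert mean_hr == pytest.approx(60000.0 / mean_nn, rel=1e-12)


def test_time_domain_matches_loop_oracle(rng):
    for seg in random_segments(rng, 200):
        got = time_domain(seg)
        expected = time_domain_loop(seg.nn_ms.tolist())
        np.testing.assert_allclose(got, expected, rtol=1e-12)


@given(st.lists(st.floats(min_value=400.0, max_value=1500.0), min_size=3, max_size=60),
       st.floats(min_value=-50.0, max_value=50.0))
@settings(deadline=None, max_examples=50)
def test_variability_indexes_are_shift_invariant_and_reversal_invariant(values, shift):
    seg = make_segment(values)
    shifted = make_segment(np.asarray(values) + shift)
    reversed_seg = make_segment(np.asarray(values)[::-1])
    _, _, sdnn, pnn50 = time_domain(seg)
    _, _, sdnn_s, pnn50_s = time_domain(shifted)
    _, _, sdnn_r, pnn50_r = time_domain(reversed_seg)
    assert sdnn_s == pytest.approx(sdnn, abs=1e-9)
    assert pnn50_s == pytest.approx(pnn50)
    assert sdnn_r == pytest.approx(sdnn, abs=1e-9)
    assert pnn50_r == pytest.approx(pnn50)
    sd1, sd2, *_ = poincare(seg)
    sd1_s, sd2_s, *_ = poincare(shifted)
    sd1_r, sd2_r, *_ = poincare(reversed_seg)
    assert (sd1_s, sd2_s) == pytest.approx((sd1, sd2), abs=1e-9)
    assert (sd1_r, sd2_r) == pytest.approx((sd1, sd2), abs=1e-9)


# ---------------------------------------------------------------- resampling

def test_resampling_a_constant_is_constant():
    seg = make_segment([1000.0] * 100)
    _, samples = resample_tachogram(seg, 3.0)
    assert np.all(samples == 1000.0)


def test_two_point_linear_interpolation_closed_form():
    segment = NNSegment(nn_ms=[800.0, 1000.0], end_times_s=[0.0, 1.0],
                        start_time_s=0.0)
    grid, samples = resample_tachogram(segment, 3.0)
    np.testing.assert_allclose(grid, [0.0, 1 / 3, 2 / 3, 1.0], atol=1e-12)
    np.testing.assert_allclose(samples, [800.0, 800 + 200 / 3, 800 + 400 / 3, 1000.0],
                               atol=1e-9)


def test_resampling_is_exact_on_linear_tachograms(rng):
    for _ in range(20):
        n = int(rng.integers(10, 80))
        ends = np.cumsum(rng.uniform(0.5, 1.2, n))
        slope = rng.uniform(-30.0, 30.0)
        intercept = rng.uniform(700.0, 1100.0)
        vals = intercept + slope * ends
        seg = NNSegment(nn_ms=np.clip(vals, 310, 1990), end_times_s=ends,
                        start_time_s=0.0)
        if np.any(vals != np.clip(vals, 310, 1990)):
            continue
        grid, samples = resample_tachogram(seg, 3.0)
        np.testing.assert_allclose(samples, intercept + slope * grid, rtol=1e-12)


# ---------------------------------------------------------------- spectrum

def test_welch_integral_recovers_white_noise_variance(rng):
    ratios = []
    for _ in range(100):
        x = rng.normal(0.0, 1.0, 900)
        sp = welch_psd(x)
        ratios.append(np.trapezoid(sp.psd_ms2_per_hz, sp.frequencies_hz) / np.var(x))
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)


def test_sinusoid_power_concentrates_in_lf_band():
    t = np.arange(0.0, 300.0, 1 / 3)
    x = 1000.0 + 50.0 * np.sin(2 * np.pi * 0.1 * t)
    sp = welch_psd(x)
    total = np.trapezoid(sp.psd_ms2_per_hz, sp.frequencies_hz)
    assert total == pytest.approx(50.0 ** 2 / 2.0, rel=0.05)
    lf, hf, lf_nu, *_ = band_powers(sp)
    assert lf == pytest.approx(1250.0, rel=0.10)
    assert lf_nu >= 99.0
    # power concentrated within one resolution bandwidth of 0.1 Hz
    df = 3.0 / sp.settings.nperseg
    near = np.abs(sp.frequencies_hz - 0.1) <= 2 * df
    assert np.trapezoid(np.where(near, sp.psd_ms2_per_hz, 0.0),
                        sp.frequencies_hz) >= 0.9 * total


def test_null_signal_has_zero_psd():
    sp = welch_psd(np.zeros(900))
    assert np.all(sp.psd_ms2_per_hz == 0.0)


def test_short_series_falls_back_to_single_window():
    with pytest.warns(UserWarning, match="single window"):
        sp = welch_psd(np.sin(np.arange(100)), WelchSettings(nperseg=256))
    assert sp.frequencies_hz.size > 0


def _spectrum(f, p):
    return SpectrumEstimate(frequencies_hz=np.asarray(f, float),
                            psd_ms2_per_hz=np.asarray(p, float),
                            settings=WelchSettings())


def test_equal_band_powers_give_symmetric_normalised_units():
    f = np.linspace(0.0, 0.5, 501)
    p = np.zeros_like(f)
    p[(f >= 0.08) & (f <= 0.12)] = 10.0   # inside LF
    p[(f >= 0.28) & (f <= 0.32)] = 10.0   # inside HF, same integral
    lf, hf, lf_nu, hf_nu, log_ratio = band_powers(_spectrum(f, p))
    assert lf == pytest.approx(hf, rel=1e-9)
    assert lf_nu == pytest.approx(50.0, abs=1e-6)
    assert hf_nu == pytest.approx(50.0, abs=1e-6)
    assert log_ratio == pytest.approx(0.0, abs=1e-9)
    assert lf_nu + hf_nu == pytest.approx(100.0, abs=1e-9)


def test_power_above_hf_band_is_flagged_undefined():
    f = np.linspace(0.0, 1.0, 401)
    p = np.where(f > 0.45, 5.0, 0.0)
    lf, hf, lf_nu, hf_nu, log_ratio = band_powers(_spectrum(f, p))
    assert lf == 0.0 and hf == 0.0
    assert math.isnan(lf_nu) and math.isnan(hf_nu) and math.isnan(log_ratio)


# ---------------------------------------------------------------- Poincaré

def test_constant_series_degenerate_ellipse():
    sd1, sd2, sd2_sd1, sd1_sd2 = poincare(make_segment([900.0] * 100))
    assert sd1 == 0.0 and sd2 == 0.0
    assert math.isnan(sd2_sd1) and math.isnan(sd1_sd2)


def test_perfect_alternation_has_only_perpendicular_spread():
    seg = make_segment([800.0, 1000.0] * 150)
    sd1, sd2, sd2_sd1, sd1_sd2 = poincare(seg)
    assert sd1 == pytest.approx(200.0 / math.sqrt(2.0), abs=2.0)
    assert sd2 == pytest.approx(0.0, abs=2.0)
    assert math.isnan(sd1_sd2)  # SD2 = 0, ratio flagged


def test_poincare_matches_rotated_coordinate_oracle(rng):
    for seg in random_segments(rng, 200):
        sd1, sd2, sd2_sd1, sd1_sd2 = poincare(seg)
        e1, e2 = poincare_loop(seg.nn_ms.tolist())
        assert sd1 == pytest.approx(e1, rel=1e-12)
        assert sd2 == pytest.approx(e2, rel=1e-12)
        assert sd2_sd1 == pytest.approx(e2 / e1, rel=1e-12)
        assert sd1_sd2 == pytest.approx(e1 / e2, rel=1e-12)


def test_sd1_sd2_identity_with_lag1_scatter_variance(rng):
    """SD1^2 + SD2^2 equals twice the variance of all plotted coordinates."""
    for seg in random_segments(rng, 100):
        sd1, sd2, *_ = poincare(seg)
        coords = np.concatenate([seg.nn_ms[:-1], seg.nn_ms[1:]])
        assert sd1 ** 2 + sd2 ** 2 == pytest.approx(
            2.0 * np.var(coords, ddof=1), rel=0.01)


# ---------------------------------------------------------------- aggregation

def test_compute_all_constant_segment_and_determinism():
    seg = make_segment([800.0] * 300)
    a = compute_all(seg)
    b = compute_all(seg)
    assert a == b
    assert a.mean_hr_bpm == pytest.approx(75.0)
    assert a.sdnn_ms == 0.0 and a.pnn50_pct == 0.0
    assert a.sd1_ms == 0.0 and a.sd2_ms == 0.0
    assert math.isnan(a.log10_lf_hf)
    assert a.mean_hr_bpm == pytest.approx(60000.0 / a.mean_nn_ms, rel=1e-12)


def test_compute_all_nu_invariant(rng):
    seg = next(random_segments(rng, 1))
    idx = compute_all(seg)
    assert idx.lf_nu + idx.hf_nu == pytest.approx(100.0, abs=1e-9)
    assert idx.sd1_sd2_ratio == pytest.approx(1.0 / idx.sd2_sd1_ratio, rel=1e-9)


def test_too_short_segment_raises_with_identity():
    seg = make_segment([800.0, 900.0], subject_id="S004")
    with pytest.raises(InsufficientDataError, match="S004"):
        compute_all(seg)
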