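"""Wavelet, red-noise, bandpass, recurrence and rate-of-change diagnostics."""

import numpy as np
import pytest

from palaeoveg.core import Series
from palaeoveg.timeseries import (
    bandpass,
    cwt,
    detrend,
    recurrence_det,
    rednoise_significance,
    roc_trend,
)


def make_series(values, dt=1.0):
    return Series(np.arange(len(values)) * dt, np.asarray(values, float))


def ar1(rng, n, phi=0.7, sigma=1.0):
    x = np.empty(n)
    x[0] = rng.standard_normal() * sigma / np.sqrt(1 - phi**2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.standard_normal() * sigma
    return x


# ---------------------------------------------------------------- detrend


def test_detrend_removes_pure_line():
    t = np.arange(100.0)
    out = detrend(make_series(3.0 + 0.5 * t))
    np.testing.assert_allclose(out.value, 0.0, atol=1e-9)


def test_detrend_recovers_sine_on_line():
    t = np.arange(2000.0)
    sine = np.sin(2 * np.pi * t / 40)
    out = detrend(make_series(sine + 0.01 * t + 5))
    # the sine leaks O(period/length) into the fitted line; long window -> small
    assert np.abs(out.value - (sine - sine.mean())).max() < 3 * 40 / len(t)
    assert np.corrcoef(out.value, sine)[0, 1] > 0.999
    assert out.value.mean() == pytest.approx(0.0, abs=1e-12)


def test_detrend_requires_uniform_spacing():
    s = Series(np.array([0.0, 1.0, 3.0]), np.zeros(3))
    with pytest.raises(ValueError, match="uniform"):
        detrend(s)


# ------------------------------------------------------------------- CWT


def test_cwt_peak_at_tone_period():
    t = np.arange(0, 1000, 1.0)
    res = cwt(make_series(np.sin(2 * np.pi * t / 20)))
    peak = res.period[np.argmax(res.global_power())]
    # within one grid step of 20 kyr
    idx = np.argmin(np.abs(res.period - 20))
    neighbours = res.period[max(idx - 1, 0) : idx + 2]
    assert neighbours.min() <= peak <= neighbours.max()


def test_cwt_power_concentrates_within_octave():
    t = np.arange(0, 2000, 1.0)
    res = cwt(make_series(np.sin(2 * np.pi * t / 41)))
    inside = (res.period >= 41 / np.sqrt(2)) & (res.period <= 41 * np.sqrt(2))
    gp = res.global_power()
    assert gp[inside].sum() / gp.sum() >= 0.5


def test_cwt_amplitude_doubling_quadruples_power():
    t = np.arange(0, 600, 1.0)
    base = np.sin(2 * np.pi * t / 25)
    r1 = cwt(make_series(base + 0.1))
    r2 = cwt(make_series(2 * base + 0.1))
    # normalized by variance the ratio cancels; compare unnormalized power
    p1 = r1.power * r1.variance
    p2 = r2.power * r2.variance
    mask = r1.inside_coi()
    ratio = p2[mask] / np.maximum(p1[mask], 1e-12)
    assert np.median(ratio) == pytest.approx(4.0, rel=0.05)


def test_cwt_rejects_too_long_period():
    t = np.arange(0, 100, 1.0)
    with pytest.raises(ValueError, match="shorter"):
        cwt(make_series(np.sin(t)), periods=np.array([80.0]))


def test_cwt_matches_pywavelets_peak():
    # independent implementation cross-check of the period localization
    import pywt

    t = np.arange(0, 800, 1.0)
    x = np.sin(2 * np.pi * t / 50)
    res = cwt(make_series(x))
    ours = res.period[np.argmax(res.global_power())]
    scales = np.arange(2, 200)
    coeffs, freqs = pywt.cwt(x, scales, "cmor1.5-1.0", sampling_period=1.0)
    theirs = 1.0 / freqs[np.argmax((np.abs(coeffs) ** 2).mean(axis=1))]
    assert ours == pytest.approx(theirs, rel=0.1)
    assert ours == pytest.approx(50.0, rel=0.1)


# ------------------------------------------------------------- red noise


def test_embedded_tone_detected_in_ar1(rng):
    t = np.arange(0, 1500, 1.0)
    x = 3 * np.sin(2 * np.pi * t / 41) + ar1(rng, len(t), 0.6)
    s = make_series(x)
    res = cwt(detrend(s))
    sig = rednoise_significance(res, s)
    band = np.abs(res.period - 41) < 5
    inside = res.inside_coi()
    frac_41 = sig[band[:, None] & inside].mean()
    assert frac_41 > 0.8


def test_false_positive_rate_near_level(rng):
    rates = []
    for _ in range(60):
        s = make_series(ar1(rng, 512, 0.7))
        res = cwt(s)
        sig = rednoise_significance(res, s)
        rates.append(sig[res.inside_coi()].mean())
    assert np.mean(rates) == pytest.approx(0.05, abs=0.025)


def test_rednoise_rejects_unit_root():
    s = make_series(np.zeros(64))
    with pytest.raises(ValueError):
        res = cwt(make_series(np.sin(np.arange(64.0))))
        rednoise_significance(res, s, alpha=1.0)


# -------------------------------------------------------------- bandpass


def test_bandpass_preserves_inband_tone():
    t = np.arange(0, 3000, 1.0)
    s = make_series(np.sin(2 * np.pi * t / 100))
    out = bandpass(s, (13, 250))
    assert np.std(out.value) / np.std(s.value) == pytest.approx(1.0, abs=0.02)


def test_bandpass_rejects_outband_tone():
    t = np.arange(0, 3000, 1.0)
    s = make_series(np.sin(2 * np.pi * t / 500))
    out = bandpass(s, (13, 250))
    assert np.std(out.value) / np.std(s.value) < 0.05


def test_bandpass_removes_linear_trend():
    t = np.arange(0, 2000, 1.0)
    out = bandpass(make_series(0.01 * t + 3), (13, 250))
    assert np.abs(out.value).max() < 1e-6


def test_bandpass_idempotent():
    rng = np.random.default_rng(5)
    t = np.arange(0, 2000, 1.0)
    s = make_series(rng.standard_normal(len(t)))
    once = bandpass(s, (13, 250))
    twice = bandpass(once, (13, 250))
    # response is exactly 1 in the passband; only the taper transitions differ
    assert np.sqrt(np.mean((twice.value - once.value) ** 2)) < 0.15 * np.std(once.value)


def test_bandpass_band_outside_resolvable():
    s = make_series(np.zeros(100))
    with pytest.raises(ValueError):
        bandpass(s, (0.5, 50))
    with pytest.raises(ValueError):
        bandpass(s, (13, 10000))


# ------------------------------------------------------------ recurrence


def test_det_constant_series_fully_deterministic():
    s = make_series(np.zeros(200))
    assert recurrence_det(s, eps=0.5) == pytest.approx(1.0, abs=1e-3)


def test_det_sine_above_09():
    t = np.arange(200.0)
    s = make_series(np.sin(2 * np.pi * t / 20))
    d = recurrence_det(s, eps=0.2)
    assert d > 0.9


def test_det_iid_noise_near_zero(rng):
    s = make_series(rng.standard_normal(300))
    d = recurrence_det(s, eps=0.1, embed=3, delay=1)
    assert d < 0.2


def test_det_bounds_and_monotone_in_eps(rng):
    s = make_series(ar1(rng, 150, 0.5))
    eps_grid = [0.2, 0.5, 1.0, 2.0, 5.0]
    dets = [recurrence_det(s, eps=e, delay=1) for e in eps_grid]
    assert all(0.0 <= d <= 1.0 for d in dets)
    assert all(b >= a - 1e-12 for a, b in zip(dets, dets[1:]))


def test_det_brute_force_small_case(rng):
    # independent O(n^3) recurrence computation on a short series
    x = ar1(rng, 40, 0.3)
    m, tau, eps, l_min = 2, 1, 0.8, 2
    n = len(x) - (m - 1) * tau
    V = np.column_stack([x[:n], x[tau : tau + n]])
    R = np.zeros((n, n), bool)
    for i in range(n):
        for j in range(n):
            R[i, j] = np.linalg.norm(V[i] - V[j]) <= eps
    total = long = 0
    for k in range(1, n):
        run = 0
        for i in range(n - k):
            if R[i, i + k]:
                run += 1
            if not R[i, i + k] or i == n - k - 1:
                if run:
                    total += run
                    if run >= l_min:
                        long += run
                run = 0
    expected = long / total if total else 0.0
    got = recurrence_det(make_series(x), eps=eps, embed=m, delay=tau, l_min=l_min)
    assert got == pytest.approx(expected, abs=1e-12)


def test_det_windowed_series(rng):
    t = np.arange(400.0)
    x = np.where(t < 200, np.sin(2 * np.pi * t / 20), 0.0)
    x = x + rng.standard_normal(400) * np.where(t < 200, 0.02, 1.0)
    out = recurrence_det(make_series(x), eps=0.3, window=100.0, delay=1)
    early = out.value[out.age < 120]
    late = out.value[out.age > 280]
    assert early.mean() > late.mean() + 0.3


def test_det_eps_validation():
    s = make_series(np.arange(50.0))
    with pytest.raises(ValueError):
        recurrence_det(s, eps=-1.0)


# ---------------------------------------------------------- rate of change


def test_roc_flags_whole_line():
    t = np.arange(0, 200, 1.0)
    r = roc_trend(make_series(2.0 + 0.3 * t), n_sim=2000)
    # z-scored slope is 1/std(t); flagged everywhere
    assert r.significant.all()
    np.testing.assert_allclose(r.deriv, 1 / np.std(t), rtol=0.05)


def test_roc_constant_no_flags(rng):
    t = np.arange(0, 200, 1.0)
    r = roc_trend(make_series(1.0 + 0.1 * rng.standard_normal(200)), n_sim=2000)
    assert not r.significant.any()


def test_roc_step_bracketed(rng):
    t = np.arange(0, 300, 1.0)
    y = np.where(t < 150, 0.0, 3.0) + 0.3 * rng.standard_normal(300)
    r = roc_trend(make_series(y), n_sim=2000)
    ivals = r.change_intervals()
    assert len(ivals) >= 1
    lo, hi = min(i[0] for i in ivals), max(i[1] for i in ivals)
    assert lo <= 150 <= hi
    assert hi - lo < 120  # localized, not the whole record


def test_roc_needs_enough_points():
    with pytest.raises(ValueError):
        roc_trend(make_series(np.arange(10.0)), k=20)
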