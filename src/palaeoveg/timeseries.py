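"""Spectral and recurrence diagnostics for proxy time series.

All routines operate on uniformly resampled :class:`~palaeoveg.core.Series`
(see :func:`palaeoveg.core.resample_uniform`). The module provides

* :func:`detrend` — linear or mean detrending;
* :func:`cwt` — Morlet (ω₀ = 6) continuous wavelet transform in the
  Torrence–Compo formulation, variance-normalized, with cone of influence;
* :func:`rednoise_significance` — pointwise 95 % chi-square test of wavelet
  power against the theoretical AR(1) (red-noise) background spectrum;
* :func:`bandpass` — frequency-domain filter with cosine-tapered edges;
* :func:`recurrence_det` — recurrence-plot determinism (DET), the fraction
  of recurrence points on diagonal lines of length ≥ ``l_min``, optionally
  in sliding windows; values near 0 mean unpredictable dynamics;
* :func:`roc_trend` — rate-of-change analysis: penalized-spline trend with
  REML smoothness selection, first derivative by finite differences, and
  simultaneous 95 % intervals identifying periods of substantial change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar

from palaeoveg.core import Series

__all__ = [
    "CWTResult",
    "RocResult",
    "detrend",
    "cwt",
    "rednoise_significance",
    "bandpass",
    "recurrence_det",
    "roc_trend",
]

MORLET_OMEGA0 = 6.0
#: Fourier factor: period = factor × scale for Morlet ω₀
FOURIER_FACTOR = 4 * np.pi / (MORLET_OMEGA0 + np.sqrt(2 + MORLET_OMEGA0**2))


def _uniform_dt(s: Series) -> float:
    srt = s.ascending()
    d = np.diff(srt.age)
    if len(d) == 0:
        raise ValueError("series too short")
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise ValueError("series must be uniformly spaced (resample first)")
    return float(d[0])


def detrend(s: Series, mode: str = "linear") -> Series:
    """Remove a least-squares linear trend (default) or the mean.

    Output has exactly zero mean. Requires uniform spacing.
    """
    _uniform_dt(s)
    srt = s.ascending()
    y = srt.value.astype(float)
    if mode == "linear":
        t = srt.age - srt.age.mean()
        coef = np.polyfit(t, y, 1)
        resid = y - np.polyval(coef, t)
    elif mode == "mean":
        resid = y - y.mean()
    else:
        raise ValueError(f"unknown detrend mode {mode!r}")
    resid = resid - resid.mean()
    return Series(srt.age, resid, s.label)


# ---------------------------------------------------------------------------
# continuous wavelet transform (Torrence & Compo style Morlet)
# ---------------------------------------------------------------------------


@dataclass
class CWTResult:
    age: np.ndarray  # kyr grid (ascending)
    period: np.ndarray  # kyr
    power: np.ndarray  # (n_period, n_time), normalized by series variance
    coi: np.ndarray  # max unaffected period per time point (kyr)
    dt: float
    variance: float

    def inside_coi(self) -> np.ndarray:
        """Boolean mask of points unaffected by edge effects."""
        return self.period[:, None] <= self.coi[None, :]

    def global_power(self) -> np.ndarray:
        return self.power.mean(axis=1)


def cwt(s: Series, periods=None, dj: float = 0.1) -> CWTResult:
    """Morlet (ω₀ = 6) continuous wavelet transform.

    Power is normalized by the series variance so that, for a red-noise
    input, expected normalized power equals the AR(1) background spectrum.
    ``periods`` defaults to a log grid from 2·dt up to half the record
    length (spacing ``dj`` octaves).
    """
    dt = _uniform_dt(s)
    srt = s.ascending()
    x = srt.value - srt.value.mean()
    n = len(x)
    variance = float(x.var(ddof=0))
    if variance == 0:
        raise ValueError("constant series has no spectrum")
    if periods is None:
        p_min, p_max = 2 * dt, n * dt / 2
        n_scales = int(np.floor(np.log2(p_max / p_min) / dj)) + 1
        periods = p_min * 2 ** (dj * np.arange(n_scales))
    periods = np.asarray(periods, dtype=float)
    if np.max(periods) > n * dt / 2 * (1 + 1e-9) + 1e-12:
        raise ValueError("series shorter than twice the longest requested period")
    scales = periods / FOURIER_FACTOR

    # zero-pad to next power of two to limit wrap-around
    n_pad = int(2 ** np.ceil(np.log2(n)))
    xhat = np.fft.fft(x, n_pad)
    omega = 2 * np.pi * np.fft.fftfreq(n_pad, dt)
    W = np.empty((len(scales), n), dtype=complex)
    for i, sc in enumerate(scales):
        # Morlet daughter in frequency space, unit-energy normalization
        psi = (
            np.sqrt(2 * np.pi * sc / dt)
            * np.pi**-0.25
            * np.exp(-0.5 * (sc * omega - MORLET_OMEGA0) ** 2)
            * (omega > 0)
        )
        W[i] = np.fft.ifft(xhat * psi)[:n]
    power = np.abs(W) ** 2 / variance

    # cone of influence: e-folding time sqrt(2)·scale
    edge = dt * np.minimum(np.arange(n), np.arange(n)[::-1])
    coi = FOURIER_FACTOR / np.sqrt(2) * np.maximum(edge, dt * 1e-9)
    return CWTResult(srt.age, periods, power, coi, dt, variance)


def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = np.sum(x * x)
    if denom == 0:
        return 0.0
    return float(np.sum(x[1:] * x[:-1]) / denom)


def rednoise_significance(
    result: CWTResult, s: Series, level: float = 0.95, alpha: float | None = None
) -> np.ndarray:
    """Pointwise chi-square test of wavelet power against AR(1) red noise.

    The lag-1 autocorrelation ``alpha`` is estimated from ``s`` unless given.
    Normalized wavelet power is distributed as P_k·χ²₂/2 under the AR(1)
    null, where P_k is the discrete Fourier red-noise spectrum at the scale's
    equivalent Fourier period. Returns a boolean mask of significant points.
    """
    srt = s.ascending()
    if alpha is None:
        alpha = _lag1_autocorr(srt.value.astype(float))
    if alpha >= 1:
        raise ValueError("lag-1 autocorrelation must be < 1")
    alpha = max(alpha, 0.0)
    freq = result.dt / result.period  # cycles per step
    pk = (1 - alpha**2) / (1 + alpha**2 - 2 * alpha * np.cos(2 * np.pi * freq))
    chi2_crit = stats.chi2.ppf(level, 2) / 2
    return result.power > (pk * chi2_crit)[:, None]


# ---------------------------------------------------------------------------
# bandpass
# ---------------------------------------------------------------------------


def bandpass(s: Series, band=(13.0, 250.0), taper: float = 0.1) -> Series:
    """Frequency-domain bandpass keeping periods within ``band`` (kyr).

    The series is linearly detrended, transformed, multiplied by a response
    that is 1 inside the band and falls to 0 over a raised-cosine transition
    of relative width ``taper`` at each edge, and back-transformed.
    """
    dt = _uniform_dt(s)
    p_min, p_max = sorted(float(b) for b in band)
    n = len(s)
    if p_min < 2 * dt:
        raise ValueError(f"short-period edge {p_min} kyr below Nyquist period {2*dt} kyr")
    if p_max > n * dt:
        raise ValueError(f"long-period edge {p_max} kyr exceeds record length {n*dt} kyr")
    srt = s.ascending()
    y = detrend(srt).value
    f = np.abs(np.fft.fftfreq(n, dt))
    f_lo, f_hi = 1.0 / p_max, 1.0 / p_min

    def edge(fv, f0, width, rising):
        resp = np.zeros_like(fv)
        lo, hi = f0 - width, f0 + width
        inside = (fv >= lo) & (fv <= hi)
        ramp = 0.5 * (1 - np.cos(np.pi * (fv[inside] - lo) / (2 * width)))
        resp[inside] = ramp if rising else 1 - ramp
        resp[fv > hi] = 1.0 if rising else 0.0
        resp[fv < lo] = 0.0 if rising else 1.0
        return resp

    response = edge(f, f_lo, taper * f_lo, rising=True) * edge(
        f, f_hi, taper * f_hi, rising=False
    )
    out = np.real(np.fft.ifft(np.fft.fft(y) * response))
    return Series(srt.age, out, s.label)


# ---------------------------------------------------------------------------
# recurrence / determinism
# ---------------------------------------------------------------------------


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = len(x) - (m - 1) * tau
    if n < 2:
        raise ValueError("series too short for the requested embedding")
    return np.column_stack([x[i * tau : i * tau + n] for i in range(m)])


def _det_of_matrix(R: np.ndarray, l_min: int) -> float:
    """DET from a boolean recurrence matrix, main diagonal excluded."""
    n = len(R)
    total = 0
    long_enough = 0
    for k in range(1, n):
        diag = np.diagonal(R, offset=k)
        # run lengths of True values
        padded = np.concatenate(([False], diag, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        lengths = edges[1::2] - edges[0::2]
        total += lengths.sum()
        long_enough += lengths[lengths >= l_min].sum()
    if total == 0:
        return 0.0
    return float(long_enough) / float(total)


def first_acf_zero(x: np.ndarray, max_lag: int | None = None) -> int:
    """First lag at which the autocorrelation crosses zero (min 1)."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    denom = np.sum(x * x)
    if denom == 0:
        return 1
    max_lag = max_lag or len(x) // 2
    for lag in range(1, max_lag):
        if np.sum(x[lag:] * x[:-lag]) / denom <= 0:
            return lag
    return max(1, max_lag - 1)


def recurrence_det(
    s: Series,
    eps: float | None = None,
    l_min: int = 2,
    window: float | None = None,
    step: float | None = None,
    embed: int = 3,
    delay: int | None = None,
) -> float | Series:
    """Recurrence determinism (DET) of a uniformly spaced series.

    State vectors are delay embeddings of dimension ``embed`` with delay
    ``delay`` (default: first autocorrelation zero). Two states recur when
    their Euclidean distance is ≤ ``eps`` (default: 10 % of the embedded
    cloud's bounding-box diagonal). DET is the fraction of recurrence points
    forming diagonal lines of length ≥ ``l_min``, the main diagonal excluded.

    With ``window`` (kyr) the statistic is evaluated in sliding windows
    (step defaults to window/4) and returned as a Series at window centres;
    otherwise a single float is returned.
    """
    dt = _uniform_dt(s)
    srt = s.ascending()
    x = srt.value.astype(float)
    if delay is None:
        delay = first_acf_zero(x)
    if eps is None:
        rng = np.ptp(x)
        eps = 0.1 * rng * np.sqrt(embed)
        if eps <= 0:
            raise ValueError("cannot infer eps from a constant series; pass eps")
    if eps <= 0:
        raise ValueError("eps must be positive")

    def _one(xw: np.ndarray) -> float:
        # cap the delay so the embedding leaves enough state vectors
        tau = max(1, min(delay, (len(xw) - 10) // max(embed - 1, 1)))
        V = _embed(xw, embed, tau)
        d2 = np.sum((V[:, None, :] - V[None, :, :]) ** 2, axis=-1)
        R = d2 <= eps * eps
        return _det_of_matrix(R, l_min)

    if window is None:
        if len(x) < 10:
            raise ValueError("need at least 10 points")
        return _one(x)

    w_pts = int(round(window / dt))
    if w_pts < 10:
        raise ValueError("window must cover at least 10 points")
    s_pts = max(1, int(round((step if step is not None else window / 4) / dt)))
    centres, dets = [], []
    for start in range(0, len(x) - w_pts + 1, s_pts):
        seg = x[start : start + w_pts]
        centres.append(srt.age[start] + (w_pts - 1) * dt / 2)
        dets.append(_one(seg))
    return Series(np.array(centres), np.array(dets), label=f"DET({s.label})")


# ---------------------------------------------------------------------------
# rate-of-change: penalized-spline trend + derivative + simultaneous CI
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    grid: np.ndarray  # evaluation grid (age units of the input)
    trend: np.ndarray  # fitted trend of the z-scored series
    deriv: np.ndarray  # first derivative of the trend
    deriv_lo: np.ndarray  # simultaneous lower band
    deriv_hi: np.ndarray  # simultaneous upper band
    significant: np.ndarray  # band excludes zero
    lambda_: float  # selected smoothing parameter

    def change_intervals(self) -> list[tuple[float, float]]:
        """Contiguous grid intervals flagged as substantial change."""
        out = []
        sig = self.significant
        i = 0
        while i < len(sig):
            if sig[i]:
                j = i
                while j + 1 < len(sig) and sig[j + 1]:
                    j += 1
                out.append((float(self.grid[i]), float(self.grid[j])))
                i = j + 1
            else:
                i += 1
        return out


def _bspline_design(x: np.ndarray, k: int, degree: int = 3):
    """Cubic B-spline design matrix with k basis functions on range(x)."""
    xl, xr = x.min(), x.max()
    n_interior = k - degree - 1
    if n_interior < 0:
        raise ValueError("too few basis functions for a cubic spline")
    interior = np.linspace(xl, xr, n_interior + 2)[1:-1]
    t = np.concatenate([[xl] * (degree + 1), interior, [xr] * (degree + 1)])
    X = BSpline.design_matrix(np.clip(x, xl, xr), t, degree).toarray()
    return X, t


def roc_trend(
    s: Series,
    k: int = 20,
    grid_size: int = 200,
    n_sim: int = 10_000,
    level: float = 0.95,
    seed: int | None = 0,
) -> RocResult:
    """Penalized-spline trend of a z-scored series with derivative bands.

    The input is z-score transformed, fitted with a cubic B-spline
    (``k`` basis functions, second-difference penalty) whose smoothing
    parameter is selected by restricted maximum likelihood, and the trend's
    first derivative is computed by central finite differences on a fine
    grid. A simultaneous ``level`` interval for the derivative is built by
    simulating ``n_sim`` draws from the posterior of the spline
    coefficients; grid points where the band excludes zero mark periods of
    substantial change.
    """
    srt = s.ascending()
    x = srt.age.astype(float)
    y = srt.value.astype(float)
    n = len(x)
    if n <= k:
        raise ValueError(f"need more than k={k} points (got {n})")
    sd = y.std(ddof=0)
    y = (y - y.mean()) / (sd if sd > 0 else 1.0)

    X, knots = _bspline_design(x, k)
    D = np.diff(np.eye(k), n=2, axis=0)
    S = D.T @ D
    XtX = X.T @ X
    Xty = X.T @ y
    null_dim = 2  # second-difference penalty leaves linear functions unpenalized

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        A = XtX + lam * S
        try:
            beta = np.linalg.solve(A, Xty)
        except np.linalg.LinAlgError:
            return np.inf
        rss = np.sum((y - X @ beta) ** 2)
        pen = lam * beta @ S @ beta
        # eigenvalues of the penalty for the log|lam*S|_+ term
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        s_eig = np.linalg.eigvalsh(S)
        s_pos = s_eig[s_eig > s_eig.max() * 1e-10]
        logdet_lamS = np.sum(np.log(lam * s_pos))
        nn = n - null_dim
        return nn * np.log(rss + pen) + logdet_A - logdet_lamS

    res = minimize_scalar(neg2_reml, bounds=(-10, 20), method="bounded")
    lam = float(np.exp(res.x))
    A = XtX + lam * S
    Ainv = np.linalg.inv(A)
    beta = Ainv @ Xty
    rss = np.sum((y - X @ beta) ** 2)
    edf = np.trace(Ainv @ XtX)
    sigma2 = rss / max(n - edf, 1.0)
    Vb = sigma2 * Ainv  # Bayesian posterior covariance of the coefficients

    h = (x.max() - x.min()) / (grid_size * 20)
    # inset by h so the central-difference stencil stays inside the range
    grid = np.linspace(x.min() + h, x.max() - h, grid_size)
    deg = 3
    Xg = BSpline.design_matrix(np.clip(grid, x.min(), x.max()), knots, deg).toarray()
    Xp = BSpline.design_matrix(
        np.clip(grid + h, x.min(), x.max()), knots, deg
    ).toarray()
    Xm = BSpline.design_matrix(
        np.clip(grid - h, x.min(), x.max()), knots, deg
    ).toarray()
    Xd = (Xp - Xm) / (2 * h)  # finite-difference derivative design

    trend = Xg @ beta
    deriv = Xd @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xd, Vb, Xd), 1e-300))

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(Vb + 1e-12 * np.eye(k) * np.trace(Vb) / k)
    draws = beta[None, :] + rng.standard_normal((n_sim, k)) @ L.T
    dev = np.abs((draws @ Xd.T) - deriv[None, :]) / se[None, :]
    crit = float(np.quantile(dev.max(axis=1), level))

    lo = deriv - crit * se
    hi = deriv + crit * se
    sig = (lo > 0) | (hi < 0)
    return RocResult(grid, trend, deriv, lo, hi, sig, lam)
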