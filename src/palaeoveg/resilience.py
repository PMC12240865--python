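"""Ecosystem resilience from categorical megabiome sequences.

Resilience is summarized by two durations extracted from the time-ordered
megabiome labels:

* **residence time** — how long a megabiome persists. A transition boundary
  is placed at the age midpoint of the two adjacent samples where the label
  changes; episodes tile the record exactly. The first and last episodes are
  bounded by the first/last sample age and flagged edge-censored.
* **recovery time** — the elapsed time from a megabiome's last occurrence
  (end of a maximal run, forward in calendar time) to its first
  reoccurrence. A megabiome that never returns is flagged censored
  ("not recovering").

Longer residence and shorter recovery mean higher resilience. Trends along
time or a climate gradient are fitted with a tricube-weighted local linear
(LOESS) smoother with case-resampling bootstrap confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from palaeoveg.biomization import BiomeSequence
from palaeoveg.core import Series

__all__ = [
    "Episode",
    "Recovery",
    "ResilienceTable",
    "residence_times",
    "recovery_times",
    "loess_trend",
    "resilience_vs_climate",
    "gmst_rate_of_change",
]


@dataclass(frozen=True)
class Episode:
    megabiome: str
    t_start: float  # ka BP (older end)
    t_end: float  # ka BP (younger end)
    residence: float  # kyr
    edge_censored: bool


@dataclass(frozen=True)
class Recovery:
    megabiome: str
    t_last: float  # ka BP of last occurrence before the gap
    t_return: float  # ka BP of first reoccurrence (NaN if censored)
    recovery: float  # kyr (NaN if censored)
    censored: bool


@dataclass
class ResilienceTable:
    episodes: list[Episode]
    recoveries: list[Recovery]

    def episodes_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.episodes])

    def recoveries_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.recoveries])

    def mean_residence(self, include_censored: bool = False) -> pd.Series:
        df = self.episodes_frame()
        if not include_censored:
            df = df[~df.edge_censored]
        return df.groupby("megabiome")["residence"].mean()

    def mean_recovery(self, include_censored: bool = False) -> pd.Series:
        """Mean recovery per megabiome; censored (never-returning) intervals
        are excluded by default because their duration is unbounded."""
        df = self.recoveries_frame()
        if not include_censored:
            df = df[~df.censored]
        return df.groupby("megabiome")["recovery"].mean()


def _runs(seq: BiomeSequence) -> list[tuple[str, int, int]]:
    """Maximal runs as (label, first index, last index) in old→young order."""
    labels = seq.megabiome
    runs = []
    start = 0
    for i in range(1, len(labels)):
        if labels[i] != labels[start]:
            runs.append((labels[start], start, i - 1))
            start = i
    runs.append((labels[start], start, len(labels) - 1))
    return runs


def residence_times(seq: BiomeSequence) -> list[Episode]:
    """Episodes of persistence, with boundaries at transition midpoints.

    Episode durations tile the record: they sum to (oldest − youngest
    sample age) exactly.
    """
    if len(seq) < 2:
        raise ValueError("need at least two samples to extract episodes")
    age = seq.age  # decreasing, old → young
    runs = _runs(seq)
    episodes = []
    for k, (label, i0, i1) in enumerate(runs):
        t_start = age[0] if k == 0 else 0.5 * (age[i0 - 1] + age[i0])
        t_end = age[-1] if k == len(runs) - 1 else 0.5 * (age[i1] + age[i1 + 1])
        episodes.append(
            Episode(
                megabiome=label,
                t_start=float(t_start),
                t_end=float(t_end),
                residence=float(t_start - t_end),
                edge_censored=(k == 0 or k == len(runs) - 1),
            )
        )
    return episodes


def recovery_times(seq: BiomeSequence) -> list[Recovery]:
    """Time from the end of each maximal run to the next sample of the same
    megabiome; censored when the megabiome never reoccurs.

    Runs forward in calendar time (old → young). Reversing the input
    sequence therefore yields the mirrored intervals, not the same ones.
    """
    if len(seq) < 2:
        raise ValueError("need at least two samples to extract recoveries")
    age = seq.age
    labels = seq.megabiome
    out = []
    for label, i0, i1 in _runs(seq):
        if i1 == len(labels) - 1:
            continue  # run reaches the young end: no gap follows
        nxt = next((j for j in range(i1 + 1, len(labels)) if labels[j] == label), None)
        if nxt is None:
            out.append(Recovery(label, float(age[i1]), float("nan"), float("nan"), True))
        else:
            out.append(
                Recovery(label, float(age[i1]), float(age[nxt]), float(age[i1] - age[nxt]), False)
            )
    return out


def resilience_table(seq: BiomeSequence) -> ResilienceTable:
    return ResilienceTable(residence_times(seq), recovery_times(seq))


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------


def _loess_fit(x, y, x0, span, degree=1):
    n = len(x)
    q = int(np.ceil(span * n))
    if q < degree + 2:
        raise ValueError(
            f"span {span} gives a {q}-point window; need at least {degree + 2}"
        )
    if q > n:
        raise ValueError(f"span {span} needs {q} points but only {n} available")
    out = np.empty(len(x0))
    for j, xx in enumerate(x0):
        d = np.abs(x - xx)
        h = np.partition(d, q - 1)[q - 1]
        if h == 0:
            out[j] = y[d == 0].mean()
            continue
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        if degree == 0:
            out[j] = np.average(y, weights=w)
            continue
        X = np.column_stack([np.ones(n), x - xx])
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y, rcond=None)
        out[j] = beta[0]
    return out


def loess_trend(
    x,
    y,
    span: float = 0.75,
    n_boot: int = 1000,
    grid=None,
    degree: int = 1,
    seed: int | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Tricube-weighted local linear fit with a bootstrap confidence band.

    Returns a DataFrame with columns ``x, fit, lo, hi`` on ``grid`` (default:
    the sorted unique x). The band is percentile-based over ``n_boot``
    case-resampling replicates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 points for a LOESS trend")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if grid is None:
        grid = np.unique(x)
    grid = np.asarray(grid, dtype=float)
    fit = _loess_fit(x, y, grid, span, degree)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(grid)))
    n = len(x)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        o = np.argsort(xb)
        boots[b] = _loess_fit(xb[o], yb[o], grid, span, degree)
    alpha = (1 - level) / 2
    lo, hi = np.percentile(boots, [100 * alpha, 100 * (1 - alpha)], axis=0)
    return pd.DataFrame({"x": grid, "fit": fit, "lo": lo, "hi": hi})


def resilience_vs_climate(
    table: ResilienceTable,
    driver: Series,
    normalize: bool = True,
    span: float = 0.75,
    n_boot: int = 200,
    seed: int | None = None,
    recovery_match: str = "midpoint",
    norm_method: str = "zscore",
) -> tuple[pd.DataFrame, dict]:
    """Match residence/recovery durations to a driver and fit LOESS curves.

    The driver is linearly interpolated at the episode midpoint (residence)
    or the gap midpoint (recovery; ``recovery_match='start'`` uses the gap's
    old end instead). Durations are normalized within megabiome (z-score by
    default, min–max with ``norm_method='minmax'``). Censored entries and
    points outside the driver span are dropped. Returns the matched table
    and a dict of LOESS curves keyed by (megabiome, kind).
    """
    drv = driver.ascending()
    lo, hi = drv.age[0], drv.age[-1]

    rows = []
    for e in table.episodes:
        if e.edge_censored:
            continue
        mid = 0.5 * (e.t_start + e.t_end)
        if lo <= mid <= hi:
            rows.append((e.megabiome, "residence", mid, e.residence))
    for r in table.recoveries:
        if r.censored:
            continue
        t = 0.5 * (r.t_last + r.t_return) if recovery_match == "midpoint" else r.t_last
        if lo <= t <= hi:
            rows.append((r.megabiome, "recovery", t, r.recovery))
    df = pd.DataFrame(rows, columns=["megabiome", "kind", "age", "value"])
    if df.empty:
        return df.assign(driver=[], value_norm=[]), {}
    df["driver"] = np.interp(df["age"], drv.age, drv.value)

    def _norm(g):
        v = g["value"].to_numpy(float)
        if not normalize:
            return v
        if norm_method == "minmax":
            rng_ = v.max() - v.min()
            return (v - v.min()) / rng_ if rng_ > 0 else np.zeros_like(v)
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    df["value_norm"] = np.nan
    for key, g in df.groupby(["megabiome", "kind"]):
        df.loc[g.index, "value_norm"] = _norm(g)

    curves = {}
    for key, g in df.groupby(["megabiome", "kind"]):
        if len(g) >= 10:
            curves[key] = loess_trend(
                g["driver"], g["value_norm"], span=span, n_boot=n_boot, seed=seed
            )
    return df, curves


def gmst_rate_of_change(gmst: Series) -> Series:
    """Rate of change (°C kyr⁻¹) as consecutive first differences.

    Computed forward in calendar time (old → young) and assigned to the
    younger point of each pair; irregular spacing is handled as
    Δvalue/Δelapsed-time.
    """
    if len(gmst) < 2:
        raise ValueError("need at least two points")
    s = gmst.ascending()  # age increasing = older to the right
    age, val = s.age, s.value
    # forward time runs right-to-left on the age axis
    rate = (val[:-1] - val[1:]) / (age[1:] - age[:-1])
    return Series(age[:-1], rate, label=f"d({gmst.label})/dt")
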