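"""Driver attribution and modern calibration.

Two groups of tools live here. The first attributes variability in a
vegetation proxy (AP%) to exogenous drivers — summer insolation, global ice
volume (δ¹⁸O, sign-flipped so that low = low ice), and CO₂ — via a
recursive standardized path model: each endogenous variable is regressed on
its parents by ordinary least squares on z-scored series, edge coefficients
are standardized partial coefficients, and indirect effects are products of
coefficients along directed paths. Because 1-kyr interpolation manufactures
serial dependence, p-values are reported both naive and corrected with a
lag-1 effective-sample-size adjustment.

The second group calibrates taxa against modern climate: weighted-averaging
optima/tolerances from a site × taxon percentage table, and Gaussian kernel
density estimates of the climate occupied by a vegetation type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from palaeoveg.core import Series, resample_uniform
from palaeoveg.timeseries import bandpass

__all__ = [
    "PathModel",
    "prepare_sem_inputs",
    "fit_path_model",
    "spearman_matrix",
    "wa_optima",
    "climate_pdf",
    "ClimatePDF",
]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def prepare_sem_inputs(
    ap: Series,
    lr04: Series,
    co2: Series,
    insol: Series,
    scale: str = "all",
    dt: float = 1.0,
    band=(13.0, 250.0),
) -> pd.DataFrame:
    """Align, transform and standardize the path-model inputs.

    δ¹⁸O is multiplied by −1 (so low values mean low ice volume); with
    ``scale='orbital'`` the AP% series is bandpass-filtered to the orbital
    window before standardization; all series are linearly interpolated to a
    common ``dt``-kyr grid restricted to the overlapping age span and
    z-scored. Columns: ``ap, ice, co2, insolation``; index: age (ka).
    """
    if scale not in ("all", "orbital"):
        raise ValueError("scale must be 'all' or 'orbital'")
    lr04 = Series(lr04.age, -lr04.value, lr04.label)
    series = {"ap": ap, "ice": lr04, "co2": co2, "insolation": insol}
    grids = {}
    for name, s in series.items():
        u = resample_uniform(s, dt)
        grids[name] = u
    lo = max(g.age[0] for g in grids.values())
    hi = min(g.age[-1] for g in grids.values())
    if hi - lo < 100.0:
        raise ValueError(f"overlapping span {hi - lo:.1f} kyr is < 100 kyr")
    n = int(np.floor((hi - lo) / dt)) + 1
    grid = lo + dt * np.arange(n)
    cols = {}
    for name, u in grids.items():
        v = np.interp(grid, u.age, u.value)
        if name == "ap" and scale == "orbital":
            v = bandpass(Series(grid, v), band=band).value
        cols[name] = _zscore(v)
    return pd.DataFrame(cols, index=pd.Index(grid, name="age_ka"))


@dataclass
class PathModel:
    """A fitted recursive (acyclic) standardized path model."""

    nodes: list[str]
    edges: list[tuple[str, str]]
    coefficients: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    p_values_ess: dict[tuple[str, str], float]  # lag-1 ESS-corrected
    covariances: dict[tuple[str, str], float]  # exogenous correlations
    r_squared: dict[str, float] = field(default_factory=dict)

    def stars(self, edge: tuple[str, str], corrected: bool = True) -> str:
        """Significance stars: '***' for P<0.001, '**' for 0.001<P<0.01."""
        p = (self.p_values_ess if corrected else self.p_values)[edge]
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        return ""

    def indirect_effect(self, path: list[str]) -> float:
        """Product of edge coefficients along a directed path."""
        out = 1.0
        for a, b in zip(path, path[1:]):
            out *= self.coefficients[(a, b)]
        return out

    def total_effect(self, source: str, target: str) -> float:
        """Sum of effects over every directed path from source to target."""
        children = {}
        for a, b in self.edges:
            children.setdefault(a, []).append(b)

        def walk(node, weight):
            if node == target:
                return weight
            return sum(
                walk(c, weight * self.coefficients[(node, c)])
                for c in children.get(node, [])
            )

        return walk(source, 1.0)


def _check_acyclic(nodes, edges):
    children = {n: [] for n in nodes}
    for a, b in edges:
        children[a].append(b)
    state = {n: 0 for n in nodes}

    def visit(n):
        if state[n] == 1:
            raise ValueError("path-model edge set contains a cycle")
        if state[n] == 2:
            return
        state[n] = 1
        for c in children[n]:
            visit(c)
        state[n] = 2

    for n in nodes:
        visit(n)


def _ess(x: np.ndarray, y: np.ndarray) -> float:
    """Effective sample size from lag-1 autocorrelations (Bretherton)."""
    n = len(x)

    def r1(v):
        v = v - v.mean()
        den = np.sum(v * v)
        return np.sum(v[1:] * v[:-1]) / den if den > 0 else 0.0

    rx, ry = r1(x), r1(y)
    factor = (1 - rx * ry) / (1 + rx * ry) if (1 + rx * ry) != 0 else 1.0
    return max(3.0, n * max(factor, 1e-3))


def fit_path_model(
    data: pd.DataFrame,
    edges: list[tuple[str, str]],
    condition_warn: float = 1e4,
) -> PathModel:
    """Fit a recursive path model by per-equation least squares.

    ``data`` holds z-scored columns; ``edges`` is an acyclic (parent, child)
    list. Each endogenous node is regressed on all its parents; the edge
    coefficient is the standardized partial regression coefficient, with
    t-test p-values reported both naive and corrected for serial dependence
    via a lag-1 effective sample size. Correlations among exogenous nodes
    are reported as covariances.
    """
    nodes = list(data.columns)
    edges = [(str(a), str(b)) for a, b in edges]
    for a, b in edges:
        if a not in nodes or b not in nodes:
            raise ValueError(f"edge ({a}, {b}) references unknown node")
    _check_acyclic(nodes, edges)
    parents: dict[str, list[str]] = {}
    for a, b in edges:
        parents.setdefault(b, []).append(a)

    Z = data.apply(lambda c: _zscore(c.to_numpy(float)))
    n = len(Z)
    coeffs, pvals, pvals_ess, r2 = {}, {}, {}, {}
    for child, pars in parents.items():
        X = Z[pars].to_numpy()
        y = Z[child].to_numpy()
        cond = np.linalg.cond(X.T @ X)
        if cond > condition_warn:
            vifs = {
                p: float(
                    1.0
                    / max(
                        1e-12,
                        1
                        - _r2_of(X[:, [j for j in range(len(pars)) if j != i]], X[:, i]),
                    )
                )
                for i, p in enumerate(pars)
                if len(pars) > 1
            }
            warnings.warn(
                f"collinear parents of {child!r} (condition number {cond:.3g}); "
                f"VIF: {vifs}",
                stacklevel=2,
            )
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ y)
        resid = y - X @ beta
        dof = n - len(pars) - 1
        sigma2 = resid @ resid / max(dof, 1)
        se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
        r2[child] = float(1 - resid @ resid / (y @ y))
        for i, p in enumerate(pars):
            t = beta[i] / se[i] if se[i] > 0 else np.inf
            coeffs[(p, child)] = float(beta[i])
            pvals[(p, child)] = float(2 * stats.t.sf(abs(t), dof))
            n_eff = _ess(X[:, i], y)
            dof_eff = max(n_eff - len(pars) - 1, 2)
            se_eff = se[i] * np.sqrt(dof / dof_eff)
            t_eff = beta[i] / se_eff if se_eff > 0 else np.inf
            pvals_ess[(p, child)] = float(2 * stats.t.sf(abs(t_eff), dof_eff))

    endo = set(parents)
    exo = [nd for nd in nodes if nd not in endo]
    covs = {}
    for i, a in enumerate(exo):
        for b in exo[i + 1 :]:
            covs[(a, b)] = float(np.corrcoef(Z[a], Z[b])[0, 1])
    return PathModel(nodes, edges, coeffs, pvals, pvals_ess, covs, r2)


def _r2_of(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tot = np.sum((y - y.mean()) ** 2)
    return float(1 - resid @ resid / tot) if tot > 0 else 0.0


def spearman_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations (unit diagonal; NaN for constants)."""
    if len(data) < 3:
        raise ValueError("need at least 3 rows")
    cols = list(data.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            x, y = data[a].to_numpy(float), data[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r = np.nan
            else:
                r = stats.spearmanr(x, y).statistic
            out.loc[a, b] = out.loc[b, a] = r
    return out


# ---------------------------------------------------------------------------
# modern calibration
# ---------------------------------------------------------------------------


def wa_optima(
    modern_pollen: pd.DataFrame,
    climate: pd.Series | np.ndarray,
    min_occurrences: int = 5,
) -> pd.DataFrame:
    """Weighted-averaging climate optimum and tolerance per taxon.

    optimum u_k = Σ y_ik x_i / Σ y_ik and tolerance
    t_k = sqrt(Σ y_ik (x_i − u_k)² / Σ y_ik), with y the site × taxon
    abundances and x the site climate. Taxa present at fewer than
    ``min_occurrences`` sites get NaN (their optimum is unreliable);
    taxa absent everywhere likewise.
    """
    Y = modern_pollen.to_numpy(dtype=float)
    x = np.asarray(climate, dtype=float)
    if len(x) != len(Y):
        raise ValueError("climate vector length must match number of sites")
    rows = []
    for j, taxon in enumerate(modern_pollen.columns):
        y = Y[:, j]
        present = y > 0
        n_occ = int(present.sum())
        if n_occ == 0 or n_occ < min_occurrences:
            rows.append((taxon, np.nan, np.nan, n_occ))
            continue
        w = y.sum()
        u = float(np.sum(y * x) / w)
        t = float(np.sqrt(np.sum(y * (x - u) ** 2) / w))
        rows.append((taxon, u, t, n_occ))
    return pd.DataFrame(
        rows, columns=["taxon", "optimum", "tolerance", "n_occurrences"]
    ).set_index("taxon")


@dataclass
class ClimatePDF:
    grid: np.ndarray
    density: np.ndarray
    mode: float
    modes: list[float]
    interval_50: tuple[float, float]
    interval_90: tuple[float, float]
    bandwidth: float


def climate_pdf(values, grid_size: int = 512) -> ClimatePDF:
    """Gaussian KDE (Silverman bandwidth) of climate at presence locations.

    Reports the global mode, all local modes, and the central 50 % / 90 %
    intervals (equal-tail quantiles) describing the favourable climate
    envelope of a vegetation type.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 30:
        raise ValueError("need at least 30 values for a reliable density")
    kde = stats.gaussian_kde(v, bw_method="silverman")
    bw = float(kde.factor * v.std(ddof=1))
    lo, hi = v.min() - 3 * bw, v.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    peaks = [
        i
        for i in range(1, grid_size - 1)
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
    ]
    modes = [float(grid[i]) for i in peaks]
    mode = float(grid[int(np.argmax(dens))])
    q = np.quantile(v, [0.25, 0.75, 0.05, 0.95])
    return ClimatePDF(
        grid,
        dens,
        mode,
        modes,
        (float(q[0]), float(q[1])),
        (float(q[2]), float(q[3])),
        bw,
    )
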