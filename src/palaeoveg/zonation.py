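"""Regime-shift detection: CONISS zonation, multivariate regression-tree
change points, and linear ordination (PCA) of pollen percentages.

CONISS is stratigraphically constrained agglomerative clustering: only
adjacent clusters may merge, and each merge is the one that minimally
increases the total within-cluster sum of squares. Dispersion is squared
Euclidean distance on square-root-transformed percentages by default (a
chord-like metric that stabilizes multinomial variance). The number of
zones can be chosen by comparing merge increments against a broken-stick
null model.

The multivariate regression tree (MRT) splits the record recursively on age
thresholds minimizing the multivariate within-node sum of squares, pruned by
cross-validated relative error with the 1-SE rule — an independent
change-point detector that should agree with CONISS on clean data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConissResult",
    "MRTResult",
    "PCAResult",
    "coniss",
    "broken_stick_zones",
    "mrt_changepoints",
    "pca_pollen",
]


def _as_matrix(pct) -> tuple[np.ndarray, list[str]]:
    if isinstance(pct, pd.DataFrame):
        return pct.to_numpy(dtype=float), [str(c) for c in pct.columns]
    arr = np.asarray(pct, dtype=float)
    return arr, [f"t{i}" for i in range(arr.shape[1])]


def _apply_transform(X: np.ndarray, transform: str) -> np.ndarray:
    if transform == "sqrt":
        if np.any(X < 0):
            raise ValueError("sqrt transform needs non-negative data")
        return np.sqrt(X)
    if transform in (None, "none"):
        return X
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# CONISS
# ---------------------------------------------------------------------------


@dataclass
class ConissResult:
    increments: np.ndarray  # within-SS increase per merge, in merge order
    merge_order: list[tuple[int, int]]  # sample index ranges merged at each step
    total_dispersion: float
    n_zones: int
    zones: np.ndarray  # zone label (0-based, old-to-first-row order) per sample
    boundaries: list[float]  # boundary positions (ages if given, else indices)
    bstick: pd.DataFrame  # observed vs broken-stick increments per split


def coniss(
    pct,
    transform: str = "sqrt",
    n_zones: int | None = None,
    ages=None,
) -> ConissResult:
    """Stratigraphically constrained incremental sum-of-squares clustering.

    ``pct`` is a time-ordered sample × taxon matrix. ``n_zones=None`` selects
    the zone count by broken-stick comparison. ``ages`` (same order as rows)
    places zone boundaries at midpoints between adjacent samples of
    different zones; without ages, boundaries are row midpoints.
    """
    X, _ = _as_matrix(pct)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if n_zones is not None and n_zones > n:
        raise ValueError(f"n_zones={n_zones} exceeds {n} samples")
    X = _apply_transform(X, transform)

    # clusters kept as contiguous blocks: per-cluster n, sum vector, sum of squares
    sizes = [1] * n
    sums = [X[i].copy() for i in range(n)]
    starts = list(range(n))  # first sample index of each cluster

    def merge_cost(i: int) -> float:
        na, nb = sizes[i], sizes[i + 1]
        d = sums[i] / na - sums[i + 1] / nb
        return na * nb / (na + nb) * float(d @ d)

    costs = [merge_cost(i) for i in range(n - 1)]
    increments = []
    merge_order = []
    boundary_sets: list[list[int]] = []  # internal boundaries remaining after each merge

    while len(sizes) > 1:
        j = int(np.argmin(costs))
        increments.append(costs[j])
        merge_order.append((starts[j], starts[j + 1]))
        sizes[j] += sizes[j + 1]
        sums[j] = sums[j] + sums[j + 1]
        del sizes[j + 1], sums[j + 1], starts[j + 1]
        del costs[j]
        if j > 0:
            costs[j - 1] = merge_cost(j - 1)
        if j < len(costs):
            costs[j] = merge_cost(j)
        boundary_sets.append(list_boundaries(starts))
    increments = np.asarray(increments)
    total = float(increments.sum())

    bstick = _bstick_table(increments, total)
    if n_zones is None:
        n_zones = broken_stick_zones(increments)

    internal = boundary_sets[n - 1 - n_zones] if n_zones < n else list(range(1, n))
    zones = np.zeros(n, dtype=int)
    for b in internal:
        zones[b:] += 1
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        bounds = [float(0.5 * (ages[b - 1] + ages[b])) for b in internal]
    else:
        bounds = [b - 0.5 for b in internal]
    return ConissResult(
        increments, merge_order, total, int(n_zones), zones, bounds, bstick
    )


def list_boundaries(starts: list[int]) -> list[int]:
    return [s for s in starts if s > 0]


def _bstick_table(increments: np.ndarray, total: float) -> pd.DataFrame:
    """Observed vs broken-stick merge increments, largest split first."""
    m = len(increments)  # = n - 1 pieces
    obs = increments[::-1]  # last merge first: the 1→2 group split
    bs = np.array(
        [total / m * np.sum(1.0 / np.arange(j, m + 1)) for j in range(1, m + 1)]
    )
    return pd.DataFrame(
        {"n_groups": np.arange(2, m + 2), "observed": obs, "broken_stick": bs}
    )


def broken_stick_zones(increments: np.ndarray) -> int:
    """Zone count: splits whose increment exceeds the broken-stick share.

    Counting from the final (largest-scale) merge down, the number of zones
    is 1 + the number of leading splits whose observed dispersion increment
    exceeds its broken-stick expectation.
    """
    total = float(np.sum(increments))
    if total == 0:
        return 1
    tab = _bstick_table(np.asarray(increments), total)
    k = 0
    for obs, bs in zip(tab["observed"], tab["broken_stick"]):
        if obs > bs:
            k += 1
        else:
            break
    return k + 1


# ---------------------------------------------------------------------------
# multivariate regression tree on age
# ---------------------------------------------------------------------------


@dataclass
class MRTResult:
    split_ages: list[float]  # pruned tree's split thresholds (sorted)
    n_splits: int
    cv_table: pd.DataFrame  # relative error per candidate tree size
    greedy_splits: list[float]  # full greedy sequence before pruning


def _node_sse(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """SSE of rows [i, j) from prefix sums of X and X²."""
    n = j - i
    if n <= 0:
        return 0.0
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return float(np.sum(s2 - s * s / n))


def _best_split(prefix, prefix2, i, j, min_leaf):
    best = (np.inf, None)
    base = _node_sse(prefix, prefix2, i, j)
    for cut in range(i + min_leaf, j - min_leaf + 1):
        sse = _node_sse(prefix, prefix2, i, cut) + _node_sse(prefix, prefix2, cut, j)
        if sse < best[0]:
            best = (sse, cut)
    if best[1] is None:
        return None
    return base - best[0], best[1]  # SSE reduction, cut position


def _greedy_cuts(X: np.ndarray, max_splits: int, min_leaf: int) -> list[int]:
    n = len(X)
    prefix = np.vstack([np.zeros(X.shape[1]), np.cumsum(X, axis=0)])
    prefix2 = np.vstack([np.zeros(X.shape[1]), np.cumsum(X**2, axis=0)])
    segments = [(0, n)]
    cuts: list[int] = []
    for _ in range(max_splits):
        best = (0.0, None, None)
        for seg in segments:
            r = _best_split(prefix, prefix2, seg[0], seg[1], min_leaf)
            if r is not None and r[0] > best[0]:
                best = (r[0], r[1], seg)
        if best[1] is None or best[0] <= 1e-12:
            break
        _, cut, seg = best
        segments.remove(seg)
        segments.extend([(seg[0], cut), (cut, seg[1])])
        cuts.append(cut)
    return cuts


def mrt_changepoints(
    pct,
    age,
    max_splits: int = 5,
    cv_folds: int = 10,
    min_leaf: int = 3,
    transform: str = "sqrt",
    seed: int = 0,
) -> MRTResult:
    """Ordered multivariate regression tree on age, pruned by CV + 1-SE.

    Rows must be ordered by age. Splits are age thresholds (midpoints of the
    bracketing samples); tree size is chosen as the smallest number of
    splits whose cross-validated relative error is within one standard
    error of the minimum.
    """
    if max_splits < 1:
        raise ValueError("max_splits must be >= 1")
    X, _ = _as_matrix(pct)
    X = _apply_transform(X, transform)
    age = np.asarray(age, dtype=float)
    if len(age) != len(X):
        raise ValueError("age and data length mismatch")
    order = np.argsort(age)
    X, age = X[order], age[order]
    n = len(X)

    cuts = _greedy_cuts(X, max_splits, min_leaf)
    greedy_ages = [float(0.5 * (age[c - 1] + age[c])) for c in cuts]

    # cross-validated relative error per tree size (0..len(cuts) splits)
    rng = np.random.default_rng(seed)
    folds = rng.integers(0, cv_folds, n)
    tss = float(np.sum((X - X.mean(axis=0)) ** 2))
    sizes = range(0, len(cuts) + 1)
    cv_err = {m: [] for m in sizes}
    for f in range(cv_folds):
        train, test = folds != f, folds == f
        if test.sum() == 0 or train.sum() <= 2 * min_leaf:
            continue
        Xtr, atr = X[train], age[train]
        tr_cuts = _greedy_cuts(Xtr, max_splits, min_leaf)
        thresholds = [0.5 * (atr[c - 1] + atr[c]) for c in tr_cuts]
        for m in sizes:
            th = sorted(thresholds[:m])
            bins_tr = np.searchsorted(th, atr)
            bins_te = np.searchsorted(th, age[test])
            sse = 0.0
            for b in np.unique(bins_te):
                members = Xtr[bins_tr == b]
                mean = members.mean(axis=0) if len(members) else Xtr.mean(axis=0)
                sse += float(np.sum((X[test][bins_te == b] - mean) ** 2))
            cv_err[m].append(sse)
    rows = []
    for m in sizes:
        errs = np.array(cv_err[m], dtype=float)
        per_fold = errs / (tss / max(len(errs), 1))
        rel = errs.sum() / tss if tss > 0 else 0.0
        se = per_fold.std(ddof=1) / np.sqrt(len(per_fold)) if len(per_fold) > 1 else 0.0
        rows.append((m, rel, se))
    cv_table = pd.DataFrame(rows, columns=["n_splits", "cv_rel_error", "se"])
    best_idx = int(cv_table["cv_rel_error"].idxmin())
    threshold = cv_table.loc[best_idx, "cv_rel_error"] + cv_table.loc[best_idx, "se"]
    chosen = int(
        cv_table.loc[cv_table["cv_rel_error"] <= threshold, "n_splits"].min()
    )
    return MRTResult(
        split_ages=sorted(greedy_ages[:chosen]),
        n_splits=chosen,
        cv_table=cv_table,
        greedy_splits=greedy_ages,
    )


# ---------------------------------------------------------------------------
# PCA ordination
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame  # sample × axis
    loadings: pd.DataFrame  # taxon × axis
    eigenvalues: np.ndarray
    explained: np.ndarray  # fraction of variance per axis
    retained_taxa: list[str]


def pca_pollen(pct, min_pct: float = 2.0, transform: str = "sqrt") -> PCAResult:
    """Centred PCA of square-root-transformed pollen percentages.

    Only taxa exceeding ``min_pct`` % in at least one sample are retained
    (rare taxa contribute mostly noise to a linear ordination). Columns are
    centred but not variance-scaled. Axis signs follow a fixed convention:
    the taxon with the largest |loading| on each axis loads positively.
    """
    X, names = _as_matrix(pct)
    keep = np.nanmax(X, axis=0) > min_pct
    if keep.sum() < 2:
        raise ValueError(f"fewer than 2 taxa exceed {min_pct}% in any sample")
    Xk = _apply_transform(X[:, keep], transform)
    kept_names = [nm for nm, k in zip(names, keep) if k]
    C = Xk - Xk.mean(axis=0)
    U, sv, Vt = np.linalg.svd(C, full_matrices=False)
    n = len(C)
    eig = sv**2 / (n - 1)
    # sign convention
    for a in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    scores = U * sv
    axes = [f"PC{i+1}" for i in range(len(sv))]
    idx = pct.index if isinstance(pct, pd.DataFrame) else pd.RangeIndex(n)
    return PCAResult(
        scores=pd.DataFrame(scores, index=idx, columns=axes),
        loadings=pd.DataFrame(Vt.T, index=kept_names, columns=axes),
        eigenvalues=eig,
        explained=eig / eig.sum(),
        retained_taxa=kept_names,
    )
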