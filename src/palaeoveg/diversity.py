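"""Rarefaction richness and Pielou evenness.

Rarefied richness follows Hurlbert: the expected number of taxa in a random
subsample of ``n`` grains drawn without replacement from a count vector,

    E(S_n) = sum_i [ 1 - C(N - N_i, n) / C(N, n) ],

evaluated with log-gamma arithmetic because C(N, 300) overflows naive
binomials. Extrapolation (n > N) is refused.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from palaeoveg.core import PollenCore

__all__ = ["rarefied_richness", "pielou_evenness", "group_diversity"]

log = logging.getLogger(__name__)


def _as_counts(counts) -> np.ndarray:
    if isinstance(counts, Mapping):
        counts = list(counts.values())
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    return arr[arr > 0].astype(int)


def _log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(counts, n: int = 300) -> float:
    """Hurlbert expected taxon richness E(S_n) at subsample size ``n``.

    ``counts`` is a per-taxon grain-count vector (or mapping); zeros are
    ignored. Requires ``n <= sum(counts)``; rarefaction does not extrapolate.
    """
    c = _as_counts(counts)
    if c.size == 0:
        raise ValueError("sample has no grains")
    N = int(c.sum())
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > N:
        raise ValueError(f"cannot rarefy {N} grains to n={n} (no extrapolation)")
    # P(taxon i absent from the subsample) = C(N - N_i, n) / C(N, n)
    log_denom = _log_choose(N, n)
    p_absent = np.zeros(len(c))
    ok = (N - c) >= n
    p_absent[ok] = np.exp(_log_choose(N - c[ok], n) - log_denom)
    return float(np.sum(1.0 - p_absent))


def pielou_evenness(counts) -> float:
    """Pielou's J = H'/ln(S) over positive-count taxa; NaN when S = 1."""
    c = _as_counts(counts)
    S = len(c)
    if S < 2:
        warnings.warn("Pielou evenness undefined for a single taxon", stacklevel=2)
        return float("nan")
    p = c / c.sum()
    H = -np.sum(p * np.log(p))
    return float(H / np.log(S))


def group_diversity(
    core: PollenCore,
    groups: Mapping[str, Sequence[str]] | None = None,
    n: Mapping[str, int] | int | None = None,
) -> pd.DataFrame:
    """Per-group rarefied richness series along the core.

    ``groups`` maps a label to the growth-form groups pooled under it
    (default ``{"tree": ("tree",), "shrub_herb": ("shrub", "herb")}``,
    the tree vs shrub/herb split used to control for vegetation openness).
    ``n`` sets the per-group standardization constant; by default each group
    uses the minimum group total across samples, capped at 300. Samples whose
    group total falls below the constant get a missing value.
    """
    if groups is None:
        groups = {"tree": ("tree",), "shrub_herb": ("shrub", "herb")}
    counts = core.counts_frame()
    by_group: dict[str, list[str]] = {}
    for label, forms in groups.items():
        by_group[label] = [t.name for t in core.taxa if t.group in set(forms)]
    out = {}
    for label, cols in by_group.items():
        if not cols:
            out[label] = np.full(len(core), np.nan)
            continue
        sub = counts[cols].to_numpy()
        totals = sub.sum(axis=1)
        if isinstance(n, Mapping):
            n_g = n.get(label)
        else:
            n_g = n
        if n_g is None:
            positive = totals[totals > 0]
            n_g = int(min(300, positive.min())) if positive.size else 0
        vals = np.full(len(core), np.nan)
        for i in range(len(core)):
            if n_g >= 1 and totals[i] >= n_g:
                vals[i] = rarefied_richness(sub[i], n_g)
            else:
                log.info(
                    "sample %d: %s total %d < n=%s, richness missing",
                    i, label, totals[i], n_g,
                )
        out[label] = vals
    ages = core.ages
    idx = ages if not np.any(np.isnan(ages)) else core.depths
    return pd.DataFrame(out, index=idx)
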