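"""Core data model, I/O and pollen-count arithmetic.

The central object is :class:`PollenCore`: an ordered stratigraphic table of
samples, each holding raw grain counts per taxon, the exotic-marker
(*Lycopodium*) spike bookkeeping needed for concentration estimates, and —
once an :class:`AgeModel` has been applied — a calendar age in ka BP.

Conventions used throughout the package:

* depth is metres below the core top, increasing downward;
* age is ka BP (thousands of years before present), increasing into the past,
  and therefore increasing with depth;
* pollen percentages use the **terrestrial** pollen sum as denominator:
  aquatic and spore taxa are carried along but excluded from the sum, and
  their percentages are expressed relative to the same terrestrial sum
  (standard palynological practice);
* depth→age mapping is piecewise linear between tie points; a depositional
  hiatus is encoded as two tie points at the same depth with different ages.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaxonInfo",
    "SampleRecord",
    "PollenCore",
    "AgeModel",
    "Series",
    "read_counts",
    "write_counts",
    "read_series",
    "write_series",
    "percentages",
    "concentration",
    "influx",
    "apply_age_model",
    "resample_uniform",
]

#: grains per standard Lycopodium tablet (Lund batch 1031)
LYCOPODIUM_TABLET_GRAINS = 20_848

_GROUPS = ("tree", "shrub", "herb", "aquatic", "spore", "other")
#: groups contributing to the terrestrial pollen sum
TERRESTRIAL_GROUPS = ("tree", "shrub", "herb", "other")


@dataclass(frozen=True)
class TaxonInfo:
    """A pollen taxon and its growth-form group.

    ``include_in_sum`` marks membership of the terrestrial pollen sum;
    aquatics and spores are always excluded.
    """

    name: str
    group: str = "other"
    include_in_sum: bool | None = None

    def __post_init__(self):
        if self.group not in _GROUPS:
            raise ValueError(f"unknown group {self.group!r} for taxon {self.name!r}")
        include = self.include_in_sum
        if include is None:
            include = self.group in TERRESTRIAL_GROUPS
        if self.group in ("aquatic", "spore") and include:
            raise ValueError(
                f"taxon {self.name!r}: aquatic/spore taxa cannot be in the terrestrial sum"
            )
        object.__setattr__(self, "include_in_sum", include)


@dataclass
class SampleRecord:
    """One stratigraphic sample: raw counts plus spike/volume bookkeeping.

    Parameters
    ----------
    depth:
        Metres below core top.
    counts:
        Mapping taxon name → integer grain count.
    spike_counted:
        Exotic marker (*Lycopodium*) grains tallied alongside the pollen.
    spike_added:
        Marker grains added during processing (tablets × grains/tablet).
    volume:
        Sediment volume processed, cm³.
    age:
        ka BP; ``None`` until an age model is applied.
    """

    depth: float
    counts: dict[str, int]
    spike_counted: int = 0
    spike_added: int = LYCOPODIUM_TABLET_GRAINS
    volume: float = 2.0
    age: float | None = None
    sample_id: str | None = None

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError(f"sample at {self.depth} m: volume must be > 0")
        if self.spike_added <= 0:
            raise ValueError(f"sample at {self.depth} m: spike_added must be > 0")
        clean: dict[str, int] = {}
        for taxon, c in self.counts.items():
            ci = int(c)
            if ci != c:
                raise ValueError(
                    f"sample at {self.depth} m: non-integer count {c!r} for {taxon!r}"
                )
            if ci < 0:
                raise ValueError(
                    f"sample at {self.depth} m: negative count for {taxon!r}"
                )
            clean[str(taxon)] = ci
        self.counts = clean

    def terrestrial_sum(self, taxa: Sequence[TaxonInfo]) -> int:
        keep = {t.name for t in taxa if t.include_in_sum}
        return sum(c for k, c in self.counts.items() if k in keep)


@dataclass
class PollenCore:
    """An ordered collection of samples with taxon metadata.

    Invariants enforced on construction: depths strictly increase downcore,
    ages (where assigned) strictly increase with depth, every sample has at
    least one terrestrial grain and all counts are non-negative integers.
    """

    samples: list[SampleRecord]
    taxa: list[TaxonInfo] = field(default_factory=list)

    def __post_init__(self):
        if not self.samples:
            raise ValueError("PollenCore needs at least one sample")
        known = {t.name for t in self.taxa}
        extra = sorted(
            {k for s in self.samples for k in s.counts} - known
        )
        self.taxa = list(self.taxa) + [TaxonInfo(name, "other") for name in extra]
        depths = [s.depth for s in self.samples]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("sample depths must be strictly increasing downcore")
        ages = [s.age for s in self.samples if s.age is not None]
        if len(ages) > 1 and any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("sample ages must strictly increase with depth")
        for s in self.samples:
            if s.terrestrial_sum(self.taxa) < 1:
                raise ValueError(
                    f"sample at {s.depth} m has no terrestrial pollen grains"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def depths(self) -> np.ndarray:
        return np.array([s.depth for s in self.samples])

    @property
    def ages(self) -> np.ndarray:
        return np.array(
            [np.nan if s.age is None else s.age for s in self.samples]
        )

    @property
    def taxon_names(self) -> list[str]:
        return [t.name for t in self.taxa]

    def taxon(self, name: str) -> TaxonInfo:
        for t in self.taxa:
            if t.name == name:
                return t
        raise KeyError(name)

    def counts_frame(self) -> pd.DataFrame:
        """Sample × taxon count matrix (rows ordered downcore)."""
        idx = [s.sample_id or f"d{s.depth:g}" for s in self.samples]
        mat = pd.DataFrame(
            [[s.counts.get(t, 0) for t in self.taxon_names] for s in self.samples],
            index=idx,
            columns=self.taxon_names,
            dtype=int,
        )
        return mat

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class Series:
    """A generic age–value series (AP%, δ¹⁸O, GMST, CO₂, insolation ...)."""

    age: np.ndarray
    value: np.ndarray
    label: str = ""

    def __post_init__(self):
        age = np.asarray(self.age, dtype=float)
        value = np.asarray(self.value, dtype=float)
        if age.shape != value.shape or age.ndim != 1:
            raise ValueError("age and value must be 1-D vectors of equal length")
        d = np.diff(age)
        if len(age) > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError(f"series {self.label!r}: age must be strictly monotone")
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "value", value)

    def __len__(self) -> int:
        return len(self.age)

    def ascending(self) -> "Series":
        """Return the series with age increasing."""
        if len(self.age) > 1 and self.age[1] < self.age[0]:
            return Series(self.age[::-1].copy(), self.value[::-1].copy(), self.label)
        return self


class AgeModel:
    """Piecewise-linear depth→age model from tie points.

    Tie points are ``(depth_m, age_ka)`` pairs sorted by depth with ages
    strictly non-decreasing. Two tie points sharing a depth encode a hiatus:
    the age jumps discontinuously and the younger age is assigned to a sample
    lying exactly at the hiatus depth.
    """

    def __init__(self, tie_points: Iterable[tuple[float, float]]):
        pts = sorted((float(d), float(a)) for d, a in tie_points)
        if len(pts) < 2:
            raise ValueError("age model needs at least two tie points")
        depths = [p[0] for p in pts]
        ages = [p[1] for p in pts]
        for (d0, a0), (d1, a1) in zip(pts, pts[1:]):
            if d1 == d0:
                if a1 <= a0:
                    raise ValueError("hiatus tie points must have increasing ages")
            elif a1 <= a0:
                raise ValueError("tie-point ages must strictly increase with depth")
        # at most two ties may share a depth (one hiatus per depth)
        for d in set(depths):
            if depths.count(d) > 2:
                raise ValueError(f"more than two tie points at depth {d}")
        self.tie_points = pts
        self._depths = np.array(depths)
        self._ages = np.array(ages)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AgeModel":
        """Load tie points from YAML: ``tie_points: [[depth_m, age_ka], ...]``."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(doc["tie_points"])

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"tie_points": [[d, a] for d, a in self.tie_points]}, fh
            )

    @property
    def hiatuses(self) -> list[tuple[float, float, float]]:
        """(depth, age_young, age_old) for every hiatus in the model."""
        out = []
        for (d0, a0), (d1, a1) in zip(self.tie_points, self.tie_points[1:]):
            if d1 == d0:
                out.append((d0, a0, a1))
        return out

    def age_at(self, depth) -> np.ndarray | float:
        """Interpolate age (ka) at one or many depths; exact at tie points."""
        scalar = np.isscalar(depth)
        out = []
        for z in np.atleast_1d(np.asarray(depth, dtype=float)):
            d = self._depths
            if z < d[0] or z > d[-1]:
                raise ValueError(
                    f"depth {z} m outside age model range [{d[0]}, {d[-1]}] m"
                )
            i = int(np.searchsorted(d, z, side="left"))
            if i == len(d):
                i -= 1
            if d[i] == z:
                out.append(self._ages[i])  # younger age at a hiatus depth
                continue
            i -= 1
            if d[i + 1] == d[i]:  # should not happen: z strictly inside hiatus
                raise ValueError(f"depth {z} m falls inside a hiatus")
            frac = (z - d[i]) / (d[i + 1] - d[i])
            out.append(self._ages[i] + frac * (self._ages[i + 1] - self._ages[i]))
        arr = np.array(out)
        return float(arr[0]) if scalar else arr

    def sed_rate_at(self, depth: float) -> float:
        """Sedimentation rate (cm yr⁻¹) of the segment containing ``depth``.

        Within a hiatus (zero-thickness segment) the rate is 0 — influx is
        then undefined, not zero.
        """
        d, a = self._depths, self._ages
        if depth < d[0] or depth > d[-1]:
            raise ValueError(
                f"depth {depth} m outside age model range [{d[0]}, {d[-1]}] m"
            )
        i = int(np.searchsorted(d, depth, side="right")) - 1
        i = max(0, min(i, len(d) - 2))
        if d[i + 1] == d[i]:
            return 0.0
        dz_cm = (d[i + 1] - d[i]) * 100.0
        dt_yr = (a[i + 1] - a[i]) * 1000.0
        return dz_cm / dt_yr


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_LONG_COLS = {"sample_id", "depth_m", "taxon", "count"}
_META_COLS = ("spike_counted", "spike_added", "volume_cm3", "group")


def read_counts(
    path: str | Path,
    dialect: str = "csv",
    groups: Mapping[str, str] | None = None,
) -> PollenCore:
    """Read a pollen count table.

    ``dialect='csv'`` auto-detects the two tidy layouts:

    * **long** — columns ``sample_id, depth_m, taxon, count`` plus optional
      ``group, spike_counted, spike_added, volume_cm3``;
    * **wide** — one row per sample, a ``depth_m`` column and one integer
      column per taxon.

    ``dialect='tilia_export'`` reads a transposed matrix (taxa as rows, the
    first column named ``taxon``, optional ``group`` column, remaining column
    headers being depths in metres).

    Taxa absent from ``groups`` default to group ``other`` and stay in the
    terrestrial sum.
    """
    groups = dict(groups or {})
    df = pd.read_csv(path)
    if dialect == "tilia_export":
        if "taxon" not in df.columns:
            raise ValueError("tilia_export layout needs a 'taxon' first column")
        grp_col = df["group"] if "group" in df.columns else None
        if grp_col is not None:
            groups = {**dict(zip(df["taxon"], grp_col)), **groups}
        value_cols = [c for c in df.columns if c not in ("taxon", "group")]
        wide = df.set_index("taxon")[value_cols].T
        wide.insert(0, "depth_m", [float(c) for c in value_cols])
        df = wide.reset_index(drop=True)
        return _core_from_wide(df, groups)
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    if _LONG_COLS.issubset(df.columns):
        return _core_from_long(df, groups)
    if "depth_m" in df.columns:
        return _core_from_wide(df, groups)
    raise ValueError("count file needs either long columns or a depth_m column")


def _check_int(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what}: missing or non-finite counts")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError(f"{what}: counts must be integers")
    if np.any(arr < 0):
        raise ValueError(f"{what}: counts must be non-negative")
    return arr.astype(int)


def _taxa_from_groups(names: Sequence[str], groups: Mapping[str, str]) -> list[TaxonInfo]:
    return [TaxonInfo(n, groups.get(n, "other")) for n in names]


def _core_from_long(df: pd.DataFrame, groups: Mapping[str, str]) -> PollenCore:
    if "group" in df.columns:
        groups = {**dict(zip(df["taxon"], df["group"])), **groups}
    df = df.copy()
    df["count"] = _check_int(df["count"], "long table")
    samples = []
    for (sid, depth), sub in df.groupby(["sample_id", "depth_m"], sort=False):
        if sub["taxon"].duplicated().any():
            raise ValueError(f"sample {sid!r}: duplicated taxon rows")
        meta = {}
        for col, attr in (
            ("spike_counted", "spike_counted"),
            ("spike_added", "spike_added"),
            ("volume_cm3", "volume"),
        ):
            if col in sub.columns:
                meta[attr] = sub[col].iloc[0]
        if "spike_counted" in meta:
            meta["spike_counted"] = int(meta["spike_counted"])
        if "spike_added" in meta:
            meta["spike_added"] = int(meta["spike_added"])
        samples.append(
            SampleRecord(
                depth=float(depth),
                counts=dict(zip(sub["taxon"], sub["count"])),
                sample_id=str(sid),
                **meta,
            )
        )
    depths = [s.depth for s in samples]
    if len(set(depths)) != len(depths):
        raise ValueError("duplicate sample depths in count table")
    samples.sort(key=lambda s: s.depth)
    names = list(dict.fromkeys(df["taxon"]))
    return PollenCore(samples, _taxa_from_groups(names, groups))


def _core_from_wide(df: pd.DataFrame, groups: Mapping[str, str]) -> PollenCore:
    meta_cols = [c for c in ("sample_id", *_META_COLS) if c in df.columns]
    taxa_cols = [c for c in df.columns if c != "depth_m" and c not in meta_cols]
    if df["depth_m"].duplicated().any():
        raise ValueError("duplicate sample depths in count table")
    counts = _check_int(df[taxa_cols].to_numpy(), "wide table")
    samples = []
    for i, row in df.reset_index(drop=True).iterrows():
        meta = {}
        if "spike_counted" in df.columns:
            meta["spike_counted"] = int(row["spike_counted"])
        if "spike_added" in df.columns:
            meta["spike_added"] = int(row["spike_added"])
        if "volume_cm3" in df.columns:
            meta["volume"] = float(row["volume_cm3"])
        if "sample_id" in df.columns:
            meta["sample_id"] = str(row["sample_id"])
        samples.append(
            SampleRecord(
                depth=float(row["depth_m"]),
                counts=dict(zip(taxa_cols, counts[i])),
                **meta,
            )
        )
    samples.sort(key=lambda s: s.depth)
    return PollenCore(samples, _taxa_from_groups(taxa_cols, groups))


def write_counts(core: PollenCore, path: str | Path, dialect: str = "csv") -> None:
    """Write a core as tidy long CSV (the canonical exchange format)."""
    if dialect != "csv":
        raise ValueError("only the tidy long CSV writer is provided")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "sample_id",
                "depth_m",
                "taxon",
                "count",
                "group",
                "spike_counted",
                "spike_added",
                "volume_cm3",
            ]
        )
        groups = {t.name: t.group for t in core.taxa}
        for s in core.samples:
            sid = s.sample_id or f"d{s.depth:g}"
            for taxon in core.taxon_names:
                if taxon in s.counts:
                    w.writerow(
                        [
                            sid,
                            repr(s.depth),
                            taxon,
                            s.counts[taxon],
                            groups[taxon],
                            s.spike_counted,
                            s.spike_added,
                            repr(s.volume),
                        ]
                    )


def read_series(path: str | Path, label: str | None = None) -> Series:
    """Read a two-column (age_ka, value) CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("series CSV needs two columns (age_ka, value)")
    return Series(
        df.iloc[:, 0].to_numpy(float),
        df.iloc[:, 1].to_numpy(float),
        label or str(df.columns[1]),
    )


def write_series(s: Series, path: str | Path) -> None:
    pd.DataFrame({"age_ka": s.age, s.label or "value": s.value}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# count arithmetic
# ---------------------------------------------------------------------------


def percentages(core: PollenCore) -> pd.DataFrame:
    """Per-sample pollen percentages on the terrestrial-sum basis.

    Terrestrial taxa sum to 100 within each sample; aquatic/spore taxa are
    expressed relative to the same terrestrial denominator and may push the
    row total above 100.
    """
    counts = core.counts_frame()
    keep = [t.name for t in core.taxa if t.include_in_sum]
    denom = counts[keep].sum(axis=1).to_numpy(dtype=float)
    for s, d in zip(core.samples, denom):
        if d <= 0:
            raise ValueError(
                f"sample {s.sample_id or s.depth} has zero terrestrial pollen sum"
            )
    return counts.astype(float).div(denom, axis=0) * 100.0


def concentration(sample: SampleRecord) -> pd.Series:
    """Pollen concentration (grains cm⁻³) per taxon.

    conc = (count / spike_counted) × spike_added / volume. The returned
    Series carries one entry per counted taxon; ``.sum()`` is the total.
    """
    if sample.spike_counted <= 0:
        raise ValueError(
            f"sample at {sample.depth} m: spike_counted is 0, cannot estimate "
            "concentration"
        )
    factor = sample.spike_added / (sample.spike_counted * sample.volume)
    return pd.Series(
        {k: c * factor for k, c in sample.counts.items()}, dtype=float
    )


def influx(conc: float | pd.Series, sed_rate: float) -> float | pd.Series:
    """Pollen influx (grains cm⁻² yr⁻¹) = concentration × sedimentation rate.

    A zero sedimentation rate (inside a hiatus) leaves influx undefined and
    yields NaN, not zero.
    """
    if sed_rate == 0:
        if np.isscalar(conc):
            return float("nan")
        return conc * np.nan
    return conc * sed_rate


def apply_age_model(core: PollenCore, model: AgeModel) -> PollenCore:
    """Return a copy of ``core`` with ages (ka BP) assigned from ``model``.

    All sample depths must lie within the tie-point range; extrapolation is
    refused.
    """
    samples = [replace(s, age=float(model.age_at(s.depth))) for s in core.samples]
    return PollenCore(samples, list(core.taxa))


def resample_uniform(s: Series, dt: float = 1.0) -> Series:
    """Linear interpolation onto a uniform age grid of step ``dt`` kyr.

    The grid spans ``min(age) … max(age)`` only — no extrapolation.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(s) < 2:
        raise ValueError("need at least two points to resample")
    srt = s.ascending()
    lo, hi = srt.age[0], srt.age[-1]
    n = int(np.floor((hi - lo) / dt + 1e-9)) + 1
    grid = lo + dt * np.arange(n)
    vals = np.interp(grid, srt.age, srt.value)
    return Series(grid, vals, s.label)
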