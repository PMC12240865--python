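"""Biomization: taxon → PFT → biome affinity scoring and megabiome merging.

The classic biomization procedure assigns each pollen assemblage to the biome
with the highest *affinity score*. A taxon contributes to a biome whenever it
is assigned (via any plant functional type, PFT) to that biome, and its
contribution is ``sqrt(max(0, p - θ))`` where ``p`` is its percentage of the
terrestrial sum and ``θ`` a small threshold (default 0.5 %) suppressing
trace occurrences. A taxon is counted once per biome even if several of that
biome's PFTs contain it. Ties on the top score go to the biome defined by
fewer PFTs; residual ties are broken alphabetically for determinism.

Biomes are then merged into five megabiomes — forest, meadow, steppe,
shrubland and desert-steppe — and samples whose winning biome is desert are
relabelled desert-steppe (desert spectra in the alpine meadow–forest ecotone
are meadow-like, with high Cyperaceae/Poaceae, rather than true desert).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from palaeoveg.core import PollenCore, concentration, influx, percentages

__all__ = [
    "MEGABIOMES",
    "BiomeScheme",
    "BiomeAssignment",
    "BiomeSequence",
    "default_scheme",
    "affinity_scores",
    "assign_biome",
    "to_megabiome",
    "biomize_core",
    "interval_proportions",
    "influx_screen",
]

log = logging.getLogger(__name__)

MEGABIOMES = ("forest", "meadow", "steppe", "shrubland", "desert-steppe")

#: label used when every biome scores zero
UNCLASSIFIED = "unclassified"


@dataclass
class BiomeScheme:
    """Taxon→PFT and PFT→biome assignment matrices plus the megabiome map.

    Parameters
    ----------
    pft_of_taxon:
        taxon name → set of PFT identifiers.
    pfts_of_biome:
        biome name → set of PFT identifiers defining it.
    megabiome_of_biome:
        biome name → one of :data:`MEGABIOMES`.
    threshold:
        percentage threshold θ below which a taxon contributes nothing.
    desert_biomes:
        biomes whose winning samples are relabelled ``desert-steppe``.
    """

    pft_of_taxon: dict[str, set[str]]
    pfts_of_biome: dict[str, set[str]]
    megabiome_of_biome: dict[str, str]
    threshold: float = 0.5
    desert_biomes: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.pft_of_taxon = {k: set(v) for k, v in self.pft_of_taxon.items()}
        self.pfts_of_biome = {k: set(v) for k, v in self.pfts_of_biome.items()}
        taxon_pfts = set().union(*self.pft_of_taxon.values()) if self.pft_of_taxon else set()
        for biome, pfts in self.pfts_of_biome.items():
            if not pfts:
                raise ValueError(f"biome {biome!r} has no PFTs")
            orphan = pfts - taxon_pfts
            if orphan:
                raise ValueError(
                    f"biome {biome!r} references PFTs with no taxon: {sorted(orphan)}"
                )
        missing = set(self.pfts_of_biome) - set(self.megabiome_of_biome)
        if missing:
            raise ValueError(f"no megabiome for biomes {sorted(missing)}")
        bad = set(self.megabiome_of_biome.values()) - set(MEGABIOMES)
        if bad:
            raise ValueError(f"unknown megabiomes {sorted(bad)}")
        # taxa eligible for each biome, precomputed once
        self._taxa_of_biome: dict[str, frozenset[str]] = {
            b: frozenset(
                t for t, pfts in self.pft_of_taxon.items() if pfts & bpfts
            )
            for b, bpfts in self.pfts_of_biome.items()
        }

    @property
    def biomes(self) -> list[str]:
        return sorted(self.pfts_of_biome)

    def taxa_of_biome(self, biome: str) -> frozenset[str]:
        return self._taxa_of_biome[biome]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BiomeScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            pft_of_taxon={t: set(v) for t, v in doc["taxa"].items()},
            pfts_of_biome={b: set(spec["pfts"]) for b, spec in doc["biomes"].items()},
            megabiome_of_biome=dict(doc["megabiomes"]),
            threshold=float(doc.get("threshold", 0.5)),
            desert_biomes=set(doc.get("desert_biomes", [])),
        )


def default_scheme() -> BiomeScheme:
    """The packaged eastern-Tibetan-Plateau scheme.

    A reconstruction adapted from the Chinese biomization literature for the
    alpine forest–meadow–steppe ecotone; it is *not* any study's verbatim
    assignment table.
    """
    ref = resources.files("palaeoveg") / "schemes" / "zoige_default.yaml"
    with resources.as_file(ref) as p:
        return BiomeScheme.from_yaml(p)


@dataclass
class BiomeAssignment:
    """Scores and winning biome for one sample."""

    scores: dict[str, float]
    biome: str
    megabiome: str
    runner_up_ratio: float


@dataclass
class BiomeSequence:
    """Time-ordered (old→young) megabiome labels with sample ages."""

    age: np.ndarray  # ka BP, strictly decreasing (old → young)
    megabiome: np.ndarray  # str labels, may include 'unclassified'
    biome: np.ndarray | None = None
    scores: pd.DataFrame | None = None

    def __post_init__(self):
        self.age = np.asarray(self.age, dtype=float)
        self.megabiome = np.asarray(self.megabiome, dtype=object)
        if self.age.shape != self.megabiome.shape:
            raise ValueError("age and megabiome must have equal length")
        if len(self.age) > 1 and not np.all(np.diff(self.age) < 0):
            raise ValueError("ages must strictly decrease (old → young order)")

    def __len__(self) -> int:
        return len(self.age)


# ---------------------------------------------------------------------------


def affinity_scores(pct, scheme: BiomeScheme) -> dict[str, float]:
    """Affinity score of every biome for one sample.

    ``pct`` maps taxon → percentage (terrestrial-sum basis). Taxa unknown to
    the scheme are ignored (logged once per taxon name).
    """
    theta = scheme.threshold
    contrib = {}
    for taxon, p in dict(pct).items():
        if taxon not in scheme.pft_of_taxon:
            if taxon not in _warned_taxa:
                log.info("taxon %r not in biome scheme; excluded", taxon)
                _warned_taxa.add(taxon)
            continue
        contrib[taxon] = np.sqrt(max(0.0, float(p) - theta))
    return {
        b: float(sum(contrib.get(t, 0.0) for t in scheme.taxa_of_biome(b)))
        for b in scheme.biomes
    }


_warned_taxa: set[str] = set()


def assign_biome(scores: dict[str, float], scheme: BiomeScheme) -> BiomeAssignment:
    """Pick the winning biome: highest score, ties to fewer defining PFTs,
    then alphabetical; all-zero scores yield ``unclassified``."""
    if not scores:
        raise ValueError("no biome scores")
    best = max(scores.values())
    if best <= 0:
        log.info("all-zero affinity scores; sample left unclassified")
        return BiomeAssignment(dict(scores), UNCLASSIFIED, UNCLASSIFIED, np.nan)
    tied = [b for b, s in scores.items() if s == best]
    winner = min(tied, key=lambda b: (len(scheme.pfts_of_biome[b]), b))
    others = [s for b, s in scores.items() if b != winner]
    ratio = max(others) / best if others else np.nan
    mega = to_megabiome_label(winner, scheme)
    return BiomeAssignment(dict(scores), winner, mega, ratio)


def to_megabiome_label(biome: str, scheme: BiomeScheme) -> str:
    if biome in scheme.desert_biomes:
        return "desert-steppe"
    try:
        return scheme.megabiome_of_biome[biome]
    except KeyError:
        raise ValueError(f"biome {biome!r} has no megabiome mapping") from None


def to_megabiome(assignment: BiomeAssignment, scheme: BiomeScheme) -> str:
    """Megabiome label of an assignment (desert winners → desert-steppe)."""
    if assignment.biome == UNCLASSIFIED:
        return UNCLASSIFIED
    return to_megabiome_label(assignment.biome, scheme)


def biomize_core(core: PollenCore, scheme: BiomeScheme) -> BiomeSequence:
    """Biomize every sample of an age-dated core, ordered old→young."""
    ages = core.ages
    if np.any(np.isnan(ages)):
        raise ValueError("core must have ages assigned before biomization")
    pct = percentages(core)
    rows = []
    for i in range(len(core)):
        sc = affinity_scores(pct.iloc[i].to_dict(), scheme)
        rows.append(assign_biome(sc, scheme))
    # stratigraphic order is young→old (shallow→deep); reverse to old→young
    order = np.argsort(-ages, kind="stable")
    return BiomeSequence(
        age=ages[order],
        megabiome=np.array([rows[i].megabiome for i in order], dtype=object),
        biome=np.array([rows[i].biome for i in order], dtype=object),
        scores=pd.DataFrame([rows[i].scores for i in order], index=ages[order]),
    )


def interval_proportions(
    seq: BiomeSequence, boundaries: list[float] | None = None
) -> pd.DataFrame:
    """Percentage of classified samples per megabiome within age intervals.

    ``boundaries`` (ka, any order) partition the record into len+1 intervals;
    omitted → one interval spanning the whole record. Unclassified samples
    are excluded from the denominator. Rows sum to 100; an empty interval
    yields a NaN row.
    """
    edges = sorted(boundaries or [], reverse=True)
    old, young = float(np.max(seq.age)), float(np.min(seq.age))
    for b in edges:
        if not (young <= b <= old):
            raise ValueError(f"boundary {b} ka outside record span")
    cuts = [np.inf] + edges + [-np.inf]
    labels = []
    for hi, lo in zip(cuts, cuts[1:]):
        hi_s = f"{old:g}" if np.isinf(hi) else f"{hi:g}"
        lo_s = f"{young:g}" if np.isinf(lo) else f"{lo:g}"
        labels.append(f"{hi_s}-{lo_s} ka")
    out = pd.DataFrame(
        0.0, index=labels, columns=list(MEGABIOMES) + ["n_samples"]
    )
    for (hi, lo), lab in zip(zip(cuts, cuts[1:]), labels):
        mask = (seq.age <= hi) & (seq.age > lo)
        if np.isinf(hi):
            mask = seq.age > lo
        sub = seq.megabiome[mask]
        sub = sub[sub != UNCLASSIFIED]
        out.loc[lab, "n_samples"] = len(sub)
        if len(sub) == 0:
            out.loc[lab, list(MEGABIOMES)] = np.nan
            continue
        for m in MEGABIOMES:
            out.loc[lab, m] = 100.0 * np.sum(sub == m) / len(sub)
    return out


def influx_screen(
    core: PollenCore, model=None, quantile: float = 0.05
) -> pd.Series:
    """Flag samples with anomalously low total pollen influx.

    Returns a boolean Series (True = total influx strictly below the
    ``quantile`` quantile) for sensitivity re-analysis of the biomization;
    assignments themselves are never altered. If ``model`` is None the
    screen falls back to total *concentration* (no sedimentation rates).
    """
    totals = []
    for s in core.samples:
        conc = concentration(s).sum()
        if model is not None:
            totals.append(influx(conc, model.sed_rate_at(s.depth)))
        else:
            totals.append(conc)
    totals = pd.Series(
        totals, index=[s.sample_id or f"d{s.depth:g}" for s in core.samples]
    )
    cut = totals.quantile(quantile)
    return totals < cut
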