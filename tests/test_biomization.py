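"""Affinity scoring, biome assignment, megabiome merging and proportions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palaeoveg.biomization import (
    BiomeAssignment,
    BiomeScheme,
    BiomeSequence,
    affinity_scores,
    assign_biome,
    biomize_core,
    influx_screen,
    interval_proportions,
    to_megabiome,
)
from palaeoveg.core import PollenCore, SampleRecord, TaxonInfo, percentages


@pytest.fixture()
def toy_scheme():
    return BiomeScheme(
        pft_of_taxon={
            "Picea": {"bec"},
            "Pinus": {"tec"},
            "Poaceae": {"sf", "g"},
            "Cyperaceae": {"g"},
            "Artemisia": {"sf"},
        },
        pfts_of_biome={
            "conifer forest": {"bec", "tec"},
            "boreal forest": {"bec"},
            "grassland": {"sf", "g"},
        },
        megabiome_of_biome={
            "conifer forest": "forest",
            "boreal forest": "forest",
            "grassland": "steppe",
        },
        threshold=0.5,
    )


# ---------------------------------------------------------------- scoring


def test_threshold_dead_zone(toy_scheme):
    sc = affinity_scores({"Picea": 0.4}, toy_scheme)
    assert all(v == 0.0 for v in sc.values())


def test_sqrt_above_threshold(toy_scheme):
    sc = affinity_scores({"Picea": 4.5}, toy_scheme)
    assert sc["boreal forest"] == pytest.approx(2.0)  # sqrt(4.5 - 0.5)


def test_shared_taxon_contributes_fully_to_both(toy_scheme):
    sc = affinity_scores({"Picea": 10.0}, toy_scheme)
    assert sc["conifer forest"] == sc["boreal forest"] > 0


def test_taxon_in_two_pfts_of_one_biome_counted_once(toy_scheme):
    # Poaceae maps to both sf and g, both defining grassland
    sc = affinity_scores({"Poaceae": 4.5}, toy_scheme)
    assert sc["grassland"] == pytest.approx(2.0)


def test_unknown_taxon_excluded(toy_scheme):
    a = affinity_scores({"Picea": 10.0}, toy_scheme)
    b = affinity_scores({"Picea": 10.0, "Martianella": 50.0}, toy_scheme)
    assert a == b


def test_scores_monotone_in_percentage(toy_scheme):
    lo = affinity_scores({"Picea": 2.0}, toy_scheme)
    hi = affinity_scores({"Picea": 5.0}, toy_scheme)
    assert all(hi[b] >= lo[b] for b in lo)


# ---------------------------------------------------------------- assignment


def test_argmax_assignment(toy_scheme):
    a = assign_biome({"conifer forest": 3.1, "grassland": 2.0, "boreal forest": 0.1}, toy_scheme)
    assert a.biome == "conifer forest"
    assert a.megabiome == "forest"
    assert a.runner_up_ratio == pytest.approx(2.0 / 3.1)


def test_tie_broken_by_fewer_pfts(toy_scheme):
    # conifer forest has 2 PFTs, boreal forest 1 -> boreal forest wins the tie
    a = assign_biome({"conifer forest": 2.0, "boreal forest": 2.0}, toy_scheme)
    assert a.biome == "boreal forest"


def test_residual_tie_alphabetical():
    scheme = BiomeScheme(
        pft_of_taxon={"X": {"p1"}, "Y": {"p2"}},
        pfts_of_biome={"b_zeta": {"p1"}, "b_alpha": {"p2"}},
        megabiome_of_biome={"b_zeta": "forest", "b_alpha": "steppe"},
    )
    a = assign_biome({"b_zeta": 1.5, "b_alpha": 1.5}, scheme)
    assert a.biome == "b_alpha"


def test_all_zero_scores_unclassified(toy_scheme):
    a = assign_biome({"conifer forest": 0.0, "grassland": 0.0}, toy_scheme)
    assert a.biome == "unclassified"


# ------------------------------------------------------------- megabiomes


def test_megabiome_merge_rules(scheme):
    def mega(biome):
        return to_megabiome(
            BiomeAssignment({}, biome, "", np.nan), scheme
        )

    assert mega("cool evergreen needle-leaved forest") == "forest"
    assert mega("graminoid and forb tundra") == "meadow"
    assert mega("temperate grassland") == "steppe"
    assert mega("erect dwarf-shrub tundra") == "shrubland"


def test_desert_relabelled_desert_steppe(scheme):
    a = BiomeAssignment({}, "desert", "", np.nan)
    assert to_megabiome(a, scheme) == "desert-steppe"


def test_unmapped_biome_errors(toy_scheme):
    a = BiomeAssignment({}, "lunar maria", "", np.nan)
    with pytest.raises(ValueError):
        to_megabiome(a, toy_scheme)


# ------------------------------------------------------------ whole cores


def _core(counts_list, ages, groups):
    samples = [
        SampleRecord(depth=float(i), counts=c, age=a, spike_counted=10)
        for i, (c, a) in enumerate(zip(counts_list, ages))
    ]
    return PollenCore(samples, [TaxonInfo(n, g) for n, g in groups.items()])


def test_biomize_pure_end_members(toy_scheme):
    groups = {"Picea": "tree", "Poaceae": "herb"}
    core = _core(
        [{"Picea": 290, "Poaceae": 10}, {"Picea": 10, "Poaceae": 290}],
        ages=[1.0, 5.0],
        groups=groups,
    )
    seq = biomize_core(core, toy_scheme)
    # old -> young ordering
    assert list(seq.megabiome) == ["steppe", "forest"]
    assert seq.age[0] > seq.age[-1]


def test_biomize_requires_ages(toy_scheme):
    core = _core([{"Picea": 300}], ages=[None], groups={"Picea": "tree"})
    with pytest.raises(ValueError, match="ages"):
        biomize_core(core, toy_scheme)


def test_scale_invariance(toy_scheme):
    groups = {"Picea": "tree", "Poaceae": "herb"}
    c1 = _core([{"Picea": 30, "Poaceae": 15}], [1.0], groups)
    c2 = _core([{"Picea": 300, "Poaceae": 150}], [1.0], groups)
    s1, s2 = biomize_core(c1, toy_scheme), biomize_core(c2, toy_scheme)
    assert list(s1.megabiome) == list(s2.megabiome)
    np.testing.assert_allclose(s1.scores.to_numpy(), s2.scores.to_numpy())


@settings(deadline=None, max_examples=30)
@given(p=st.floats(0.0, 0.5))
def test_dead_zone_property(scheme, p):
    base = affinity_scores({"Picea": 20.0}, scheme)
    plus = affinity_scores({"Picea": 20.0, "Artemisia": p}, scheme)
    assert base == plus


# ---------------------------------------------------------- proportions


def test_interval_proportions_simple():
    ages = np.linspace(100, 10, 10)
    labels = np.array(["forest"] * 9 + ["meadow"], dtype=object)
    seq = BiomeSequence(ages, labels)
    tab = interval_proportions(seq)
    assert tab.iloc[0]["forest"] == pytest.approx(90.0)
    assert tab.iloc[0]["meadow"] == pytest.approx(10.0)


def test_interval_proportions_rows_sum_100():
    rng = np.random.default_rng(0)
    ages = np.linspace(3400, 10, 200)
    labels = rng.choice(["forest", "meadow", "steppe"], 200).astype(object)
    seq = BiomeSequence(ages, labels)
    tab = interval_proportions(seq, boundaries=[2730, 1540, 620])
    sums = tab[["forest", "meadow", "steppe", "shrubland", "desert-steppe"]].sum(axis=1)
    np.testing.assert_allclose(sums, 100.0, atol=1e-9)
    assert tab["n_samples"].sum() == 200


def test_proportions_invariant_to_sample_duplication():
    ages = np.linspace(100, 10, 12)
    labels = np.array(["forest"] * 8 + ["steppe"] * 4, dtype=object)
    seq = BiomeSequence(ages, labels)
    dense_ages = np.linspace(100, 10, 24)
    dense = BiomeSequence(dense_ages, np.repeat(labels, 2))
    a = interval_proportions(seq)
    b = interval_proportions(dense)
    np.testing.assert_allclose(
        a[["forest", "steppe"]].to_numpy(), b[["forest", "steppe"]].to_numpy()
    )


def test_unclassified_excluded_from_denominator():
    ages = np.linspace(100, 10, 4)
    labels = np.array(["forest", "unclassified", "forest", "meadow"], dtype=object)
    tab = interval_proportions(BiomeSequence(ages, labels))
    assert tab.iloc[0]["forest"] == pytest.approx(200 / 3)
    assert tab.iloc[0]["n_samples"] == 3


def test_boundary_outside_span_rejected():
    seq = BiomeSequence(np.array([50.0, 10.0]), np.array(["forest", "forest"], dtype=object))
    with pytest.raises(ValueError):
        interval_proportions(seq, boundaries=[500.0])


# --------------------------------------------------------------- screening


def test_influx_screen_flags_low_sample():
    counts = [{"A": 300}] * 9 + [{"A": 300}]
    samples = []
    for i, c in enumerate(counts):
        # last sample has a huge spike count -> tiny concentration
        spike = 10 if i < 9 else 1000
        samples.append(SampleRecord(float(i), c, spike_counted=spike))
    core = PollenCore(samples)
    flags = influx_screen(core, quantile=0.15)
    assert flags.iloc[-1]
    assert flags.sum() == 1


def test_influx_screen_uniform_no_flags():
    samples = [SampleRecord(float(i), {"A": 300}, spike_counted=10) for i in range(10)]
    flags = influx_screen(PollenCore(samples), quantile=0.05)
    assert flags.sum() == 0  # strict inequality on ties


def test_influx_screen_rate_matches_quantile(rng):
    # continuous influx values -> flag rate equals the configured quantile
    n = 400
    samples = [
        SampleRecord(float(i), {"A": int(300 + rng.integers(0, 5000))}, spike_counted=37)
        for i in range(n)
    ]
    flags = influx_screen(PollenCore(samples), quantile=0.10)
    assert flags.mean() == pytest.approx(0.10, abs=0.01)
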