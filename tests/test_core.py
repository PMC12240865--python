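"""Data model, I/O, age–depth modelling and count arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palaeoveg.core import (
    AgeModel,
    PollenCore,
    SampleRecord,
    Series,
    TaxonInfo,
    apply_age_model,
    concentration,
    influx,
    percentages,
    read_counts,
    resample_uniform,
    write_counts,
)


def make_core(counts_list, groups=None, **kw):
    samples = [
        SampleRecord(depth=float(i), counts=c, **kw) for i, c in enumerate(counts_list)
    ]
    taxa = [TaxonInfo(n, g) for n, g in (groups or {}).items()]
    return PollenCore(samples, taxa)


# ---------------------------------------------------------------- validation


def test_depths_must_increase():
    s = [SampleRecord(1.0, {"A": 5}), SampleRecord(1.0, {"A": 5})]
    with pytest.raises(ValueError, match="strictly increasing"):
        PollenCore(s)


def test_negative_and_fractional_counts_rejected():
    with pytest.raises(ValueError, match="negative"):
        SampleRecord(0.0, {"A": -1})
    with pytest.raises(ValueError, match="non-integer"):
        SampleRecord(0.0, {"A": 1.5})


def test_aquatic_taxon_cannot_join_terrestrial_sum():
    with pytest.raises(ValueError):
        TaxonInfo("Typha", "aquatic", include_in_sum=True)
    assert TaxonInfo("Typha", "aquatic").include_in_sum is False


def test_sample_without_terrestrial_grains_rejected():
    with pytest.raises(ValueError, match="terrestrial"):
        make_core([{"Typha": 10}], groups={"Typha": "aquatic"})


# ---------------------------------------------------------------- file I/O


def test_long_csv_roundtrip(tmp_path):
    core = make_core(
        [{"Pinus": 60, "Poaceae": 40}, {"Pinus": 10, "Poaceae": 90}, {"Pinus": 5, "Poaceae": 200}],
        groups={"Pinus": "tree", "Poaceae": "herb"},
        spike_counted=50,
        volume=2.5,
    )
    p = tmp_path / "core.csv"
    write_counts(core, p)
    back = read_counts(p)
    assert len(back) == 3
    assert back.counts_frame().equals(core.counts_frame())
    assert [t.group for t in back.taxa] == [t.group for t in core.taxa]
    assert back.samples[0].volume == 2.5
    assert back.samples[0].spike_counted == 50


def test_wide_and_long_layouts_parse_identically(tmp_path):
    long = tmp_path / "long.csv"
    wide = tmp_path / "wide.csv"
    long.write_text(
        "sample_id,depth_m,taxon,count\n"
        "s1,0.5,Pinus,30\ns1,0.5,Poaceae,70\n"
        "s2,1.5,Pinus,80\ns2,1.5,Poaceae,20\n"
    )
    wide.write_text("depth_m,Pinus,Poaceae\n0.5,30,70\n1.5,80,20\n")
    a, b = read_counts(long), read_counts(wide)
    assert np.array_equal(a.counts_frame().to_numpy(), b.counts_frame().to_numpy())
    assert list(a.depths) == list(b.depths)
    assert a.taxon_names == b.taxon_names


def test_tilia_export_dialect(tmp_path):
    p = tmp_path / "tilia.csv"
    p.write_text("taxon,group,0.5,1.5\nPinus,tree,30,80\nPoaceae,herb,70,20\n")
    core = read_counts(p, dialect="tilia_export")
    assert core.counts_frame().to_numpy().tolist() == [[30, 70], [80, 20]]
    assert core.taxon("Pinus").group == "tree"


def test_reader_rejects_bad_files(tmp_path):
    neg = tmp_path / "neg.csv"
    neg.write_text("depth_m,Pinus\n0.5,-3\n")
    with pytest.raises(ValueError, match="non-negative"):
        read_counts(neg)
    dup = tmp_path / "dup.csv"
    dup.write_text("depth_m,Pinus\n0.5,3\n0.5,4\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_counts(dup)


# ---------------------------------------------------------------- percentages


def test_percentages_use_terrestrial_sum():
    core = make_core(
        [{"Pinus": 60, "Poaceae": 40, "Typha": 10}],
        groups={"Pinus": "tree", "Poaceae": "herb", "Typha": "aquatic"},
    )
    pct = percentages(core)
    assert pct.iloc[0]["Pinus"] == pytest.approx(60.0)
    assert pct.iloc[0]["Poaceae"] == pytest.approx(40.0)
    # aquatic percentage uses the same terrestrial denominator
    assert pct.iloc[0]["Typha"] == pytest.approx(10.0)


def test_percentages_hand_example():
    pct = percentages(make_core([{"A": 1, "B": 2}]))
    assert pct.iloc[0]["A"] == pytest.approx(100 / 3)
    assert pct.iloc[0]["B"] == pytest.approx(200 / 3)


def test_single_taxon_is_100():
    pct = percentages(make_core([{"A": 7}]))
    assert pct.iloc[0]["A"] == pytest.approx(100.0)


@settings(deadline=None, max_examples=50)
@given(
    st.lists(
        st.dictionaries(
            st.sampled_from(["A", "B", "C", "D"]),
            st.integers(0, 500),
            min_size=1,
        ).filter(lambda d: sum(d.values()) > 0),
        min_size=1,
        max_size=6,
    )
)
def test_percentage_closure_property(counts_list):
    core = make_core(counts_list)
    pct = percentages(core)
    np.testing.assert_allclose(pct.sum(axis=1), 100.0, atol=1e-9)


# ----------------------------------------------------- concentration / influx


def test_concentration_formula():
    s = SampleRecord(0.0, {"Pinus": 300}, spike_counted=100, spike_added=20848, volume=2.0)
    assert concentration(s)["Pinus"] == pytest.approx(31272.0)


def test_concentration_zero_count_and_volume_scaling():
    s1 = SampleRecord(0.0, {"A": 0, "B": 10}, spike_counted=10, volume=1.0)
    s2 = SampleRecord(0.0, {"A": 0, "B": 10}, spike_counted=10, volume=2.0)
    c1, c2 = concentration(s1), concentration(s2)
    assert c1["A"] == 0.0
    assert c1["B"] == pytest.approx(2 * c2["B"])


def test_concentration_requires_spike():
    s = SampleRecord(0.0, {"A": 10}, spike_counted=0)
    with pytest.raises(ValueError, match="spike_counted"):
        concentration(s)


def test_concentration_homogeneous_in_counts():
    a = SampleRecord(0.0, {"A": 30}, spike_counted=10)
    b = SampleRecord(0.0, {"A": 90}, spike_counted=10)
    assert concentration(b)["A"] == pytest.approx(3 * concentration(a)["A"])


def test_influx_product_and_hiatus():
    assert influx(31272.0, 0.03) == pytest.approx(938.16)
    assert np.isnan(influx(31272.0, 0.0))  # hiatus: undefined, not 0
    assert influx(0.0, 0.03) == 0.0


# ---------------------------------------------------------------- age model


def test_age_model_linear_and_exact_at_ties():
    m = AgeModel([(0.0, 0.0), (100.0, 100.0)])
    assert m.age_at(50.0) == pytest.approx(50.0)
    assert m.age_at(100.0) == pytest.approx(100.0)


def test_age_model_bracketing_segment_only():
    # three unequal segments; interior depths follow only their own segment
    m = AgeModel([(0.0, 0.0), (10.0, 50.0), (30.0, 70.0), (100.0, 1000.0)])
    assert m.age_at(5.0) == pytest.approx(25.0)
    assert m.age_at(20.0) == pytest.approx(60.0)
    assert m.age_at(65.0) == pytest.approx(70 + (65 - 30) / 70 * 930)


def test_age_model_monotone_everywhere():
    m = AgeModel([(0.0, 0.0), (10.0, 50.0), (30.0, 70.0), (100.0, 1000.0)])
    z = np.linspace(0, 100, 333)
    ages = m.age_at(z)
    assert np.all(np.diff(ages) > 0)


def test_age_model_rejects_non_monotone_and_extrapolation():
    with pytest.raises(ValueError):
        AgeModel([(0.0, 10.0), (5.0, 5.0)])
    m = AgeModel([(0.0, 0.0), (10.0, 10.0)])
    with pytest.raises(ValueError, match="outside"):
        m.age_at(11.0)


def test_hiatus_as_duplicate_depth():
    # age jumps 2934 -> 2964 ka at 900 m
    m = AgeModel([(800.0, 2800.0), (900.0, 2934.0), (900.0, 2964.0), (1000.0, 3100.0)])
    assert m.hiatuses == [(900.0, 2934.0, 2964.0)]
    assert m.age_at(900.0) == pytest.approx(2934.0)  # younger side
    assert m.age_at(899.999) < 2934.0
    assert m.age_at(900.001) > 2964.0
    assert m.sed_rate_at(900.0) > 0


def test_apply_age_model_and_yaml_roundtrip(tmp_path):
    core = make_core([{"A": 10}, {"A": 10}], spike_counted=5)
    m = AgeModel([(0.0, 0.0), (1.0, 7.0)])
    p = tmp_path / "ties.yaml"
    m.to_yaml(p)
    m2 = AgeModel.from_yaml(p)
    dated = apply_age_model(core, m2)
    assert dated.samples[0].age == 0.0
    assert dated.samples[1].age == pytest.approx(7.0)


def test_sed_rate_per_segment():
    m = AgeModel([(0.0, 0.0), (1.0, 10.0), (2.0, 12.0)])
    # 1 m per 10 kyr = 100 cm / 10000 yr
    assert m.sed_rate_at(0.5) == pytest.approx(0.01)
    assert m.sed_rate_at(1.5) == pytest.approx(0.05)


# ---------------------------------------------------------------- resampling


def test_resample_trivial_grid():
    s = Series(np.array([0.0, 2.0]), np.array([0.0, 2.0]))
    out = resample_uniform(s, 1.0)
    np.testing.assert_allclose(out.value, [0, 1, 2])


def test_resample_idempotent_on_uniform():
    s = Series(np.arange(5.0), np.array([3.0, 1, 4, 1, 5]))
    out = resample_uniform(s, 1.0)
    np.testing.assert_allclose(out.value, s.value)


def test_resample_matches_hand_interpolation():
    s = Series(np.array([0.0, 1.0, 2.5, 4.0, 7.0]), np.array([0.0, 2.0, 5.0, 2.0, 8.0]))
    out = resample_uniform(s, 2.0)
    np.testing.assert_allclose(out.age, [0, 2, 4, 6])
    np.testing.assert_allclose(out.value, [0.0, 4.0, 2.0, 6.0])


def test_resample_rejects_bad_dt():
    s = Series(np.array([0.0, 2.0]), np.array([0.0, 2.0]))
    with pytest.raises(ValueError):
        resample_uniform(s, 0.0)
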