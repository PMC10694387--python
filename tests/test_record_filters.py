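"""Duplicate criteria, basis/temporal filters and curation scenarios."""

import pandas as pd
import pytest

from occurate.record_filters import (
    CurationScenario,
    DuplicateKey,
    apply_scenario,
    dedupe,
    default_scenarios,
    discard_proportions,
    filter_basis,
    filter_temporal,
)


def _records(rows):
    df = pd.DataFrame(rows)
    defaults = {
        "recordID": [f"r{i}" for i in range(len(df))],
        "acceptedName": "Bryum argenteum",
        "scientificName": "Bryum argenteum",
        "decimalLatitude": 45.25,
        "decimalLongitude": -3.5,
        "eventDate": "1985-06-15",
        "year": 1985,
        "basisOfRecord": "PreservedSpecimen",
        "recordedBy": "Smith",
        "cellID": "c1",
    }
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    return df


def test_duplicate_key_requires_minimum():
    with pytest.raises(ValueError, match="event_date"):
        DuplicateKey(components=("species_name", "latitude", "longitude"))
    with pytest.raises(ValueError, match="unknown"):
        DuplicateKey(components=("species_name", "latitude", "longitude", "event_date", "basis"))


def test_collector_in_key_separates_duplicates():
    records = _records([{"recordedBy": "Smith"}, {"recordedBy": "Jones"}])
    without, _, _ = dedupe(records)  # name+coords+date
    assert len(without) == 1
    with_collector, _, _ = dedupe(
        records,
        DuplicateKey(components=("species_name", "latitude", "longitude", "event_date", "recorded_by")),
    )
    assert len(with_collector) == 2


def test_dedupe_idempotent_and_keeps_first():
    records = _records([{"recordID": "a"}, {"recordID": "b"}, {"recordID": "c"}])
    once, _, _ = dedupe(records)
    assert list(once["recordID"]) == ["a"]
    twice, _, _ = dedupe(once)
    pd.testing.assert_frame_equal(twice, once)


def test_missing_key_component_blocks_merging():
    records = _records([{"eventDate": pd.NA}, {"eventDate": pd.NA}])
    kept, _, rep = dedupe(records)
    assert len(kept) == 2 and rep.details["incomplete_key"] == 2


def test_dedupe_kept_count_input_order_invariant(world):
    annotated = world.records.assign(acceptedName=world.records["scientificName"])
    n1 = len(dedupe(annotated)[0])
    shuffled = annotated.sample(frac=1.0, random_state=0)
    n2 = len(dedupe(shuffled)[0])
    assert n1 == n2


def test_dedupe_matches_duplicate_groups_in_ledger(world, ledger):
    # the date-only duplicate key merges exactly the planted copy groups
    annotated = world.records.assign(acceptedName=world.records["scientificName"])
    kept, removed, rep = dedupe(annotated)
    assert len(kept) == ledger["duplicate_group"].nunique()
    assert set(removed["recordID"]) <= set(ledger.index[ledger["is_duplicate_copy"]])


def test_filter_basis_format_insensitive():
    records = _records(
        [{"basisOfRecord": "PRESERVED_SPECIMEN"}, {"basisOfRecord": "HumanObservation"}]
    )
    kept, removed, _ = filter_basis(records, {"PreservedSpecimen"})
    assert len(kept) == 1 and removed["basisOfRecord"].iloc[0] == "HumanObservation"
    all_kept, _, _ = filter_basis(records, {"PreservedSpecimen", "HumanObservation"})
    assert len(all_kept) == 2


def test_cellwise_discard_example():
    # 10 records in a cell, 2 preserved → 80% of records discarded there
    rows = [{"basisOfRecord": "PreservedSpecimen" if i < 2 else "HumanObservation",
             "acceptedName": f"Sp {i}"} for i in range(10)]
    records = _records(rows)
    kept, _, _ = filter_basis(records, {"PreservedSpecimen"})
    props = discard_proportions(records, kept)
    assert props.loc["c1", "prop_records"] == pytest.approx(0.8)
    assert props.loc["c1", "prop_species"] == pytest.approx(0.8)


@pytest.mark.parametrize(
    "year,kwargs,removed",
    [
        (1599, dict(min_year=1600, require_year=True), True),
        (1985, dict(min_year=1970, max_year=2000), False),
        (1985, dict(min_year=1990), True),
        (pd.NA, dict(min_year=1600, require_year=True), True),
        (pd.NA, dict(min_year=1990), False),  # no year, not required → kept
    ],
)
def test_temporal_variants(year, kwargs, removed):
    records = _records([{"year": year}])
    _, rem, _ = filter_temporal(records, **kwargs)
    assert (len(rem) == 1) is removed


def test_temporal_bad_window_rejected():
    with pytest.raises(ValueError):
        filter_temporal(_records([{}]), min_year=2000, max_year=1990)


def test_nested_temporal_windows(world):
    base = world.records
    k1990 = set(filter_temporal(base, min_year=1990)[0]["recordID"])
    k1970 = set(filter_temporal(base, min_year=1970)[0]["recordID"])
    k1900 = set(filter_temporal(base, min_year=1900)[0]["recordID"])
    k1600r = set(filter_temporal(base, min_year=1600, require_year=True)[0]["recordID"])
    r1990 = set(filter_temporal(base, min_year=1990, require_year=True)[0]["recordID"])
    assert r1990 <= k1990 and r1990 <= k1600r
    assert k1990 <= k1970 <= k1900


def test_scenarios_contractive_and_ordered(world, standardised):
    maps, consensus = standardised
    for scenario in default_scenarios():
        curated, reports = apply_scenario(world.records, scenario, maps, consensus)
        assert len(curated) <= len(world.records)
        assert reports[-1].name == "duplicates"  # dedupe runs last
        for rep in reports:
            assert rep.n_in == rep.n_kept + rep.n_removed


def test_date_specim_equals_basis_then_dedupe(world, standardised):
    maps, consensus = standardised
    from occurate.taxonomy import apply_consensus

    scenario = next(s for s in default_scenarios() if s.name == "date-specim")
    curated, _ = apply_scenario(world.records, scenario, maps, consensus)
    tax, _, _ = apply_consensus(world.records, maps, consensus)
    manual, _, _ = filter_basis(tax, {"PreservedSpecimen"})
    manual, _, _ = dedupe(manual)
    assert list(curated["recordID"]) == list(manual["recordID"])


def test_unknown_taxonomy_source_rejected(world, standardised):
    maps, consensus = standardised
    bad = CurationScenario(name="x", taxonomy_source="NOPE")
    with pytest.raises(ValueError, match="NOPE"):
        apply_scenario(world.records, bad, maps, consensus)


def test_discard_proportions_bounds():
    records = _records([{"acceptedName": f"Sp {i}"} for i in range(5)])
    same = discard_proportions(records, records)
    assert (same == 0).all().all()
    none = discard_proportions(records, records.iloc[0:0])
    assert (none == 1).all().all()
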