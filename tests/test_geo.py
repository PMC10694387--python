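"""Equal-area projection, exclusion rules and grid/band/region assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from occurate import ease2, geo, simulate
from occurate.geo import StudyGrid
from occurate.io import RECORD_COLUMNS


def make_records(rows):
    df = pd.DataFrame(rows)
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    if df["recordID"].isna().all():
        df["recordID"] = [f"r{i}" for i in range(len(df))]
    return df[RECORD_COLUMNS]


# --------------------------------------------------------------------- ease2


def test_projection_matches_published_extent():
    # documented EASE-Grid 2.0 Global map extent
    assert ease2.X_MAX == pytest.approx(17367530.44, abs=0.5)
    assert ease2.Y_MAX == pytest.approx(7342230.14, abs=0.5)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    lon=st.floats(min_value=-180, max_value=180),
    lat=st.floats(min_value=-85, max_value=85),
)
def test_projection_round_trip(lon, lat):
    lon2, lat2 = ease2.inverse(*ease2.forward(lon, lat))
    assert lon2 == pytest.approx(lon, abs=1e-9)
    assert lat2 == pytest.approx(lat, abs=1e-6)


def test_equal_area_property():
    """Cells of equal projected size cover equal spherical area: y spacing
    compresses towards the pole as 1/cos-like latitude stretching."""
    _, y1 = ease2.forward(0.0, 30.0)
    _, y2 = ease2.forward(0.0, 30.1)
    _, y3 = ease2.forward(0.0, 80.0)
    _, y4 = ease2.forward(0.0, 80.1)
    assert (y2 - y1) > (y4 - y3)  # same degree step, less projected distance


# ----------------------------------------------------------------- filters


def test_filter_fossil():
    df = make_records(
        [{"basisOfRecord": "FossilSpecimen"}, {"basisOfRecord": "PreservedSpecimen"}]
    )
    kept, removed, rep = geo.filter_fossil(df)
    assert len(kept) == 1 and removed["basisOfRecord"].iloc[0] == "FossilSpecimen"
    kept2, _, _ = geo.filter_fossil(kept)
    pd.testing.assert_frame_equal(kept2, kept)


@pytest.mark.parametrize(
    "event,year,removed",
    [
        ("1985-06-15", 1985, False),
        ("1985-13-02", 1985, True),  # invalid month
        ("1985-02-30", 1985, True),  # invalid day
        ("2150-06-15", 2150, True),  # future
        (pd.NA, pd.NA, False),  # undated records survive pre-processing
    ],
)
def test_filter_dates(event, year, removed):
    df = make_records([{"eventDate": event, "year": year}])
    kept, rem, _ = geo.filter_dates(df)
    assert (len(rem) == 1) is removed


@pytest.mark.parametrize(
    "lat,lon,removed",
    [
        (45.0, 45.0, True),  # same value in latitude and longitude
        (52.37, 0.0, True),  # zero coordinate
        (45.0, -3.0, True),  # integer pair: no decimal digits
        (45.5, -3.0, False),  # one coordinate fractional
        (19.99, 10.5, True),  # south of the study area
        (45.3, -3.2, False),
        (pd.NA, 10.5, True),  # missing
    ],
)
def test_filter_coordinates_rules(lat, lon, removed):
    df = make_records([{"decimalLatitude": lat, "decimalLongitude": lon}])
    kept, rem, _ = geo.filter_coordinates(df)
    assert (len(rem) == 1) is removed


def test_zero_pair_only_flag():
    df = make_records([{"decimalLatitude": 52.37, "decimalLongitude": 0.0}])
    _, rem, _ = geo.filter_coordinates(df, zero_pair_only=True)
    assert len(rem) == 0


def test_country_mismatch_buffer():
    polys = {"AA": box(0.0, 40.0, 10.0, 50.0)}
    df = make_records(
        [
            {"decimalLatitude": 45.0, "decimalLongitude": 5.0, "countryCode": "AA"},
            {"decimalLatitude": 45.0, "decimalLongitude": 10.05, "countryCode": "AA"},
            {"decimalLatitude": 45.0, "decimalLongitude": 10.5, "countryCode": "AA"},
            {"decimalLatitude": 45.0, "decimalLongitude": 30.0, "countryCode": pd.NA},
            {"decimalLatitude": 45.0, "decimalLongitude": 30.0, "countryCode": "ZZ"},
        ]
    )
    kept, removed, rep = geo.filter_country_mismatch(df, polys, buffer_deg=0.1)
    # inside kept; 0.05° outside kept via buffer; 0.5° outside removed;
    # missing code kept; unknown code kept but counted unmatchable
    assert list(removed["decimalLongitude"]) == [10.5]
    assert rep.details["unmatchable_country_code"] == 1


def test_gazetteer_radius():
    gaz = simulate.default_gazetteer()
    cent = gaz.entries.iloc[0]
    df = make_records(
        [
            {"decimalLatitude": cent.decimalLatitude, "decimalLongitude": cent.decimalLongitude},
            {"decimalLatitude": cent.decimalLatitude + 1.0, "decimalLongitude": cent.decimalLongitude},
        ]
    )
    kept, removed, rep = geo.filter_gazetteer(df, gaz)
    assert len(removed) == 1 and len(kept) == 1
    assert rep.details.get("country_centroid") == 1


@pytest.mark.parametrize(
    "rank,name,kept",
    [
        ("SPECIES", "Bryum argenteum", True),
        ("GENUS", "Bryum", False),
        ("VARIETY", "Bryum argenteum var. lanatum", True),
        (pd.NA, "Bryum argenteum", True),  # binomial with missing rank
        (pd.NA, "Bryum", False),
    ],
)
def test_filter_rank(rank, name, kept):
    df = make_records([{"taxonRank": rank, "scientificName": name}])
    k, _, _ = geo.filter_rank(df)
    assert (len(k) == 1) is kept


def test_filters_partition_and_order_independence(world):
    records = world.records
    filters = [
        geo.filter_fossil,
        geo.filter_dates,
        geo.filter_coordinates,
        lambda df: geo.filter_country_mismatch(df, world.countries),
        lambda df: geo.filter_gazetteer(df, world.gazetteer),
        geo.filter_rank,
    ]
    for f in filters:
        kept, removed, rep = f(records)
        assert len(kept) + len(removed) == len(records) == rep.n_in
        assert set(kept["recordID"]).isdisjoint(removed["recordID"])
    # conjunction of record-level predicates: any order, same kept set
    def chain(order):
        df = records
        for f in order:
            df, _, _ = f(df)
        return set(df["recordID"])

    assert chain(filters) == chain(filters[::-1])


def test_each_filter_recovers_planted_class_exactly(world, ledger):
    checks = [
        (geo.filter_fossil(world.records), ["fossil"]),
        (geo.filter_dates(world.records), ["invalid_date"]),
        (geo.filter_coordinates(world.records), ["zero_coord", "integer_coord", "lat_eq_lon"]),
        (geo.filter_country_mismatch(world.records, world.countries), ["country_mismatch"]),
        (geo.filter_gazetteer(world.records, world.gazetteer), ["centroid"]),
        (geo.filter_rank(world.records), ["genus_rank"]),
    ]
    for (kept, removed, _), classes in checks:
        planted = set(ledger.index[ledger[classes].any(axis=1)])
        assert set(removed["recordID"]) == planted  # precision = recall = 1


# ------------------------------------------------------------------ gridding


def test_cells_are_a_function_of_coordinates():
    grid = StudyGrid()
    df = make_records(
        [
            {"decimalLatitude": 45.0005, "decimalLongitude": 5.0},
            {"decimalLatitude": 45.0005, "decimalLongitude": 5.0},
            {"decimalLatitude": 45.005, "decimalLongitude": 5.001},  # ~1 km away
        ]
    )
    kept, _, _ = geo.assign_cells(df, grid)
    assert kept["cellID"].nunique() == 1


def test_band_numbering_monotone_northwards():
    df = make_records(
        [
            {"decimalLatitude": 25.0, "decimalLongitude": 5.3},
            {"decimalLatitude": 70.0, "decimalLongitude": 5.3},
        ]
    )
    kept, _, _ = geo.assign_cells(df)
    bands = kept["bandIndex"].tolist()
    assert bands[0] < bands[1]
    assert 1 <= bands[0] and bands[1] <= 49


def test_cell_edges_half_open():
    grid = StudyGrid()
    # construct a point exactly on a cell edge in projected x
    edge_x = grid.origin_x + 123 * grid.cell_size_m
    lon_edge, lat = ease2.inverse(edge_x, ease2.forward(0.0, 45.0)[1])
    df = make_records([{"decimalLatitude": float(lat), "decimalLongitude": float(lon_edge)}])
    kept, _, _ = geo.assign_cells(df, grid)
    assert kept["cellID"].iloc[0].startswith("c0123")  # higher-index side


def test_region_rules():
    grid = StudyGrid()
    regions = grid.region_of_lon([-100.0, 5.0, 120.0])
    assert list(regions) == ["NorthAmerica", "EuropeNAfrica", "Asia"]


def test_assigned_cells_match_generator_intent(world, ledger):
    kept, _, _ = geo.preprocess(
        world.records, country_polygons=world.countries, gazetteer=world.gazetteer
    )
    merged = kept.merge(
        ledger[["cellID", "bandIndex", "region"]].rename(
            columns={"cellID": "cell_true", "bandIndex": "band_true", "region": "region_true"}
        ),
        left_on="recordID",
        right_index=True,
    )
    # survivors carry no coordinate errors, so assignment equals the plan
    assert (merged["cellID"] == merged["cell_true"]).all()
    assert (merged["bandIndex"] == merged["band_true"]).all()
    assert (merged["region"] == merged["region_true"]).all()
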