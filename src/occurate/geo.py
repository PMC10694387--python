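"""Record-level geographic/temporal exclusion rules and equal-area gridding.

Implements the pre-processing chain applied to every raw occurrence table:
drop fossil specimens, records with illegitimate collection dates
(present but non-calendar or future; undated records survive), suspect
coordinates (zero, integer pairs, latitude = longitude, missing, south of
the study area), records whose point contradicts their declared country
(0.1° buffer), records at known problem locations (country centroids,
repository headquarters), and records not identified to species level or
lower. Survivors are assigned to 100-km equal-area grid cells (EASE-Grid
2.0 Global), to one of 49 latitudinal bands numbered northwards from the
southern study-area edge, and to a region by longitude.

Every filter partitions its input (kept ∪ removed = input) and depends
only on the record itself, so the kept set of the full chain is
order-independent.
"""

from __future__ import annotations

import calendar
import json
import re
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

from . import ease2
from .io import Gazetteer
from .report import FilterReport, split

EARTH_RADIUS_KM = 6371.0088

#: Default longitude intervals (west-closed) → region label.
DEFAULT_REGION_RULES = (
    (-180.0, -30.0, "NorthAmerica"),
    (-30.0, 60.0, "EuropeNAfrica"),
    (60.0, 180.0, "Asia"),
)


@dataclass
class StudyGrid:
    """The 100-km equal-area analysis grid over the temperate Northern Hemisphere.

    Cells are half-open squares [low, high) in projected x/y; the band
    index is the cell row, numbered 1..n_bands from the southern edge
    (min_latitude_deg) northwards. Points on the global upper/eastern edge
    fall into the last cell.
    """

    cell_size_m: float = 100_000.0
    n_bands: int = 49
    min_latitude_deg: float = 20.0
    region_rules: tuple = DEFAULT_REGION_RULES

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        self.origin_x = -ease2.X_MAX
        _, self.origin_y = ease2.forward(0.0, self.min_latitude_deg)
        self.origin_y = float(self.origin_y)
        self.n_cols = int(np.ceil(2 * ease2.X_MAX / self.cell_size_m))

    def band_of_y(self, y):
        """Band index (1..n_bands) of projected y; NaN outside the grid."""
        y = np.asarray(y, dtype=float)
        row = np.floor((y - self.origin_y) / self.cell_size_m)
        # clamp the polar edge into the top band
        row = np.where((y <= ease2.Y_MAX) & (row >= self.n_bands), self.n_bands - 1, row)
        row = np.where((row < 0) | (row >= self.n_bands), np.nan, row)
        return row + 1

    def region_of_lon(self, lon):
        lon = np.asarray(lon, dtype=float)
        out = np.full(lon.shape, None, dtype=object)
        for lo, hi, label in self.region_rules:
            m = (lon >= lo) & (lon < hi) if hi < 180 else (lon >= lo) & (lon <= hi)
            out[m] = label
        return out


def assign_cells(records: pd.DataFrame, grid: StudyGrid | None = None):
    """Annotate records with ``cellID``, ``bandIndex`` and ``region``.

    Records whose projected point falls outside the grid extent are
    excluded and counted as ``out_of_grid``. Returns (annotated, excluded,
    FilterReport).
    """
    grid = grid or StudyGrid()
    lon = records["decimalLongitude"].to_numpy(dtype=float)
    lat = records["decimalLatitude"].to_numpy(dtype=float)
    x, y = ease2.forward(lon, lat)
    col = np.floor((x - grid.origin_x) / grid.cell_size_m)
    col = np.where((x <= ease2.X_MAX) & (col >= grid.n_cols), grid.n_cols - 1, col)
    band = grid.band_of_y(y)
    ok = (~np.isnan(band)) & (col >= 0) & (col < grid.n_cols)

    out = records.copy()
    with np.errstate(invalid="ignore"):
        out["bandIndex"] = pd.array(band, dtype="Int64")
        out["cellID"] = [
            f"c{int(c):04d}b{int(b):02d}" if good else pd.NA
            for c, b, good in zip(col, np.nan_to_num(band), ok)
        ]
    out["region"] = grid.region_of_lon(lon)
    kept, removed, report = split(out, ~pd.Series(ok, index=out.index), "assign_cells")
    report.details["out_of_grid"] = int((~ok).sum())
    return kept, removed, report


# ---------------------------------------------------------------------------
# record-level exclusion rules
# ---------------------------------------------------------------------------

_BASIS_NORM_RE = re.compile(r"[^a-z]")


def normalise_basis(value) -> str:
    """Case/format-insensitive basisOfRecord key ("PRESERVED_SPECIMEN" ≡ "PreservedSpecimen")."""
    if pd.isna(value):
        return ""
    return _BASIS_NORM_RE.sub("", str(value).lower())


def filter_fossil(records: pd.DataFrame):
    """Drop fossil records (basisOfRecord = FossilSpecimen)."""
    basis = records["basisOfRecord"].map(normalise_basis)
    return split(records, basis == "fossilspecimen", "fossil")


_DATE_RE = re.compile(r"^(\d{4})(?:-(\d{1,2})(?:-(\d{1,2}))?)?$")


def _date_ok(value: str, max_year: int) -> bool:
    m = _DATE_RE.match(str(value).strip())
    if not m:
        return False
    year = int(m.group(1))
    if year > max_year or year == 0:
        return False
    month = int(m.group(2)) if m.group(2) else None
    day = int(m.group(3)) if m.group(3) else None
    if month is not None and not 1 <= month <= 12:
        return False
    if day is not None and not 1 <= day <= calendar.monthrange(year, month)[1]:
        return False
    return True


def filter_dates(records: pd.DataFrame, max_year: int | None = None):
    """Drop records with an illegitimate collection date.

    A date is illegitimate when present but not a calendar date
    (e.g. month 13, day 32) or in the future. Records with no date at all
    are kept — missing temporal metadata is handled by the optional
    temporal curation filters, not by pre-processing.
    """
    max_year = max_year or date.today().year
    bad_event = records["eventDate"].map(
        lambda v: (not pd.isna(v)) and not _date_ok(v, max_year)
    )
    year = pd.to_numeric(records["year"], errors="coerce")
    bad_year = year.notna() & ((year > max_year) | (year <= 0))
    return split(
        records,
        bad_event | bad_year,
        "illegitimate_date",
        details={
            "invalid_eventDate": int(bad_event.sum()),
            "invalid_year": int(bad_year.sum()),
        },
    )


def filter_coordinates(
    records: pd.DataFrame,
    min_latitude_deg: float = 20.0,
    zero_pair_only: bool = False,
):
    """Drop records with suspect or out-of-area coordinates.

    Rules: (a) latitude exactly equal to longitude; (b) a zero coordinate
    (both must be zero when ``zero_pair_only``); (c) both coordinates
    integral, i.e. no decimal precision; (d) missing coordinates;
    (e) latitude south of ``min_latitude_deg``. The report attributes each
    removal to its first matching rule in the order d, b, a, c, e.
    """
    lat = pd.to_numeric(records["decimalLatitude"], errors="coerce")
    lon = pd.to_numeric(records["decimalLongitude"], errors="coerce")
    missing = lat.isna() | lon.isna()
    zero = (lat == 0) & (lon == 0) if zero_pair_only else (lat == 0) | (lon == 0)
    equal = lat == lon
    integer = (lat == lat.round(0)) & (lon == lon.round(0))
    south = lat < min_latitude_deg
    for m in (zero, equal, integer, south):
        m &= ~missing
    remove = missing | zero | equal | integer | south
    first = {
        "missing": missing,
        "zero_coordinate": zero & ~missing,
        "lat_eq_lon": equal & ~missing & ~zero,
        "integer_pair": integer & ~missing & ~zero & ~equal,
        "south_of_study_area": south & ~missing & ~zero & ~equal & ~integer,
    }
    return split(
        records, remove, "coordinates", details={k: int(v.sum()) for k, v in first.items()}
    )


def load_country_polygons(path) -> dict:
    """Read a GeoJSON FeatureCollection into {country code: shapely geometry}.

    The code is taken from the first of the ``code``, ``ISO_A2`` or ``iso_a2``
    feature properties.
    """
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    out = {}
    for feat in gj["features"]:
        props = feat.get("properties", {})
        code = props.get("code") or props.get("ISO_A2") or props.get("iso_a2")
        if code is None:
            raise ValueError("country feature without a code/ISO_A2 property")
        out[str(code)] = shapely_shape(feat["geometry"])
    return out


def filter_country_mismatch(
    records: pd.DataFrame, country_polygons: dict, buffer_deg: float = 0.1
):
    """Drop records whose point falls outside their declared country.

    The country polygon is buffered by ``buffer_deg`` (~10 km) so points
    just over a border or off the coast survive. Records with no
    countryCode are kept (the rule tests mismatches, not missing
    metadata); unknown codes are kept and counted as unmatchable.
    """
    lat = records["decimalLatitude"].to_numpy(dtype=float)
    lon = records["decimalLongitude"].to_numpy(dtype=float)
    points = shapely.points(lon, lat)
    remove = np.zeros(len(records), dtype=bool)
    unmatchable = 0
    codes = records["countryCode"]
    for code, idx in records.groupby(codes, dropna=True).groups.items():
        geom = country_polygons.get(code)
        pos = records.index.get_indexer(idx)
        if geom is None:
            unmatchable += len(pos)
            continue
        inside = shapely.covers(geom.buffer(buffer_deg), points[pos])
        remove[pos] = ~inside
    return split(
        records,
        pd.Series(remove, index=records.index),
        "country_mismatch",
        details={"unmatchable_country_code": unmatchable},
    )


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between degree coordinates (vectorised)."""
    lat1, lon1, lat2, lon2 = (np.deg2rad(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    h = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def filter_gazetteer(records: pd.DataFrame, gazetteer: Gazetteer):
    """Drop records within each gazetteer entry's radius (centroids, institutions)."""
    lat = records["decimalLatitude"].to_numpy(dtype=float)
    lon = records["decimalLongitude"].to_numpy(dtype=float)
    remove = np.zeros(len(records), dtype=bool)
    per_kind: dict[str, int] = {}
    for entry in gazetteer.entries.itertuples(index=False):
        near = (
            haversine_km(lat, lon, entry.decimalLatitude, entry.decimalLongitude)
            <= entry.radius_km
        )
        per_kind[entry.kind] = per_kind.get(entry.kind, 0) + int((near & ~remove).sum())
        remove |= near
    return split(records, pd.Series(remove, index=records.index), "gazetteer", details=per_kind)


SPECIES_OR_LOWER = {"species", "subspecies", "variety", "form"}


def filter_rank(records: pd.DataFrame):
    """Keep records identified at species level or lower (forms, subspecies, varieties).

    Records with no stated rank are kept when the name is at least a
    binomial, removed when it is uninomial (a bare genus).
    """
    rank = records["taxonRank"].map(lambda v: "" if pd.isna(v) else str(v).strip().lower())
    binomial = records["scientificName"].map(
        lambda v: (not pd.isna(v)) and len(str(v).split()) >= 2
    )
    keep = rank.isin(SPECIES_OR_LOWER) | ((rank == "") & binomial)
    return split(records, ~keep, "taxon_rank")


def preprocess(
    records: pd.DataFrame,
    grid: StudyGrid | None = None,
    country_polygons: dict | None = None,
    gazetteer: Gazetteer | None = None,
    buffer_deg: float = 0.1,
    max_year: int | None = None,
):
    """Run the full pre-processing chain and grid assignment.

    Returns ``(kept, removed, reports)`` where ``removed`` concatenates the
    rejects of every rule and ``reports`` is the ordered list of
    FilterReports (conservation: len(kept) + len(removed) = len(records)).
    """
    grid = grid or StudyGrid()
    reports: list[FilterReport] = []
    removed_parts = []
    kept = records
    steps = [
        lambda df: filter_fossil(df),
        lambda df: filter_dates(df, max_year=max_year),
        lambda df: filter_coordinates(df, min_latitude_deg=grid.min_latitude_deg),
    ]
    if country_polygons is not None:
        steps.append(lambda df: filter_country_mismatch(df, country_polygons, buffer_deg))
    if gazetteer is not None:
        steps.append(lambda df: filter_gazetteer(df, gazetteer))
    steps.append(lambda df: filter_rank(df))
    for step in steps:
        kept, removed, rep = step(kept)
        reports.append(rep)
        removed_parts.append(removed)
    kept, removed, rep = assign_cells(kept, grid)
    reports.append(rep)
    removed_parts.append(removed)
    removed_all = pd.concat(removed_parts) if removed_parts else records.iloc[0:0]
    return kept, removed_all, reports
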