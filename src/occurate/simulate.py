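"""Synthetic occurrence worlds with known planted structure.

Generates Darwin-Core-style occurrence tables that emulate the pathologies
of aggregated biodiversity data — clustered sampling effort, coordinate
errors (zeros, integer pairs, latitude = longitude, country mismatches,
country centroids), duplicate records differing only in collector,
synonym/orthographic name variants that resolve differently across
taxonomic reference sources, undated and future-dated records, fossil
specimens and genus-level identifications — on top of a community whose
per-band species richness follows a two-segment piecewise-linear
latitudinal gradient with a known breakpoint.

Every generated record is described in a ground-truth ledger (which error
classes it carries, its duplicate group, its true accepted name and its
intended grid cell), so each downstream cleaning filter can be checked for
exact recovery of its planted class. The synthetic geography uses
axis-aligned rectangle countries with known centroids, which makes the
country-mismatch and centroid rules exactly verifiable without external
polygon data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping

from . import ease2
from .geo import StudyGrid
from .io import Gazetteer
from .taxonomy import TaxonLookup, normalise_name

# --------------------------------------------------------------------------
# synthetic geography: rectangle countries tiling the study area
# --------------------------------------------------------------------------

LAT_LO, LAT_HI = 20.0, 89.5
#: country code -> (lon_min, lon_max); three per region, tiling each region.
COUNTRY_BOUNDS = {
    "XA": (-180.0, -130.3),
    "XB": (-130.3, -80.7),
    "XC": (-80.7, -30.0),
    "XD": (-30.0, 0.4),
    "XE": (0.4, 30.2),
    "XF": (30.2, 60.0),
    "XG": (60.0, 100.6),
    "XH": (100.6, 140.2),
    "XI": (140.2, 180.0),
}
_CODES = list(COUNTRY_BOUNDS)

SOURCES = ("GBIF", "TPL", "TNRS", "Tropicos", "WFO")

GENERA = [
    "Bryum", "Sphagnum", "Polytrichum", "Hypnum", "Dicranum", "Grimmia",
    "Orthotrichum", "Tortula", "Mnium", "Fontinalis", "Racomitrium",
    "Schistidium", "Pohlia", "Brachythecium", "Fissidens",
]
_SYLLABLES = ["ra", "mi", "lo", "ve", "tu", "ca", "ne", "si", "po", "du", "fa", "ge"]
_SUFFIXES = ["um", "a", "ii", "ense", "oides", "atum", "ella"]
_AUTHORITIES = ["Hedw.", "(Brid.) Schimp.", "Mitt.", "Lindb.", "Bruch & Schimp."]


def default_countries() -> dict:
    """Rectangle country polygons (code → shapely geometry)."""
    return {
        code: box(lo, LAT_LO, hi, LAT_HI) for code, (lo, hi) in COUNTRY_BOUNDS.items()
    }


def country_centroids() -> dict:
    """Known (lon, lat) centroid of each rectangle country."""
    return {
        code: ((lo + hi) / 2.0, (LAT_LO + LAT_HI) / 2.0)
        for code, (lo, hi) in COUNTRY_BOUNDS.items()
    }


def default_gazetteer(radius_km: float = 1.0) -> Gazetteer:
    """Country centroids plus a repository headquarters and an institution."""
    rows = [
        {
            "label": f"centroid_{code}",
            "decimalLatitude": lat,
            "decimalLongitude": lon,
            "radius_km": radius_km,
            "kind": "country_centroid",
        }
        for code, (lon, lat) in country_centroids().items()
    ]
    rows.append(
        {"label": "repository_hq", "decimalLatitude": 55.68, "decimalLongitude": 12.59,
         "radius_km": radius_km, "kind": "repository_hq"}
    )
    rows.append(
        {"label": "herbarium_1", "decimalLatitude": 40.45, "decimalLongitude": -3.69,
         "radius_km": radius_km, "kind": "institution"}
    )
    return Gazetteer(entries=pd.DataFrame(rows))


def country_code_of(lon, lat):
    """Vectorised country assignment on the synthetic rectangle world."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    out = np.full(lon.shape, None, dtype=object)
    in_lat = (lat >= LAT_LO) & (lat <= LAT_HI)
    for code, (lo, hi) in COUNTRY_BOUNDS.items():
        m = in_lat & (lon >= lo) & (lon <= hi) & (out == None)  # noqa: E711
        out[m] = code
    return out


def write_countries_geojson(path) -> None:
    """Write the rectangle countries as a GeoJSON FeatureCollection."""
    import json

    features = [
        {
            "type": "Feature",
            "properties": {"code": code},
            "geometry": mapping(geom),
        }
        for code, geom in default_countries().items()
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


def _default_basis_mix() -> dict:
    return {"PreservedSpecimen": 0.55, "HumanObservation": 0.40, "MaterialSample": 0.05}


def _default_synonym_tables() -> dict:
    # per-source probability that a species (and its name variants) resolves
    return {"GBIF": 0.95, "TPL": 0.90, "TNRS": 0.97, "Tropicos": 0.88, "WFO": 0.92}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic world.

    Error-class probabilities default to small rates in line with the
    pathologies documented for aggregated occurrence data: ~4% of records
    undated, ~20% of records duplicated on name+coordinates+date of which
    about one in seven differs in collector (so the collector-aware
    duplicate criterion removes ~17% while the date-only criterion removes
    ~20%), and percent-level coordinate and basis problems.
    """

    seed: int = 0
    n_species_per_region: int = 150
    breakpoint_band: int = 40
    slope_below: float = 2.0
    slope_above: float = -2.0
    base_richness: float = 6.0
    n_records: int = 120_000
    cells_per_band: int = 2
    effort_sigma: float = 0.75
    #: exponent linking a cell's sampling effort to its band species-pool size
    effort_richness_scaling: float = 1.0
    p_zero_coord: float = 0.01
    p_integer_coord: float = 0.01
    p_lat_eq_lon: float = 0.005
    p_country_mismatch: float = 0.01
    p_centroid: float = 0.005
    p_missing_date: float = 0.04
    p_invalid_date: float = 0.005
    p_fossil: float = 0.01
    p_genus_rank: float = 0.005
    duplicate_rate: float = 0.25
    p_duplicate_new_collector: float = 0.15
    basis_mix: dict = field(default_factory=_default_basis_mix)
    year_range: tuple = (1900, 2020)
    p_synonym: float = 0.10
    p_typo: float = 0.02
    p_infraspecific: float = 0.05
    p_authority: float = 0.25
    synonym_tables: dict = field(default_factory=_default_synonym_tables)
    regions: tuple = ("NorthAmerica", "EuropeNAfrica", "Asia")
    n_bands: int = 49
    #: uniquifying tag mixed into generated epithets (keeps pools of two
    #: independently generated worlds disjoint)
    name_salt: str = ""

    def validate(self) -> None:
        probs = {
            name: getattr(self, name)
            for name in (
                "p_zero_coord", "p_integer_coord", "p_lat_eq_lon", "p_country_mismatch",
                "p_centroid", "p_missing_date", "p_invalid_date", "p_fossil",
                "p_genus_rank", "duplicate_rate", "p_duplicate_new_collector",
                "p_synonym", "p_typo", "p_infraspecific", "p_authority",
            )
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not 2 <= self.breakpoint_band <= self.n_bands - 1:
            raise ValueError(f"breakpoint_band must lie in [2, {self.n_bands - 1}]")
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        if self.band_richness().min() < 1:
            raise ValueError("slopes produce non-positive richness in some band")

    def band_richness(self) -> np.ndarray:
        """True per-band richness: two-segment piecewise-linear in the band index."""
        bands = np.arange(1, self.n_bands + 1)
        below = self.base_richness + self.slope_below * (bands - 1)
        above = (
            self.base_richness
            + self.slope_below * (self.breakpoint_band - 1)
            + self.slope_above * (bands - self.breakpoint_band)
        )
        return np.where(bands <= self.breakpoint_band, below, above)


# --------------------------------------------------------------------------
# community
# --------------------------------------------------------------------------


@dataclass
class SpeciesInfo:
    name: str  # accepted binomial
    genus: str
    synonym: str  # alternative binomial resolving to `name`
    typo: str  # orthographic variant (1-char edit) of `name`
    region: str
    band_lo: int
    band_hi: int
    abundance: float


@dataclass
class RegionCommunity:
    region: str
    richness: np.ndarray  # per-band true richness (float, exact slopes)
    band_species: list  # per band (0-based), list of accepted names
    breakpoint_band: int


@dataclass
class Community:
    regions: dict
    species: dict  # accepted name -> SpeciesInfo
    n_bands: int


def _new_epithet(rng: np.random.Generator, used: set, salt: str) -> str:
    while True:
        ep = "".join(rng.choice(_SYLLABLES, size=3)) + salt + str(rng.choice(_SUFFIXES))
        if ep not in used:
            used.add(ep)
            return ep


def _typo(rng: np.random.Generator, epithet: str, used: set) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    for _ in range(50):
        i = int(rng.integers(1, len(epithet)))
        sub = letters[int(rng.integers(26))]
        cand = epithet[:i] + sub + epithet[i + 1:]
        if cand != epithet and cand not in used:
            used.add(cand)
            return cand
    return epithet + "x"  # pragma: no cover - practically unreachable


def generate_community(config: SyntheticConfig) -> Community:
    """Build the regional species pools realising the planted gradient.

    Species occupy contiguous band ranges. Scanning bands south→north, the
    active set grows by ``slope_below`` species per band up to the
    breakpoint and shrinks by ``|slope_above|`` beyond it, so the per-band
    richness follows the configured two-segment trajectory exactly (after
    integer rounding); extra turnover events (one retirement plus one
    recruitment) are spread across bands until the regional pool reaches
    ``n_species_per_region``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    richness = config.band_richness()
    target_counts = np.round(richness).astype(int)

    used_epithets: set = set()
    species: dict[str, SpeciesInfo] = {}
    regions: dict[str, RegionCommunity] = {}

    for region in config.regions:
        base_total = target_counts[0] + int(np.sum(np.clip(np.diff(target_counts), 0, None)))
        extra = max(0, config.n_species_per_region - base_total)
        turnover = np.zeros(config.n_bands, dtype=int)
        if extra:
            bands = rng.choice(np.arange(1, config.n_bands), size=extra)
            np.add.at(turnover, bands, 1)

        def make_species(band0: int) -> str:
            genus = str(rng.choice(GENERA))
            ep = _new_epithet(rng, used_epithets, config.name_salt)
            name = f"{genus} {ep}"
            syn_genus = str(rng.choice([g for g in GENERA if g != genus]))
            syn = f"{syn_genus} {_new_epithet(rng, used_epithets, config.name_salt)}"
            typo = f"{genus} {_typo(rng, ep, used_epithets)}"
            species[name] = SpeciesInfo(
                name=name, genus=genus, synonym=syn, typo=typo, region=region,
                band_lo=band0 + 1, band_hi=config.n_bands,
                abundance=float(rng.lognormal(0.0, 0.8)),
            )
            return name

        active = [make_species(0) for _ in range(target_counts[0])]
        band_species = [list(active)]
        for b in range(1, config.n_bands):
            target = target_counts[b]
            # net change first, then neutral turnover
            while len(active) < target:
                active.append(make_species(b))
            while len(active) > target:
                retiree = active.pop(int(rng.integers(len(active))))
                species[retiree].band_hi = b
            for _ in range(turnover[b]):
                if len(active) <= 1:
                    break
                retiree = active.pop(int(rng.integers(len(active))))
                species[retiree].band_hi = b
                active.append(make_species(b))
            band_species.append(list(active))
        regions[region] = RegionCommunity(
            region=region,
            richness=richness.copy(),
            band_species=band_species,
            breakpoint_band=config.breakpoint_band,
        )
    return Community(regions=regions, species=species, n_bands=config.n_bands)


# --------------------------------------------------------------------------
# records
# --------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Per-record planted-error ledger plus community-level truths."""

    records: pd.DataFrame
    per_cell: pd.DataFrame  # cellID, region, bandIndex, pool_richness, sampled_richness
    community: Community
    config: SyntheticConfig


ERROR_CLASSES = (
    "zero_coord", "integer_coord", "lat_eq_lon", "centroid", "country_mismatch",
    "missing_date", "invalid_date", "fossil", "genus_rank",
)

_REGION_LON = {
    "NorthAmerica": (-180.0, -30.0),
    "EuropeNAfrica": (-30.0, 60.0),
    "Asia": (60.0, 180.0),
}


def _sample_cells(config: SyntheticConfig, grid: StudyGrid, rng: np.random.Generator):
    """Pick the sampled cells (region, band, column) and their effort weights."""
    cells = []
    for region in config.regions:
        lon_lo, lon_hi = _REGION_LON[region]
        x_lo, _ = ease2.forward(lon_lo, 45.0)
        x_hi, _ = ease2.forward(lon_hi, 45.0)
        col_lo = int(np.ceil((float(x_lo) - grid.origin_x) / grid.cell_size_m))
        col_hi = int(np.floor((float(x_hi) - grid.origin_x) / grid.cell_size_m)) - 1
        pool = config.band_richness()
        for band in range(1, config.n_bands + 1):
            k = min(config.cells_per_band, col_hi - col_lo + 1)
            cols = rng.choice(np.arange(col_lo, col_hi + 1), size=k, replace=False)
            for col in cols:
                weight = (
                    np.round(pool[band - 1]) ** config.effort_richness_scaling
                    * rng.lognormal(0.0, config.effort_sigma)
                )
                cells.append((region, band, int(col), float(weight)))
    return cells


def generate_records(community: Community, config: SyntheticConfig):
    """Sample occurrence records from the community and plant the error classes.

    Returns ``(records, truth)``. Sampling effort is distributed over a
    fixed set of cells (``cells_per_band`` per band per region) with
    log-normal weights scaled by the band's species-pool size, mimicking
    spatially clustered effort. Error classes that rewrite the same
    coordinates (zero, integer, latitude=longitude, centroid) are mutually
    exclusive by a single categorical draw; all other classes are applied
    independently, so one record may carry several labels. Duplicate
    copies are planted on records that carry no error and have a complete
    duplicate key.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    grid = StudyGrid(n_bands=config.n_bands)
    cells = _sample_cells(config, grid, rng)
    weights = np.array([c[3] for c in cells])
    counts = rng.multinomial(config.n_records, weights / weights.sum())

    y_cap = float(ease2.forward(0.0, 89.0)[1])
    rows_region, rows_band, rows_col, rows_species = [], [], [], []
    xs, ys = [], []
    for (region, band, col, _w), n in zip(cells, counts):
        if n == 0:
            continue
        pool = community.regions[region].band_species[band - 1]
        ab = np.array([community.species[s].abundance for s in pool])
        chosen = rng.choice(pool, size=n, p=ab / ab.sum())
        x_lo = grid.origin_x + col * grid.cell_size_m
        y_lo = grid.origin_y + (band - 1) * grid.cell_size_m
        y_hi = min(y_lo + grid.cell_size_m, y_cap)
        xs.append(rng.uniform(x_lo, x_lo + grid.cell_size_m, size=n))
        ys.append(rng.uniform(y_lo, min(y_hi, y_cap), size=n))
        rows_region += [region] * n
        rows_band += [band] * n
        rows_col += [col] * n
        rows_species += list(chosen)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    lon, lat = ease2.inverse(x, y)
    # occurrence databases serve ≤ ~6 decimal places (≈ 0.1 m)
    lon, lat = np.round(lon, 6), np.round(lat, 6)
    n = len(lon)

    # keep clean coordinates clear of gazetteer radii (nudge east if close)
    gaz = default_gazetteer()
    from .geo import haversine_km

    for entry in gaz.entries.itertuples(index=False):
        near = haversine_km(lat, lon, entry.decimalLatitude, entry.decimalLongitude) <= (
            2.0 * entry.radius_km
        )
        lon = np.where(near, lon + 0.05, lon)

    species = np.array(rows_species, dtype=object)
    genus = np.array([community.species[s].genus for s in species], dtype=object)

    # --- temporal fields ------------------------------------------------
    years = rng.integers(config.year_range[0], config.year_range[1] + 1, size=n)
    months = rng.integers(1, 13, size=n)
    days = rng.integers(1, 29, size=n)
    event_date = np.array(
        [f"{yy:04d}-{mm:02d}-{dd:02d}" for yy, mm, dd in zip(years, months, days)],
        dtype=object,
    )
    year_col = years.astype(object)

    date_state = rng.choice(
        3, size=n,
        p=[1 - config.p_missing_date - config.p_invalid_date,
           config.p_missing_date, config.p_invalid_date],
    )
    missing_date = date_state == 1
    invalid_date = date_state == 2
    event_date[missing_date] = pd.NA
    year_col[missing_date] = None
    future = invalid_date & (rng.random(n) < 0.5)
    bad_month = invalid_date & ~future
    event_date[bad_month] = [f"{yy:04d}-13-02" for yy in years[bad_month]]
    event_date[future] = "2150-06-15"
    year_col[future] = 2150

    # --- coordinate error classes (mutually exclusive rewrites) ---------
    p_coord = [config.p_zero_coord, config.p_integer_coord, config.p_lat_eq_lon,
               config.p_centroid]
    coord_state = rng.choice(5, size=n, p=[1 - sum(p_coord), *p_coord])
    zero = coord_state == 1
    integer = coord_state == 2
    lat_eq_lon = coord_state == 3
    centroid = coord_state == 4

    lon = lon.copy()
    lat = lat.copy()
    lon[zero] = 0.0
    lat_r = np.round(lat)
    lon_r = np.round(lon)
    lon_r = np.where(lon_r == 0, 1.0, lon_r)
    lon_r = np.where(lat_r == lon_r, lon_r + 1.0, lon_r)
    lat[integer] = lat_r[integer]
    lon[integer] = lon_r[integer]
    lon[lat_eq_lon] = lat[lat_eq_lon]
    cents = country_centroids()
    cent_codes = rng.choice(_CODES, size=n)
    cent_lon = np.array([cents[c][0] for c in cent_codes])
    cent_lat = np.array([cents[c][1] for c in cent_codes])
    lon[centroid] = cent_lon[centroid]
    lat[centroid] = cent_lat[centroid]

    country = country_code_of(lon, lat)
    mismatch = rng.random(n) < config.p_country_mismatch
    # declare a country four slots away along the longitude tiling: always
    # far outside the 0.1° buffer of the true location
    true_idx = np.array([_CODES.index(c) if c is not None else 0 for c in country])
    wrong = np.array(_CODES, dtype=object)[(true_idx + 4) % len(_CODES)]
    country = np.where(mismatch, wrong, country)

    # --- basis, rank, names ---------------------------------------------
    basis_values = list(config.basis_mix)
    basis_p = np.array([config.basis_mix[b] for b in basis_values], dtype=float)
    basis = rng.choice(basis_values, size=n, p=basis_p / basis_p.sum())
    fossil = rng.random(n) < config.p_fossil
    basis = np.where(fossil, "FossilSpecimen", basis)

    genus_rank = rng.random(n) < config.p_genus_rank
    rank = np.full(n, "SPECIES", dtype=object)

    raw = species.astype(object).copy()
    u = rng.random(n)
    use_typo = u < config.p_typo
    use_syn = (~use_typo) & (u < config.p_typo + config.p_synonym)
    raw[use_typo] = [community.species[s].typo for s in species[use_typo]]
    raw[use_syn] = [community.species[s].synonym for s in species[use_syn]]
    infra = rng.random(n) < config.p_infraspecific
    infra_rank = rng.choice(["var.", "subsp.", "f."], size=n)
    rank_names = {"var.": "VARIETY", "subsp.": "SUBSPECIES", "f.": "FORM"}
    for i in np.flatnonzero(infra):
        ep = _SYLLABLES[int(rng.integers(len(_SYLLABLES)))] + str(rng.choice(_SUFFIXES))
        raw[i] = f"{raw[i]} {infra_rank[i]} {ep}"
        rank[i] = rank_names[infra_rank[i]]
    author = rng.random(n) < config.p_authority
    for i in np.flatnonzero(author):
        raw[i] = f"{raw[i]} {_AUTHORITIES[int(rng.integers(len(_AUTHORITIES)))]}"
    raw[genus_rank] = genus[genus_rank]
    rank[genus_rank] = "GENUS"

    collectors = np.array([f"Collector {i:03d}" for i in range(200)], dtype=object)
    recorded_by = rng.choice(collectors, size=n)
    dataset = rng.choice(["GBIF", "CNABH", "iDigBio", "BIEN"], size=n)

    record_id = np.array([f"s{config.seed}_{i:07d}" for i in range(n)], dtype=object)
    cell_id = np.array(
        [f"c{c:04d}b{b:02d}" for c, b in zip(rows_col, rows_band)], dtype=object
    )

    records = pd.DataFrame(
        {
            "recordID": record_id,
            "scientificName": raw,
            "decimalLatitude": lat,
            "decimalLongitude": lon,
            "countryCode": country,
            "eventDate": event_date,
            "year": pd.array([None if v is None else int(v) for v in year_col], dtype="Int64"),
            "basisOfRecord": basis,
            "recordedBy": recorded_by,
            "datasetName": dataset,
            "taxonRank": rank,
        }
    )
    truth = pd.DataFrame(
        {
            "recordID": record_id,
            "region": rows_region,
            "bandIndex": rows_band,
            "cellID": cell_id,
            "true_species": species,
            "zero_coord": zero,
            "integer_coord": integer,
            "lat_eq_lon": lat_eq_lon,
            "centroid": centroid,
            "country_mismatch": mismatch,
            "missing_date": missing_date,
            "invalid_date": invalid_date,
            "fossil": fossil,
            "genus_rank": genus_rank,
            "uses_synonym": use_syn,
            "uses_typo": use_typo,
            "is_duplicate_copy": np.zeros(n, dtype=bool),
            "duplicate_group": record_id.copy(),
        }
    )

    # --- duplicates ------------------------------------------------------
    clean = ~truth[list(ERROR_CLASSES)].any(axis=1)
    eligible = np.flatnonzero(clean.to_numpy() & ~missing_date)
    dup_mask = rng.random(len(eligible)) < config.duplicate_rate
    dup_idx = eligible[dup_mask]
    if len(dup_idx):
        copies = records.iloc[dup_idx].copy()
        tcopies = truth.iloc[dup_idx].copy()
        new_collector = rng.random(len(dup_idx)) < config.p_duplicate_new_collector
        alt = rng.choice(collectors, size=len(dup_idx))
        same = copies["recordedBy"].to_numpy(dtype=object)
        # a differing collector must actually differ
        alt = np.where(alt == same, collectors[(np.searchsorted(collectors, alt) + 1) % 200], alt)
        copies["recordedBy"] = np.where(new_collector, alt, same)
        copies["recordID"] = [f"s{config.seed}_d{i:07d}" for i in range(len(dup_idx))]
        tcopies["recordID"] = copies["recordID"].to_numpy()
        tcopies["is_duplicate_copy"] = True
        tcopies["duplicate_group"] = truth.iloc[dup_idx]["recordID"].to_numpy()
        records = pd.concat([records, copies], ignore_index=True)
        truth = pd.concat([truth, tcopies], ignore_index=True)

    per_cell = _per_cell_truth(truth, community, config)
    return records, GroundTruth(records=truth, per_cell=per_cell, community=community, config=config)


def _per_cell_truth(truth: pd.DataFrame, community: Community, config: SyntheticConfig):
    pool = {
        (region, b + 1): len(rc.band_species[b])
        for region, rc in community.regions.items()
        for b in range(config.n_bands)
    }
    grouped = truth.groupby(["cellID", "region", "bandIndex"])
    out = grouped["true_species"].nunique().rename("sampled_richness").reset_index()
    out["pool_richness"] = [
        pool[(r, b)] for r, b in zip(out["region"], out["bandIndex"])
    ]
    return out


def truth_summary(truth: GroundTruth) -> dict:
    """Planted counts per error class, per cell and per region (test oracle)."""
    ledger = truth.records
    classes = {c: int(ledger[c].sum()) for c in ERROR_CLASSES}
    classes["duplicate_copies"] = int(ledger["is_duplicate_copy"].sum())
    classes["duplicate_groups"] = int(ledger["duplicate_group"].nunique())
    per_cell = ledger.groupby("cellID")[list(ERROR_CLASSES)].sum().astype(int)
    per_region = ledger.groupby("region")[list(ERROR_CLASSES)].sum().astype(int)
    return {"classes": classes, "per_cell": per_cell, "per_region": per_region,
            "per_cell_richness": truth.per_cell}


# --------------------------------------------------------------------------
# taxon lookup tables
# --------------------------------------------------------------------------


def build_lookup_tables(community: Community, config: SyntheticConfig) -> dict:
    """Per-source synonymy lookups with configured coverage.

    For each source, a covered species contributes its accepted name, its
    synonym and (half the time) its orthographic variant; an uncovered
    species is either listed as unresolved or absent entirely. Coverage
    probabilities come from ``config.synonym_tables``.
    """
    rng = np.random.default_rng(config.seed + 2)
    lookups = {}
    for source, coverage in config.synonym_tables.items():
        entries: dict[str, tuple] = {}
        for name, info in sorted(community.species.items()):
            norm = normalise_name(name)[0]
            if rng.random() < coverage:
                entries[norm] = (norm, "accepted")
                entries[normalise_name(info.synonym)[0]] = (norm, "synonym")
                if rng.random() < 0.5:
                    entries[normalise_name(info.typo)[0]] = (norm, "synonym")
            elif rng.random() < 0.5:
                entries[norm] = (None, "unresolved")
        lookups[source] = TaxonLookup(source_label=source, entries=entries)
    return lookups


def write_lookup_tables(lookups: dict, outdir) -> None:
    outdir = Path(outdir)
    for source, lookup in lookups.items():
        rows = [
            {"raw_name": raw, "accepted_name": acc or "", "status": status,
             "source_label": source}
            for raw, (acc, status) in sorted(lookup.entries.items())
        ]
        pd.DataFrame(rows).to_csv(
            outdir / f"lookup_{source}.csv", index=False, lineterminator="\n"
        )


# --------------------------------------------------------------------------
# bundled world
# --------------------------------------------------------------------------


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    community: Community
    records: pd.DataFrame
    truth: GroundTruth
    lookups: dict
    gazetteer: Gazetteer
    countries: dict


def generate_world(config: SyntheticConfig | None = None) -> SyntheticWorld:
    """Generate a complete synthetic study system (records, truth, lookups, geography)."""
    config = config or SyntheticConfig()
    community = generate_community(config)
    records, truth = generate_records(community, config)
    lookups = build_lookup_tables(community, config)
    return SyntheticWorld(
        config=config,
        community=community,
        records=records,
        truth=truth,
        lookups=lookups,
        gazetteer=default_gazetteer(),
        countries=default_countries(),
    )


def generate_contrast_world(seed: int = 0, n_obs_records: int = 120_000,
                            n_specimen_records: int = 60_000) -> SyntheticWorld:
    """A world where record basis and gradient are confounded.

    Human-observation records follow a rich community peaking sharply at
    band 40, while preserved-specimen records follow a much poorer
    community peaking at band 29. The all-records richness is dominated by
    the observation component, so its fitted breakpoint sits at the
    northern peak (just south of band 40 — the specimen component adds a
    secondary kink at 29); restricting to preserved specimens moves the
    fitted peak to band 29. This is the qualitative phenomenon a
    curation-sensitivity analysis must detect. Error rates are zero so
    the contrast isolates the basis filter.
    """
    no_err = dict(
        p_zero_coord=0, p_integer_coord=0, p_lat_eq_lon=0, p_country_mismatch=0,
        p_centroid=0, p_missing_date=0, p_invalid_date=0, p_fossil=0, p_genus_rank=0,
        p_typo=0, effort_sigma=0.5,
    )
    cfg_obs = SyntheticConfig(
        seed=seed * 2 + 11, breakpoint_band=40, base_richness=8.0,
        slope_below=2.0, slope_above=-6.0, n_records=n_obs_records,
        basis_mix={"HumanObservation": 1.0}, name_salt="ob",
        n_species_per_region=1, **no_err,
    )
    # identical seed => both components sample the same grid cells, so every
    # cell mixes observation and specimen records; name_salt keeps pools apart
    cfg_spec = SyntheticConfig(
        seed=seed * 2 + 11, breakpoint_band=29, base_richness=3.0,
        slope_below=0.5, slope_above=-0.5, n_records=n_specimen_records,
        basis_mix={"PreservedSpecimen": 1.0}, name_salt="sp",
        n_species_per_region=1, **no_err,
    )
    w_obs = generate_world(cfg_obs)
    w_spec = generate_world(cfg_spec)
    records = pd.concat([w_obs.records, w_spec.records], ignore_index=True)
    ledger = pd.concat([w_obs.truth.records, w_spec.truth.records], ignore_index=True)
    per_cell = pd.concat([w_obs.truth.per_cell, w_spec.truth.per_cell], ignore_index=True)
    community = Community(
        regions={**{f"obs_{k}": v for k, v in w_obs.community.regions.items()},
                 **{f"spec_{k}": v for k, v in w_spec.community.regions.items()}},
        species={**w_obs.community.species, **w_spec.community.species},
        n_bands=cfg_obs.n_bands,
    )
    lookups = {
        source: TaxonLookup(
            source_label=source,
            entries={**w_obs.lookups[source].entries, **w_spec.lookups[source].entries},
        )
        for source in w_obs.lookups
    }
    truth = GroundTruth(records=ledger, per_cell=per_cell, community=community,
                        config=cfg_obs)
    return SyntheticWorld(
        config=cfg_obs, community=community, records=records, truth=truth,
        lookups=lookups, gazetteer=default_gazetteer(), countries=default_countries(),
    )


def write_world(world: SyntheticWorld, outdir) -> None:
    """Emit the world as plain-text files (occurrences, truth, lookups, geography)."""
    from .io import write_gazetteer, write_occurrences

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_occurrences(world.records, outdir / "occurrences.csv")
    world.truth.records.to_csv(outdir / "truth.csv", index=False, lineterminator="\n")
    world.truth.per_cell.to_csv(outdir / "truth_cells.csv", index=False, lineterminator="\n")
    write_lookup_tables(world.lookups, outdir)
    write_gazetteer(world.gazetteer, outdir / "gazetteer.csv")
    write_countries_geojson(outdir / "countries.geojson")
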