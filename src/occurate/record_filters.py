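"""Cleaning filters and named curation scenarios.

Two duplicate criteria (with and without the collector name in the key),
a basis-of-record filter (e.g. preserved specimens only) and five temporal
windows, composable into named "data curation scenarios" such as
``date-specim`` (preserved specimens only, then deduplication on species
name + coordinates + collection date). Every filter is contractive and
idempotent and returns a FilterReport; scenarios apply taxonomy selection,
then the basis filter, then the temporal filter, and deduplicate last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .geo import normalise_basis
from .report import FilterReport, split
from .taxonomy import apply_consensus, apply_source

#: Darwin-Core-ish aliases for duplicate-key components → canonical columns.
KEY_COLUMNS = {
    "species_name": "acceptedName",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "event_date": "eventDate",
    "recorded_by": "recordedBy",
}

MINIMUM_KEY = ("species_name", "latitude", "longitude", "event_date")


@dataclass(frozen=True)
class DuplicateKey:
    """Which record attributes must coincide for two records to be duplicates."""

    components: tuple = MINIMUM_KEY
    #: Decimal places to round coordinates to before comparison; None = exact.
    coordinate_precision: int | None = None
    #: Compare the raw rather than the standardised species name.
    use_raw_name: bool = False

    def __post_init__(self) -> None:
        missing = set(MINIMUM_KEY) - set(self.components)
        if missing:
            raise ValueError(f"duplicate key must include {sorted(missing)}")
        unknown = set(self.components) - set(KEY_COLUMNS)
        if unknown:
            raise ValueError(f"unknown duplicate-key components: {sorted(unknown)}")


def _key_frame(records: pd.DataFrame, key: DuplicateKey) -> pd.DataFrame:
    cols = {}
    for comp in key.components:
        col = KEY_COLUMNS[comp]
        if comp == "species_name" and key.use_raw_name:
            col = "scientificName"
        series = records[col]
        if comp in ("latitude", "longitude"):
            series = pd.to_numeric(series, errors="coerce")
            if key.coordinate_precision is not None:
                series = series.round(key.coordinate_precision)
            # canonical numeric formatting: exact decimal string equality
            series = series.map(lambda v: repr(float(v)) if pd.notna(v) else pd.NA)
        cols[comp] = series
    return pd.DataFrame(cols, index=records.index)


def dedupe(records: pd.DataFrame, key: DuplicateKey | None = None):
    """Keep one record per duplicate group (first in stable input order).

    A group is the set of records agreeing on every key component; any
    record missing a key component forms a singleton group and is never
    merged away.
    """
    key = key or DuplicateKey()
    kf = _key_frame(records, key)
    complete = kf.notna().all(axis=1)
    dup = pd.Series(False, index=records.index)
    dup.loc[complete] = kf.loc[complete].duplicated(keep="first")
    n_groups = int(complete.sum() - dup.sum()) + int((~complete).sum())
    return split(
        records,
        dup,
        "duplicates",
        details={"duplicate_groups": n_groups, "incomplete_key": int((~complete).sum())},
    )


def filter_basis(records: pd.DataFrame, allowed):
    """Keep records whose basisOfRecord is in ``allowed`` (format-insensitive)."""
    allowed_norm = {normalise_basis(a) for a in allowed}
    basis = records["basisOfRecord"].map(normalise_basis)
    return split(records, ~basis.isin(allowed_norm), "basis_of_record")


def filter_temporal(
    records: pd.DataFrame,
    min_year: int | None = None,
    max_year: int | None = None,
    require_year: bool = False,
):
    """Keep records inside a collection-year window.

    With ``require_year`` records lacking a year are removed; otherwise a
    record is removed only when its year is present and outside
    [min_year, max_year]. All the usual windows (≥1600 with required year,
    ≥1900, ≥1970, 1970–2000, ≥1990) are instances.
    """
    if min_year is not None and max_year is not None and min_year > max_year:
        raise ValueError(f"min_year {min_year} > max_year {max_year}")
    year = pd.to_numeric(records["year"], errors="coerce")
    out = pd.Series(False, index=records.index)
    if min_year is not None:
        out |= year < min_year
    if max_year is not None:
        out |= year > max_year
    out = out.fillna(False)
    if require_year:
        out |= year.isna()
    return split(records, out, "temporal")


@dataclass(frozen=True)
class CurationScenario:
    """A named combination of taxonomy source and cleaning filters."""

    name: str
    taxonomy_source: str = "consensus"  # "consensus" or a lookup source label
    basis_filter: frozenset | None = None
    min_year: int | None = None
    max_year: int | None = None
    require_year: bool = False
    duplicate_key: DuplicateKey = field(default_factory=DuplicateKey)


def default_scenarios() -> list[CurationScenario]:
    """The four standard curation scenarios.

    All deduplicate on species name + coordinates + collection date
    (collector excluded): date-TNRS uses the TNRS standardisation,
    date-cons the consensus checklist, date-specim restricts to preserved
    specimens, and date-1970 to records collected in 1970 or later.
    """
    return [
        CurationScenario(name="date-TNRS", taxonomy_source="TNRS"),
        CurationScenario(name="date-cons"),
        CurationScenario(name="date-specim", basis_filter=frozenset({"PreservedSpecimen"})),
        CurationScenario(name="date-1970", min_year=1970, require_year=True),
    ]


def apply_scenario(
    records: pd.DataFrame,
    scenario: CurationScenario,
    per_source_maps: dict,
    consensus,
):
    """Curate records under one scenario.

    Order: taxonomy selection → basis filter → temporal filter → dedupe
    (last, so duplicates differing only in excluded attributes are merged
    after the restriction). Returns ``(curated, reports)``.
    """
    reports: list[FilterReport] = []
    if scenario.taxonomy_source == "consensus":
        kept, _, rep = apply_consensus(records, per_source_maps, consensus)
    else:
        if scenario.taxonomy_source not in per_source_maps:
            raise ValueError(f"unknown taxonomy source: {scenario.taxonomy_source!r}")
        kept, _, rep = apply_source(records, per_source_maps[scenario.taxonomy_source])
    reports.append(rep)
    if scenario.basis_filter is not None:
        kept, _, rep = filter_basis(kept, scenario.basis_filter)
        reports.append(rep)
    if scenario.min_year is not None or scenario.max_year is not None or scenario.require_year:
        kept, _, rep = filter_temporal(
            kept, scenario.min_year, scenario.max_year, scenario.require_year
        )
        reports.append(rep)
    kept, _, rep = dedupe(kept, scenario.duplicate_key)
    reports.append(rep)
    return kept, reports


def discard_proportions(
    before: pd.DataFrame,
    after: pd.DataFrame,
    cell_col: str = "cellID",
    name_col: str = "acceptedName",
):
    """Per-cell proportions of records and of observed species discarded.

    Cells absent from ``after`` report 1.0; cells absent from ``before``
    are undefined and omitted. Returns a frame indexed by cell with
    ``prop_records`` and ``prop_species`` columns.
    """
    n_before = before.groupby(cell_col).size()
    s_before = before.groupby(cell_col)[name_col].nunique()
    n_after = after.groupby(cell_col).size().reindex(n_before.index, fill_value=0)
    s_after = after.groupby(cell_col)[name_col].nunique().reindex(n_before.index, fill_value=0)
    out = pd.DataFrame(
        {
            "prop_records": 1.0 - n_after / n_before,
            "prop_species": 1.0 - s_after / s_before,
        }
    )
    out.index.name = cell_col
    return out
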