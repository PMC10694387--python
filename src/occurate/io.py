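"""Reading and writing occurrence tables, taxon lookups and gazetteers.

The canonical in-memory container is a :class:`pandas.DataFrame` whose
columns carry Darwin Core terms (``scientificName``, ``decimalLatitude``,
``decimalLongitude``, ``countryCode``, ``eventDate``, ``year``,
``basisOfRecord``, ``recordedBy``, ``datasetName``, ``taxonRank``) plus an
opaque ``recordID``. Source-specific column dialects are mapped onto this
schema through an explicit ``field_map`` at read time.

Files are CSV or TSV, UTF-8, header row, RFC-4180 quoting. Missing values
are empty fields. Coordinates are decimal degrees (WGS 84); unparseable
numbers become missing and are flagged in the read report, never silently
dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical occurrence columns, in on-disk order.
RECORD_COLUMNS = [
    "recordID",
    "scientificName",
    "decimalLatitude",
    "decimalLongitude",
    "countryCode",
    "eventDate",
    "year",
    "basisOfRecord",
    "recordedBy",
    "datasetName",
    "taxonRank",
]

#: Fields the field_map must cover at minimum.
MANDATORY_FIELDS = ("scientificName", "decimalLatitude", "decimalLongitude")

LOOKUP_STATUSES = {"accepted", "synonym", "unresolved", "no_match"}

GAZETTEER_KINDS = {"country_centroid", "institution", "repository_hq"}


class ConfigurationError(ValueError):
    """A read was requested with an unusable column mapping or file."""


@dataclass
class ReadReport:
    """Row accounting for one file read: rows_in = rows_clean + rows_flagged."""

    path: str
    rows_in: int = 0
    rows_clean: int = 0
    rows_flagged: int = 0
    flags: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


@dataclass
class Gazetteer:
    """Problematic reference locations (country centroids, institutions, …)."""

    entries: pd.DataFrame  # columns: label, decimalLatitude, decimalLongitude, radius_km, kind

    def __post_init__(self) -> None:
        required = {"label", "decimalLatitude", "decimalLongitude", "radius_km", "kind"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ConfigurationError(f"gazetteer missing columns: {sorted(missing)}")
        if (self.entries["radius_km"] <= 0).any():
            bad = self.entries.loc[self.entries["radius_km"] <= 0, "label"].tolist()
            raise ConfigurationError(f"gazetteer radius_km must be > 0: {bad}")
        unknown = set(self.entries["kind"]) - GAZETTEER_KINDS
        if unknown:
            raise ConfigurationError(f"unknown gazetteer kinds: {sorted(unknown)}")


def _sniff_delimiter(path: Path) -> str:
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    with open(path, newline="", encoding="utf-8") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def read_occurrences(path, field_map=None, delimiter=None):
    """Read an occurrence table into the canonical frame.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.
    field_map
        Mapping from file column name to canonical field name. Unmapped
        canonical columns present in the file are taken as-is; columns not
        in the schema are ignored. ``None`` means identity.
    delimiter
        Forced delimiter; by default inferred from the extension/content.

    Returns
    -------
    (DataFrame, ReadReport)
        Frame with canonical columns and parsed types, plus row accounting.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delimiter = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, encoding="utf-8")
    report = ReadReport(path=str(path), rows_in=len(raw))

    if field_map:
        missing = [c for c in field_map if c not in raw.columns]
        if missing:
            raise ConfigurationError(f"mapped columns absent from {path.name}: {missing}")
        raw = raw.rename(columns=dict(field_map))
    absent = [f for f in MANDATORY_FIELDS if f not in raw.columns]
    if absent:
        raise ConfigurationError(f"mandatory fields unmapped in {path.name}: {absent}")

    df = pd.DataFrame(index=raw.index)
    for col in RECORD_COLUMNS:
        df[col] = raw[col] if col in raw.columns else ""
    df = df.replace("", pd.NA)

    def _parse_float(v):
        # python float() is correctly rounded; pandas' fast parser can be
        # off by one ulp, which would break byte-stable round-trips
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    flagged = np.zeros(len(df), dtype=bool)
    for col in ("decimalLatitude", "decimalLongitude"):
        present = df[col].notna()
        parsed = df[col].map(_parse_float).astype(float)
        bad = present & parsed.isna()
        if bad.any():
            report.flags[f"unparseable_{col}"] = int(bad.sum())
            flagged |= bad.to_numpy()
        df[col] = parsed
    out_of_range = (df["decimalLatitude"].abs() > 90) | (df["decimalLongitude"].abs() > 180)
    out_of_range = out_of_range.fillna(False)
    if out_of_range.any():
        report.flags["coordinate_out_of_range"] = int(out_of_range.sum())
        flagged |= out_of_range.to_numpy()

    present_year = df["year"].notna()
    year = pd.to_numeric(df["year"], errors="coerce")
    bad_year = present_year & year.isna()
    if bad_year.any():
        report.flags["unparseable_year"] = int(bad_year.sum())
        flagged |= bad_year.to_numpy()
    df["year"] = year.astype("Int64")

    # year should equal the year component of eventDate when both present
    date_year = pd.to_numeric(
        df["eventDate"].str.extract(r"^(\d{4})", expand=False), errors="coerce"
    ).astype("Int64")
    mismatch = df["year"].notna() & date_year.notna() & (df["year"] != date_year)
    if mismatch.any():
        report.flags["year_eventDate_mismatch"] = int(mismatch.sum())
        flagged |= mismatch.to_numpy()

    if df["recordID"].isna().all():
        df["recordID"] = [f"r{i:07d}" for i in range(len(df))]
    elif df["recordID"].duplicated().any():
        dupes = df.loc[df["recordID"].duplicated(), "recordID"].unique()[:5].tolist()
        raise ConfigurationError(f"recordID not unique in {path.name}: {dupes} …")

    report.rows_flagged = int(flagged.sum())
    report.rows_clean = report.rows_in - report.rows_flagged
    if report.rows_in == 0:
        report.warnings.append("empty file: no data rows")
    return df, report


def write_occurrences(records: pd.DataFrame, path) -> None:
    """Write the canonical occurrence CSV (round-trips with read_occurrences)."""
    path = Path(path)
    out = records.reindex(columns=RECORD_COLUMNS)
    out.to_csv(
        path,
        index=False,
        na_rep="",
        lineterminator="\n",
        quoting=csv.QUOTE_MINIMAL,
        encoding="utf-8",
    )


def read_taxon_lookup(path, source_label=None, match_policy="exact", max_distance=1):
    """Load one raw-name → accepted-name synonymy table.

    The CSV needs columns ``raw_name``, ``accepted_name``, ``status``
    (accepted | synonym | unresolved | no_match) and optionally
    ``source_label``. Raw names are normalised to binomials on load;
    duplicate raw names pointing at different accepted names are rejected.
    """
    from .taxonomy import TaxonLookup, normalise_name

    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    required = {"raw_name", "accepted_name", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"taxon lookup {path.name} missing columns: {sorted(missing)}")
    bad_status = set(df["status"]) - LOOKUP_STATUSES
    if bad_status:
        raise ConfigurationError(f"unknown statuses in {path.name}: {sorted(bad_status)}")
    if source_label is None:
        source_label = (
            df["source_label"].iloc[0] if "source_label" in df.columns and len(df) else path.stem
        )

    entries: dict[str, tuple[str | None, str]] = {}
    conflicts = []
    for row in df.itertuples(index=False):
        key, _ = normalise_name(row.raw_name)
        accepted = normalise_name(row.accepted_name)[0] if row.accepted_name else None
        value = (accepted, row.status)
        if key in entries and entries[key] != value:
            conflicts.append(row.raw_name)
            continue
        entries[key] = value
    if conflicts:
        raise ConfigurationError(
            f"conflicting duplicate raw names in {path.name}: {sorted(set(conflicts))}"
        )
    return TaxonLookup(
        source_label=source_label,
        entries=entries,
        match_policy=match_policy,
        max_distance=max_distance,
    )


def read_gazetteer(path) -> Gazetteer:
    """Load a gazetteer CSV (label, decimalLatitude, decimalLongitude, radius_km, kind)."""
    df = pd.read_csv(path, encoding="utf-8")
    rename = {"lat": "decimalLatitude", "lon": "decimalLongitude"}
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    return Gazetteer(entries=df)


def write_gazetteer(gaz: Gazetteer, path) -> None:
    gaz.entries.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
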