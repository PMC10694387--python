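"""Taxonomic standardisation and multi-source consensus.

Raw name strings are normalised to bare binomials (genus + specific
epithet, authorship and infraspecific ranks stripped), resolved against
several offline synonymy lookup tables, and combined into a consensus
checklist containing the accepted names endorsed by at least ``min_votes``
of the sources (majority vote, default 3 of 5). Records whose raw name
reaches no consensus member are dropped from the consensus dataset.

Fuzzy matching (edit distance, via edlib) is off by default: offline
standardisation should be conservative, and spelling-tolerant resolution
is a property of the individual reference services, not of the vote.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .report import FilterReport

#: Infraspecific rank markers that terminate the epithet scan.
RANK_MARKERS = {
    "var",
    "var.",
    "subsp",
    "subsp.",
    "ssp",
    "ssp.",
    "f",
    "f.",
    "fo.",
    "forma",
    "cf.",
    "aff.",
}

_EPITHET_RE = re.compile(r"^[a-zA-Z][a-zA-Z-]*$")


class ConsensusConfigError(ValueError):
    pass


def normalise_name(raw: str) -> tuple[str, bool]:
    """Reduce a raw scientific name to ``Genus epithet``.

    Strips authorship strings, infraspecific epithets and rank markers,
    collapses whitespace and normalises case. Returns ``(binomial,
    is_uninomial)``; uninomial inputs come back as the capitalised genus
    with the flag set.

    >>> normalise_name("Bryum argenteum var. lanatum (P.Beauv.) Hampe")
    ('Bryum argenteum', False)
    """
    tokens = str(raw).strip().split()
    if not tokens:
        return "", True
    genus = tokens[0].capitalize()
    if len(tokens) < 2:
        return genus, True
    cand = tokens[1]
    # The epithet is a purely alphabetic lower- (or upper-) case token;
    # capitalised or dotted second tokens are authorship, rank markers stop.
    if (
        cand.lower() in RANK_MARKERS
        or not _EPITHET_RE.match(cand)
        or not (cand.islower() or cand.isupper())
    ):
        return genus, True
    return f"{genus} {cand.lower()}", False


@dataclass
class TaxonLookup:
    """One source's raw-name → accepted-name map (keys are normalised binomials)."""

    source_label: str
    entries: dict  # normalised raw name -> (accepted binomial or None, status)
    match_policy: str = "exact"  # "exact" | "fuzzy"
    max_distance: int = 1

    def accepted_names(self) -> set:
        """The source's list of accepted binomials (its checklist)."""
        return {
            acc
            for acc, status in self.entries.values()
            if acc and status in ("accepted", "synonym")
        }


def standardise(raw_names, lookup: TaxonLookup) -> dict:
    """Resolve raw names against one lookup.

    Returns ``{raw_name: (accepted binomial or None, status)}``. Exact match
    on the normalised binomial first; under the ``fuzzy`` policy, a unique
    nearest key within ``max_distance`` edits matches, ties are returned as
    ``unresolved``, and anything farther is ``no_match``.
    """
    out = {}
    keys = list(lookup.entries)
    for raw in raw_names:
        norm, _uninomial = normalise_name(raw)
        if norm in lookup.entries:
            out[raw] = lookup.entries[norm]
            continue
        if lookup.match_policy == "fuzzy" and norm:
            best, best_d, ties = None, lookup.max_distance + 1, 0
            for key in keys:
                d = edlib.align(norm, key, k=lookup.max_distance)["editDistance"]
                if d < 0:
                    continue
                if d < best_d:
                    best, best_d, ties = key, d, 1
                elif d == best_d:
                    ties += 1
            if best is not None and ties == 1:
                out[raw] = lookup.entries[best]
                continue
            if best is not None:
                out[raw] = (None, "unresolved")  # ambiguous neighbours
                continue
        out[raw] = (None, "no_match")
    return out


@dataclass
class ConsensusList:
    """Accepted names endorsed by at least ``min_votes`` sources."""

    accepted_names: set
    votes: dict = field(default_factory=dict)
    min_votes: int = 3

    def __contains__(self, name: str) -> bool:
        return name in self.accepted_names


def build_consensus(per_source_maps: dict, min_votes: int = 3) -> ConsensusList:
    """Vote accepted binomials across sources.

    ``per_source_maps`` maps source label → standardisation map (the output
    of :func:`standardise`). A name gets one vote from each source whose
    accepted-name list contains it, regardless of the synonym path;
    unresolved / no_match entries contribute nothing.
    """
    if len(per_source_maps) < min_votes:
        raise ConsensusConfigError(
            f"{len(per_source_maps)} sources cannot reach min_votes={min_votes}"
        )
    votes: dict[str, int] = {}
    for smap in per_source_maps.values():
        names = {acc for acc, status in smap.values() if acc and status in ("accepted", "synonym")}
        for name in names:
            votes[name] = votes.get(name, 0) + 1
    members = {n for n, v in votes.items() if v >= min_votes}
    return ConsensusList(accepted_names=members, votes=votes, min_votes=min_votes)


def resolve_names(raw_names, per_source_maps: dict, consensus: ConsensusList) -> tuple[dict, set]:
    """Choose one consensus member per raw name by per-source majority.

    Returns ``(mapping raw → accepted, tied raw names)``; raw names with no
    consensus candidate are absent from the mapping. Ties break to the
    lexicographically first candidate and are flagged.
    """
    mapping, tied = {}, set()
    for raw in raw_names:
        counts: dict[str, int] = {}
        for smap in per_source_maps.values():
            acc, status = smap.get(raw, (None, "no_match"))
            if acc and status in ("accepted", "synonym") and acc in consensus:
                counts[acc] = counts.get(acc, 0) + 1
        if not counts:
            continue
        top = max(counts.values())
        winners = sorted(n for n, c in counts.items() if c == top)
        if len(winners) > 1:
            tied.add(raw)
        mapping[raw] = winners[0]
    return mapping, tied


def apply_consensus(
    records: pd.DataFrame,
    per_source_maps: dict,
    consensus: ConsensusList,
    name_col: str = "scientificName",
):
    """Annotate records with the consensus accepted name (the taxConsensus set).

    Records whose raw name resolves to no consensus member are removed.
    Returns ``(kept, removed, FilterReport)``; kept rows gain an
    ``acceptedName`` column.
    """
    raw_names = records[name_col].dropna().unique()
    mapping, tied = resolve_names(raw_names, per_source_maps, consensus)
    accepted = records[name_col].map(mapping)
    kept = records.loc[accepted.notna()].copy()
    kept["acceptedName"] = accepted.loc[kept.index]
    removed = records.loc[accepted.isna()]
    report = FilterReport(
        name="taxonomy_consensus",
        n_in=len(records),
        n_kept=len(kept),
        n_removed=len(removed),
        details={"tied_raw_names": len(tied)},
    )
    return kept, removed, report


def apply_source(
    records: pd.DataFrame,
    source_map: dict,
    name_col: str = "scientificName",
):
    """Annotate records with a single source's accepted name, dropping failures."""
    mapping = {
        raw: acc
        for raw, (acc, status) in source_map.items()
        if acc and status in ("accepted", "synonym")
    }
    accepted = records[name_col].map(mapping)
    kept = records.loc[accepted.notna()].copy()
    kept["acceptedName"] = accepted.loc[kept.index]
    removed = records.loc[accepted.isna()]
    report = FilterReport(
        name="taxonomy_source", n_in=len(records), n_kept=len(kept), n_removed=len(removed)
    )
    return kept, removed, report


def cell_richness_delta(
    records_source: pd.DataFrame,
    records_consensus: pd.DataFrame,
    cell_col: str = "cellID",
    name_col: str = "acceptedName",
    region_col: str = "region",
):
    """Per-cell richness change of one standardisation source vs the consensus.

    Each cell is classed I (source richness above consensus), D (below) or
    E (equal); a cell present in only one dataset counts richness 0 in the
    other. Returns ``(delta table, per-region I/D/E proportions)``.
    """
    rich_s = records_source.groupby(cell_col)[name_col].nunique()
    rich_c = records_consensus.groupby(cell_col)[name_col].nunique()
    cells = rich_s.index.union(rich_c.index)
    delta = pd.DataFrame(
        {
            "richness_source": rich_s.reindex(cells, fill_value=0).astype(int),
            "richness_consensus": rich_c.reindex(cells, fill_value=0).astype(int),
        }
    )
    delta.index.name = cell_col
    delta["klass"] = "E"
    delta.loc[delta["richness_source"] > delta["richness_consensus"], "klass"] = "I"
    delta.loc[delta["richness_source"] < delta["richness_consensus"], "klass"] = "D"

    regions = (
        pd.concat([records_source[[cell_col, region_col]], records_consensus[[cell_col, region_col]]])
        .drop_duplicates(cell_col)
        .set_index(cell_col)[region_col]
    )
    delta["region"] = regions.reindex(cells)
    props = (
        delta.groupby("region")["klass"]
        .value_counts(normalize=True)
        .rename("proportion")
        .reset_index()
    )
    return delta.reset_index(), props
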