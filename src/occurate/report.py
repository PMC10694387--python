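"""Filter accounting shared by the preprocessing and curation stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class FilterReport:
    """One filter's row accounting. Invariant: n_in = n_kept + n_removed."""

    name: str
    n_in: int
    n_kept: int
    n_removed: int
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_in == self.n_kept + self.n_removed, self

    def as_dict(self) -> dict:
        return {
            "filter": self.name,
            "n_in": self.n_in,
            "n_kept": self.n_kept,
            "n_removed": self.n_removed,
            **{f"n_{k}": v for k, v in self.details.items()},
        }


def split(records: pd.DataFrame, remove_mask, name: str, details: dict | None = None):
    """Partition `records` by a boolean removal mask into (kept, removed, report)."""
    remove_mask = remove_mask.fillna(False) if hasattr(remove_mask, "fillna") else remove_mask
    removed = records.loc[remove_mask]
    kept = records.loc[~remove_mask]
    report = FilterReport(
        name=name,
        n_in=len(records),
        n_kept=len(kept),
        n_removed=len(removed),
        details=details or {},
    )
    return kept, removed, report


def reports_frame(reports) -> pd.DataFrame:
    """Stack FilterReports into a tidy accounting table."""
    return pd.DataFrame([r.as_dict() for r in reports])
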