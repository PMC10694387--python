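"""Latitudinal richness gradients and breakpoint (segmented) regression.

Well-sampled cells are summarised into latitudinal bands (median observed
and predicted richness per band) and each band series is fitted with a
single-breakpoint piecewise linear model

    y = β0 + β1·x + β2·(x − ψ)·1[x > ψ],

where the breakpoint ψ is read as the latitude of peak species richness.
ψ is estimated by exhaustive SSE profiling over a grid of candidate
positions (deterministic and global, unlike iterative linearisation);
for each candidate the remaining coefficients are ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def band_series(
    cell_metrics: pd.DataFrame,
    region: str | None = None,
    scenario: str = "",
    band_col: str = "bandIndex",
) -> pd.DataFrame:
    """Per-band medians of observed and predicted richness over well-sampled cells.

    ``region=None`` pools all regions ("all"). Bands with no well-sampled
    cell are omitted (they carry no information for the fit).
    """
    sel = cell_metrics.loc[cell_metrics["well_sampled"]]
    if region is not None:
        sel = sel.loc[sel["region"] == region]
    grouped = sel.groupby(band_col)
    out = pd.DataFrame(
        {
            "n_cells": grouped.size(),
            "median_observed": grouped["s_obs"].median(),
            "median_predicted": grouped["predicted_richness"].median(),
            "observed_min": grouped["s_obs"].min(),
            "observed_max": grouped["s_obs"].max(),
        }
    ).reset_index()
    out.insert(0, "region", region or "all")
    out.insert(0, "scenario", scenario)
    return out


@dataclass
class BreakpointFit:
    """A fitted single-breakpoint segmented regression."""

    psi: float
    beta0: float
    beta1: float
    beta2: float
    r_squared: float
    sse: float
    degenerate: bool = False

    @property
    def slope_below(self) -> float:
        return self.beta1

    @property
    def slope_above(self) -> float:
        return self.beta1 + self.beta2


def _ols_sse(design: np.ndarray, y: np.ndarray):
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid @ resid)


def fit_piecewise(x, y, grid_step: float = 0.25) -> BreakpointFit:
    """Fit the segmented model by profiling candidate breakpoints.

    Candidates run over the interior of the x-range at ``grid_step``
    spacing; the ψ minimising SSE wins. The fit is flagged degenerate when
    fewer than 5 distinct x values are available or when the breakpoint
    improves on the single straight line by less than 1e-9 relative SSE
    (e.g. exactly collinear data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for a segmented fit")
    order = np.argsort(x)
    x, y = x[order], y[order]

    line_coef, line_sse = _ols_sse(np.column_stack([np.ones_like(x), x]), y)
    few_x = len(np.unique(x)) < 5

    lo, hi = x.min(), x.max()
    candidates = np.arange(lo + grid_step, hi - grid_step / 2, grid_step)
    best = None
    for psi in candidates:
        hinge = np.where(x > psi, x - psi, 0.0)
        if not hinge.any():
            continue
        coef, sse = _ols_sse(np.column_stack([np.ones_like(x), x, hinge]), y)
        if best is None or sse < best[1] - 1e-15:
            best = (psi, sse, coef)
    if best is None:
        return BreakpointFit(np.nan, line_coef[0], line_coef[1], 0.0,
                             _r2(y, line_sse), line_sse, degenerate=True)

    psi, sse, coef = best
    rel_gain = (line_sse - sse) / line_sse if line_sse > 0 else 0.0
    degenerate = few_x or rel_gain < 1e-9
    if degenerate and rel_gain < 1e-9:
        return BreakpointFit(np.nan, line_coef[0], line_coef[1], 0.0,
                             _r2(y, line_sse), line_sse, degenerate=True)
    return BreakpointFit(
        psi=float(psi),
        beta0=float(coef[0]),
        beta1=float(coef[1]),
        beta2=float(coef[2]),
        r_squared=_r2(y, sse),
        sse=sse,
        degenerate=degenerate,
    )


def _r2(y: np.ndarray, sse: float) -> float:
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - sse / tss if tss > 0 else 0.0


def fit_band_series(series: pd.DataFrame, value_col: str, grid_step: float = 0.25) -> BreakpointFit:
    """Fit the segmented model to one band series column (band index as x)."""
    return fit_piecewise(series["bandIndex"], series[value_col], grid_step=grid_step)


def scenario_comparison(fits: dict, shift_threshold: float = 2.0) -> pd.DataFrame:
    """Tabulate breakpoints across scenarios and flag shifted pairs.

    ``fits`` maps (scenario, region) → dict with keys ``observed`` and
    ``predicted`` (BreakpointFit) and ``n_cells``. Within each region,
    scenario pairs whose observed breakpoints differ by more than
    ``shift_threshold`` bands are listed in the ``shifted_vs`` column.
    """
    rows = []
    for (scenario, region), entry in fits.items():
        obs, pred = entry.get("observed"), entry.get("predicted")
        rows.append(
            {
                "scenario": scenario,
                "region": region,
                "bp_observed": obs.psi if obs else np.nan,
                "bp_predicted": pred.psi if pred else np.nan,
                "r2_observed": obs.r_squared if obs else np.nan,
                "r2_predicted": pred.r_squared if pred else np.nan,
                "n_cells": entry.get("n_cells", np.nan),
            }
        )
    table = pd.DataFrame(rows)
    shifted = []
    for _, row in table.iterrows():
        others = table.loc[(table["region"] == row["region"]) & (table["scenario"] != row["scenario"])]
        names = [
            o["scenario"]
            for _, o in others.iterrows()
            if np.isfinite(row["bp_observed"])
            and np.isfinite(o["bp_observed"])
            and abs(row["bp_observed"] - o["bp_observed"]) > shift_threshold
        ]
        shifted.append(",".join(sorted(names)))
    table["shifted_vs"] = shifted
    return table
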