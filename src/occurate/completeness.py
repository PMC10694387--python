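"""Per-cell inventory completeness from species accumulation curves.

The number of records in a cell proxies survey effort. For each cell we
build the analytic (individual-based, "exact") rarefaction curve

    E[S(m)] = S_obs − Σ_i C(N − N_i, m) / C(N, m),

the expected species count in a random subsample of m of the cell's N
records, where N_i is the record count of species i. The curve is fitted
with the rational function S(m) = (a + b·m)/(1 + c·m), whose asymptote
b/c estimates the cell's true richness; completeness is the observed
richness as a percentage of that asymptote. The slope of the last stretch
of the exact curve (species gained per additional record) measures how
fast the inventory is still growing.

A cell is well-sampled when it has at least 100 records, completeness
≥ 70%, a records/richness ratio ≥ 5 and a terminal slope ≤ 0.1 (one new
species per 10 further records), all boundaries inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln


def _as_counts(species_counts) -> np.ndarray:
    if isinstance(species_counts, dict):
        counts = np.asarray(list(species_counts.values()), dtype=float)
    else:
        counts = np.asarray(species_counts, dtype=float)
    if counts.size and counts.min() < 1:
        raise ValueError("species counts must be ≥ 1")
    return counts


def rarefaction_exact(species_counts, m):
    """Expected richness E[S(m)] in a random subsample of m records.

    Hypergeometric expectation evaluated in log-space (cancellation-safe
    for large N). ``species_counts`` is a mapping or array of per-species
    record counts; ``m`` may be a scalar or array with 0 ≤ m ≤ N.
    """
    counts = _as_counts(species_counts)
    n = counts.sum()
    m_arr = np.atleast_1d(np.asarray(m, dtype=float))
    if (m_arr < 0).any() or (m_arr > n).any():
        raise ValueError(f"subsample size must lie in [0, N={int(n)}]")
    s_obs = counts.size
    # log C(N-Ni, m) - log C(N, m); the term vanishes when m > N - Ni
    rem = n - counts  # records not of species i
    mm = m_arr[:, None]
    with np.errstate(invalid="ignore"):
        log_term = (
            gammaln(rem + 1)
            - gammaln(rem - mm + 1)
            + gammaln(n - mm + 1)
            - gammaln(n + 1)
        )
    term = np.where(mm <= rem[None, :], np.exp(log_term), 0.0)
    es = s_obs - term.sum(axis=1)
    es = np.where(m_arr == 0, 0.0, es)
    return float(es[0]) if np.isscalar(m) or np.asarray(m).ndim == 0 else es


@dataclass
class SacCurve:
    """An exact species accumulation curve: E[S(m)] at increasing subsample sizes."""

    m: np.ndarray
    expected_species: np.ndarray
    s_obs: int
    n_records: int


def build_sac(species_counts, n_points: int | None = None) -> SacCurve:
    """Evaluate the exact rarefaction curve at up to ``n_points`` subsample sizes.

    Points are integer m spanning 1..N (always including both ends),
    default ``min(N, 100)`` evenly spaced.
    """
    counts = _as_counts(species_counts)
    n = int(counts.sum())
    if n < 1:
        raise ValueError("empty inventory")
    n_points = n_points or min(n, 100)
    m = np.unique(np.round(np.linspace(1, n, min(n_points, n))).astype(int))
    es = rarefaction_exact(counts, m)
    return SacCurve(m=m, expected_species=np.atleast_1d(es), s_obs=counts.size, n_records=n)


@dataclass
class RationalFit:
    """Least-squares fit of S(m) = (a + b·m)/(1 + c·m) to an accumulation curve."""

    a: float
    b: float
    c: float
    asymptote: float
    completeness_pct: float
    flag: str | None = None  # None | "flat" | "capped" | "unusable"

    @property
    def usable(self) -> bool:
        return self.flag != "unusable"


def fit_rational(curve: SacCurve) -> RationalFit:
    """Fit the rational saturation model and derive completeness.

    Solved deterministically (no random initialisation): Levenberg–
    Marquardt from a geometric start (initial slope of the curve, asymptote
    just above the curve maximum), with the rearranged linear solve
    S + c·m·S = a + b·m as an alternative start; the converged solution
    with the lower SSE and a finite asymptote wins. A flat curve means the
    inventory stopped growing — completeness 100%. A fitted asymptote
    below S_obs is capped at 100% and flagged; no admissible solution
    (c ≤ 0, i.e. no finite asymptote) flags the fit unusable.
    """
    from scipy.optimize import least_squares

    m = curve.m.astype(float)
    s = curve.expected_species.astype(float)
    if s.max() - s.min() < 1e-9:
        return RationalFit(
            a=float(s[-1]), b=0.0, c=0.0, asymptote=float(s[-1]),
            completeness_pct=100.0, flag="flat",
        )
    if len(m) < 3:
        return RationalFit(np.nan, np.nan, np.nan, np.nan, np.nan, flag="unusable")

    def residual(p):
        return (p[0] + p[1] * m) / (1.0 + p[2] * m) - s

    b0 = s[0] / m[0]
    starts = [np.array([0.0, b0, b0 / (1.05 * s.max())])]
    design = np.column_stack([np.ones_like(m), m, -m * s])
    lin, _, rank, _ = np.linalg.lstsq(design, s, rcond=None)
    if rank == 3 and np.all(np.isfinite(lin)) and lin[2] > 0:
        starts.append(lin)
    best = None
    for p0 in starts:
        try:
            res = least_squares(residual, p0, method="lm", max_nfev=500)
        except Exception:  # pragma: no cover - defensive
            continue
        if not np.all(np.isfinite(res.x)) or res.x[2] <= 0:
            continue
        sse = float(res.fun @ res.fun)
        if best is None or sse < best[0]:
            best = (sse, res.x)
    if best is None:
        return RationalFit(np.nan, np.nan, np.nan, np.nan, np.nan, flag="unusable")
    a, b, c = best[1]
    asymptote = b / c
    completeness = 100.0 * curve.s_obs / asymptote
    flag = None
    if asymptote < curve.s_obs:
        completeness, flag = 100.0, "capped"
    return RationalFit(float(a), float(b), float(c), float(asymptote), float(completeness), flag)


def terminal_slope(curve: SacCurve, tail_fraction: float = 0.1) -> float:
    """Least-squares slope (species per record) over the curve's last stretch.

    The window is the final ``tail_fraction`` of the m-range, widened to at
    least the last two points.
    """
    m = curve.m.astype(float)
    s = curve.expected_species.astype(float)
    if len(m) < 2:
        return 0.0
    cut = m[-1] - tail_fraction * (m[-1] - m[0])
    sel = m >= cut
    if sel.sum() < 2:
        sel = np.zeros_like(sel)
        sel[-2:] = True
    return float(np.polyfit(m[sel], s[sel], 1)[0])


@dataclass
class WellSampledThresholds:
    """Survey-quality thresholds for well-sampled cells (all inclusive)."""

    min_records: int = 100
    min_completeness_pct: float = 70.0
    min_ratio: float = 5.0
    max_slope: float = 0.1

    def __post_init__(self) -> None:
        if min(self.min_records, self.min_completeness_pct, self.min_ratio, self.max_slope) <= 0:
            raise ValueError("thresholds must be positive")


def classify_well_sampled(
    metrics: pd.DataFrame, thresholds: WellSampledThresholds | None = None
) -> pd.DataFrame:
    """Apply the four survey-quality criteria; adds pass flags and the 0–4 count."""
    t = thresholds or WellSampledThresholds()
    out = metrics.copy()
    out["pass_records"] = out["n_records"] >= t.min_records
    out["pass_completeness"] = out["completeness_pct"] >= t.min_completeness_pct
    out["pass_ratio"] = out["ratio"] >= t.min_ratio
    out["pass_slope"] = out["slope"] <= t.max_slope
    passes = out[["pass_records", "pass_completeness", "pass_ratio", "pass_slope"]].fillna(False)
    out["criteria_passed"] = passes.sum(axis=1).astype(int)
    out["well_sampled"] = passes.all(axis=1)
    return out


def cell_metrics(
    records: pd.DataFrame,
    cell_col: str = "cellID",
    name_col: str = "acceptedName",
    thresholds: WellSampledThresholds | None = None,
    n_points: int | None = None,
    tail_fraction: float = 0.1,
) -> pd.DataFrame:
    """Completeness metrics and well-sampled classification per grid cell.

    Carries through ``region`` and ``bandIndex`` when present. The
    asymptote of the rational fit is reported as ``predicted_richness``.
    """
    carry = [c for c in ("region", "bandIndex") if c in records.columns]
    rows = []
    for cell, grp in records.groupby(cell_col, sort=True):
        counts = grp[name_col].value_counts()
        curve = build_sac(counts.to_numpy(), n_points=n_points)
        fit = fit_rational(curve)
        row = {
            cell_col: cell,
            "n_records": curve.n_records,
            "s_obs": curve.s_obs,
            "predicted_richness": fit.asymptote,
            "completeness_pct": fit.completeness_pct,
            "slope": terminal_slope(curve, tail_fraction=tail_fraction),
            "ratio": curve.n_records / curve.s_obs,
            "fit_flag": fit.flag,
        }
        for c in carry:
            row[c] = grp[c].iloc[0]
        rows.append(row)
    metrics = pd.DataFrame(rows)
    if metrics.empty:
        cols = [cell_col, "n_records", "s_obs", "predicted_richness", "completeness_pct",
                "slope", "ratio", "fit_flag", *carry]
        metrics = pd.DataFrame(columns=cols)
    return classify_well_sampled(metrics, thresholds)


def well_sampled_across(metrics_by_filter: dict) -> pd.Series:
    """Per cell, the number of filter datasets under which it is well-sampled.

    ``metrics_by_filter`` maps a filter name to that filtered dataset's
    classified metrics frame; the result spans 0..len(metrics_by_filter).
    """
    counts: pd.Series | None = None
    for metrics in metrics_by_filter.values():
        ws = metrics.set_index(metrics.columns[0])["well_sampled"].astype(int)
        counts = ws if counts is None else counts.add(ws, fill_value=0)
    return counts.astype(int).rename("n_filters_well_sampled")
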