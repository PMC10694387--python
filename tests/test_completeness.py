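"""Exact rarefaction, accumulation curves, rational fits and well-sampled rules."""

import itertools
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from occurate.completeness import (
    SacCurve,
    WellSampledThresholds,
    build_sac,
    cell_metrics,
    classify_well_sampled,
    fit_rational,
    rarefaction_exact,
    terminal_slope,
    well_sampled_across,
)


def brute_force_rarefaction(counts, m):
    """Mean richness over ALL C(N, m) record subsets (independent oracle)."""
    records = [sp for sp, c in enumerate(counts) for _ in range(c)]
    subsets = list(itertools.combinations(range(len(records)), m))
    return np.mean([len({records[i] for i in sub}) for sub in subsets])


def test_two_species_subsample():
    # counts {A:2, B:1}, m=2: subsets {A1A2}:1, {A1B}:2, {A2B}:2 species
    assert rarefaction_exact({"A": 2, "B": 1}, 2) == pytest.approx(5 / 3, abs=1e-12)


@pytest.mark.parametrize(
    "counts,m,expected",
    [
        ([2, 1], 3, 2.0),  # m = N → S_obs
        ([2, 1], 0, 0.0),
        ([5], 1, 1.0),  # single-species inventory
        ([5], 4, 1.0),
    ],
)
def test_rarefaction_edge_values(counts, m, expected):
    assert rarefaction_exact(counts, m) == pytest.approx(expected, abs=1e-12)


def test_rarefaction_domain_error():
    with pytest.raises(ValueError):
        rarefaction_exact([2, 1], 4)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=1, max_value=5), min_size=1, max_size=5).filter(
        lambda c: sum(c) <= 12
    ),
    data=st.data(),
)
def test_rarefaction_matches_enumeration(counts, data):
    m = data.draw(st.integers(min_value=0, max_value=sum(counts)))
    exact = rarefaction_exact(counts, m)
    assert exact == pytest.approx(brute_force_rarefaction(counts, m), abs=1e-12)


def test_rarefaction_matches_vegan():
    """Independent cross-check against vegan::rarefy (individual-based)."""
    counts = [7, 3, 2, 1, 1]
    ms = [1, 3, 5, 10, 14]
    ours = rarefaction_exact(counts, ms)
    script = (
        "suppressMessages(library(vegan));"
        f"x <- c({','.join(map(str, counts))});"
        f"cat(sapply(c({','.join(map(str, ms))}), function(m) rarefy(x, sample=m)), sep=',')"
    )
    try:
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
    except (FileNotFoundError, subprocess.TimeoutExpired):
        pytest.skip("Rscript unavailable")
    theirs = np.array([float(v) for v in out.stdout.strip().split(",")])
    np.testing.assert_allclose(ours, theirs, atol=1e-5)


def test_sac_points_and_endpoint():
    curve = build_sac([2, 2, 1])  # N=5 → every m
    assert list(curve.m) == [1, 2, 3, 4, 5]
    assert curve.expected_species[-1] == pytest.approx(curve.s_obs, abs=1e-12)
    assert curve.expected_species[0] > 0


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=6).filter(
        lambda c: sum(c) <= 12
    )
)
def test_sac_monotone_and_concave(counts):
    curve = build_sac(counts)
    es = curve.expected_species
    assert np.all(np.diff(es) >= -1e-12)
    if len(es) >= 3:
        assert np.all(np.diff(es, 2) <= 1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=1, max_value=4), min_size=1, max_size=4).filter(
        lambda c: sum(c) <= 10
    ),
    data=st.data(),
)
def test_new_species_never_decreases_expectation(counts, data):
    """Adding one record of a new species raises E[S(m)] at every fixed m ≤ N."""
    m = data.draw(st.integers(min_value=1, max_value=sum(counts)))
    before = rarefaction_exact(counts, m)
    after = rarefaction_exact(list(counts) + [1], m)
    assert after >= before - 1e-12


def test_rational_fit_self_consistency():
    m = np.arange(1, 101, dtype=float)
    a, b, c = 0.0, 2.0, 0.02  # asymptote 100
    s = (a + b * m) / (1 + c * m)
    curve = SacCurve(m=m, expected_species=s, s_obs=int(round(s[-1])), n_records=100)
    fit = fit_rational(curve)
    assert fit.usable
    assert fit.asymptote == pytest.approx(100.0, rel=1e-6)


def test_flat_curve_is_complete():
    curve = SacCurve(m=np.array([1.0, 50.0, 100.0]), expected_species=np.full(3, 7.0),
                     s_obs=7, n_records=100)
    fit = fit_rational(curve)
    assert fit.completeness_pct == 100.0 and fit.flag == "flat"


def test_terminal_slope_interpretation():
    # one new species per ten records at the end of the curve
    curve = SacCurve(m=np.array([90.0, 100.0]), expected_species=np.array([20.0, 21.0]),
                     s_obs=21, n_records=100)
    assert terminal_slope(curve) == pytest.approx(0.1, abs=1e-12)
    flat = SacCurve(m=np.array([50.0, 100.0]), expected_species=np.array([9.0, 9.0]),
                    s_obs=9, n_records=100)
    assert terminal_slope(flat) == pytest.approx(0.0, abs=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=1, max_value=6), min_size=2, max_size=6).filter(
        lambda c: sum(c) <= 12
    )
)
def test_terminal_slope_below_mean_slope(counts):
    """Concavity: the end of the curve rises no faster than its average."""
    curve = build_sac(counts)
    assert terminal_slope(curve) <= curve.s_obs / curve.n_records + 1e-12


def _metrics_row(n=100, comp=70.0, ratio=5.0, slope=0.1):
    import pandas as pd

    return pd.DataFrame(
        [{"cellID": "c", "n_records": n, "s_obs": 10, "predicted_richness": 12.0,
          "completeness_pct": comp, "slope": slope, "ratio": ratio, "fit_flag": None}]
    )


def test_thresholds_inclusive_boundary():
    out = classify_well_sampled(_metrics_row())
    assert bool(out["well_sampled"].iloc[0])
    assert out["criteria_passed"].iloc[0] == 4


@pytest.mark.parametrize(
    "kwargs",
    [dict(n=99), dict(comp=69.9), dict(ratio=4.99), dict(slope=0.2)],
)
def test_single_criterion_failure_flips_flag(kwargs):
    out = classify_well_sampled(_metrics_row(**kwargs))
    assert not bool(out["well_sampled"].iloc[0])
    assert out["criteria_passed"].iloc[0] == 3


def test_thresholds_must_be_positive():
    with pytest.raises(ValueError):
        WellSampledThresholds(min_records=0)


def test_saturated_cells_reach_high_completeness():
    """Cells sampled to saturation (every species seen ≥5 times) score ≥90%."""
    rng = np.random.default_rng(42)
    complete = 0
    n_cells = 40
    for _ in range(n_cells):
        s = rng.integers(5, 40)
        counts = rng.integers(5, 30, size=s)
        fit = fit_rational(build_sac(counts))
        if fit.usable and fit.completeness_pct >= 90:
            complete += 1
    assert complete >= 0.95 * n_cells


def test_cell_metrics_and_across_filters(world, standardised):
    from occurate import geo, record_filters, taxonomy

    maps, consensus = standardised
    kept, _, _ = geo.preprocess(
        world.records, country_polygons=world.countries, gazetteer=world.gazetteer
    )
    tax, _, _ = taxonomy.apply_consensus(kept, maps, consensus)
    metrics = cell_metrics(tax)
    assert (metrics["ratio"] >= 1).all()
    ok = metrics["fit_flag"].isna()
    assert (metrics.loc[ok, "completeness_pct"] <= 100 + 1e-9).all()
    # predicted richness at least observed whenever the fit is unflagged
    assert (
        metrics.loc[ok, "predicted_richness"] >= metrics.loc[ok, "s_obs"] - 1e-9
    ).all()
    deduped, _, _ = record_filters.dedupe(tax)
    counts = well_sampled_across({"all": metrics, "dedup": cell_metrics(deduped)})
    assert counts.between(0, 2).all()
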