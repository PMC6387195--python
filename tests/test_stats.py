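"""2x2 association statistics: Yates chi-square, odds ratio, Woolf CI."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import chi2_sf_oracle
from deltascope import (
    ContingencyTable,
    associate,
    cell_table,
    make_fixture_table1,
    odds_ratio,
    summarize_sample,
    transcript_table,
    woolf_ci,
    yates_chi_square,
)
from deltascope.stats import StatsError, uncorrected_chi_square


def quants(gene):
    car = summarize_sample(make_fixture_table1(f"{gene}_carrier"))
    con = summarize_sample(make_fixture_table1(f"{gene}_control"))
    return car, con


def test_transcript_tables_from_fixture_summaries():
    t1 = transcript_table(*quants("BRCA1"))
    assert (t1.a, t1.b, t1.c, t1.d) == (26, 78, 5, 8)
    t2 = transcript_table(*quants("BRCA2"))
    assert (t2.a, t2.b, t2.c, t2.d) == (71, 89, 7, 24)


def test_cell_tables_from_fixture_summaries():
    c2 = cell_table(*quants("BRCA2"))
    assert (c2.a, c2.b, c2.c, c2.d) == (14, 36, 5, 45)
    # the complement is always n_cells - n_delta_pos (the published BRCA1
    # row prints 37, summing to 45 of 50 cells; we use 42)
    c1 = cell_table(*quants("BRCA1"))
    assert (c1.a, c1.b, c1.c, c1.d) == (8, 42, 1, 49)


def test_zero_delta_tables_flagged_degenerate():
    t = ContingencyTable(0, 104, 0, 13)
    assert t.degenerate
    with pytest.raises(StatsError, match="margin"):
        yates_chi_square(t)


@pytest.mark.parametrize(
    "table, expected_p",
    [((26, 78, 5, 8), 0.48), ((71, 89, 7, 24), 0.04), ((14, 36, 5, 45), 0.04)],
)
def test_yates_p_values_match_published(table, expected_p):
    _, p = yates_chi_square(ContingencyTable(*table))
    assert round(p, 2) == expected_p


def test_identical_rows_give_zero_statistic():
    chi2, p = yates_chi_square(ContingencyTable(10, 10, 10, 10))
    assert chi2 == 0.0 and p == 1.0


def test_near_null_correction_clamps_at_zero():
    # |O - E| < 0.5 in every cell: the Yates term clamps rather than
    # contributing a positive amount
    chi2, p = yates_chi_square(ContingencyTable(10, 10, 10, 11))
    assert chi2 == 0.0 and p == 1.0


def test_published_brca1_cell_table_p_values():
    # printed p=0.01 is only consistent with the uncorrected statistic;
    # both are computed and checked against the integration oracle
    t = ContingencyTable(8, 37, 1, 49)
    chi2, p = yates_chi_square(t)
    chi2_u, p_u = uncorrected_chi_square(t)
    assert p == pytest.approx(chi2_sf_oracle(chi2), rel=1e-9)
    assert p_u == pytest.approx(chi2_sf_oracle(chi2_u), rel=1e-9)
    assert round(p_u, 2) == 0.01
    assert p > 0.01  # Yates is conservative here


@pytest.mark.parametrize(
    "table, expected_or",
    [((14, 36, 5, 45), 3.5), ((26, 78, 5, 8), 0.53), ((5, 7, 5, 7), 1.0)],
)
def test_odds_ratio_values(table, expected_or):
    assert odds_ratio(ContingencyTable(*table)) == pytest.approx(expected_or, abs=0.005)


def test_odds_ratio_zero_cell_requires_haldane():
    t = ContingencyTable(5, 0, 3, 4)
    with pytest.raises(StatsError):
        odds_ratio(t)
    assert odds_ratio(t, haldane=True) == pytest.approx(5.5 * 4.5 / (0.5 * 3.5))


@pytest.mark.parametrize(
    "table, lo, hi",
    [((14, 36, 5, 45), 1.15, 10.63), ((71, 89, 7, 24), 1.11, 6.71)],
)
def test_woolf_ci_matches_published(table, lo, hi):
    ci = woolf_ci(ContingencyTable(*table))
    assert round(ci[0], 2) == lo
    assert round(ci[1], 2) == hi


def test_woolf_ci_null_table_symmetric_on_log_scale():
    # equal rows give OR = 1, so the logit interval is centered at 0
    lo, hi = woolf_ci(ContingencyTable(9, 4, 9, 4))
    assert np.log(lo) == pytest.approx(-np.log(hi), abs=1e-12)


def test_against_statsmodels_oracle():
    # independent implementation cross-check for OR and Woolf CI
    sm = pytest.importorskip("statsmodels.api")
    for cells in [(26, 78, 5, 8), (71, 89, 7, 24), (14, 36, 5, 45), (8, 37, 1, 49)]:
        t = ContingencyTable(*cells)
        table2x2 = sm.stats.Table2x2(np.array(cells).reshape(2, 2))
        assert odds_ratio(t) == pytest.approx(table2x2.oddsratio, rel=1e-12)
        lo, hi = woolf_ci(t)
        sm_lo, sm_hi = table2x2.oddsratio_confint(0.05)
        assert lo == pytest.approx(sm_lo, rel=1e-9)
        assert hi == pytest.approx(sm_hi, rel=1e-9)


tables = st.tuples(
    st.integers(1, 200), st.integers(1, 200), st.integers(1, 200), st.integers(1, 200)
)


@given(tables)
def test_p_value_agrees_with_integration_oracle(cells):
    t = ContingencyTable(*cells)
    chi2, p = yates_chi_square(t)
    oracle = chi2_sf_oracle(chi2)
    if oracle > 1e-300:
        assert p == pytest.approx(oracle, rel=1e-6)


@given(tables)
def test_row_swap_and_transpose_invariances(cells):
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    swapped = t.swapped_rows()
    transposed = ContingencyTable(a, c, b, d)
    col_swapped = ContingencyTable(b, a, d, c)

    chi2, p = yates_chi_square(t)
    for other in (swapped, transposed, col_swapped):
        chi2_o, p_o = yates_chi_square(other)
        assert chi2_o == pytest.approx(chi2, rel=1e-12, abs=1e-12)
        assert p_o == pytest.approx(p, rel=1e-12, abs=1e-12)

    orr = odds_ratio(t)
    assert odds_ratio(swapped) == pytest.approx(1 / orr, rel=1e-12)
    lo, hi = woolf_ci(t)
    lo_s, hi_s = woolf_ci(swapped)
    assert lo_s == pytest.approx(1 / hi, rel=1e-9)
    assert hi_s == pytest.approx(1 / lo, rel=1e-9)


@given(tables)
def test_yates_never_exceeds_uncorrected(cells):
    t = ContingencyTable(*cells)
    chi2_y, _ = yates_chi_square(t)
    chi2_u, _ = uncorrected_chi_square(t)
    assert chi2_y <= chi2_u + 1e-12


def test_woolf_coverage_at_nominal_level():
    # fixed-OR binomial sampling, 50 per row: 95% Woolf CI covers the true
    # OR in 93-97% of 2000 seeded replicates
    rng = np.random.default_rng(2024)
    true_or = 2.0
    p_control = 0.3
    odds_carrier = true_or * p_control / (1 - p_control)
    p_carrier = odds_carrier / (1 + odds_carrier)
    n = 50
    covered = 0
    reps = 2000
    for _ in range(reps):
        a = rng.binomial(n, p_carrier)
        c = rng.binomial(n, p_control)
        t = ContingencyTable(int(a), int(n - a), int(c), int(n - c))
        haldane = min(t.a, t.b, t.c, t.d) == 0
        lo, hi = woolf_ci(t, haldane=haldane)
        covered += lo <= true_or <= hi
    assert 0.93 <= covered / reps <= 0.97


def test_associate_bundles_consistent_results():
    res = associate(ContingencyTable(14, 36, 5, 45))
    assert res.ci_low <= res.odds_ratio <= res.ci_high
    assert 0 <= res.p_value <= 1
    assert res.chi2 <= res.chi2_uncorrected
    assert "Woolf" in res.method_notes
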