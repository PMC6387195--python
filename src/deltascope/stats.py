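"""2x2 contingency statistics: Yates chi-square, odds ratio, Woolf CI.

Two comparisons are built from a carrier/control pair of sample summaries:

* transcript level — delta events vs non-delta signals, pooled over cells;
* cell level — delta-positive vs delta-negative cells.

The independence test is the Yates continuity-corrected chi-square with one
degree of freedom (each |O - E| reduced by 0.5, clamped at zero, before
squaring), a conservative choice for small tables.  Effect size is the
cross-product odds ratio with a Woolf (logit-scale) confidence interval,
exp(ln OR ± z * sqrt(1/a + 1/b + 1/c + 1/d)).  An optional Haldane
correction (0.5 added to every cell) handles zero cells.  The uncorrected
chi-square is always computed alongside Yates, since published small-table
p-values are not always continuity-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .scoring import SampleQuant

__all__ = [
    "ContingencyTable",
    "AssocResult",
    "StatsError",
    "transcript_table",
    "cell_table",
    "yates_chi_square",
    "uncorrected_chi_square",
    "odds_ratio",
    "woolf_ci",
    "associate",
]


class StatsError(ValueError):
    """Invalid table for the requested statistic."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of non-negative integers.

    Row 1 (a, b) is the carrier (event, non-event) pair; row 2 (c, d) the
    control pair.
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("carrier", "control")
    col_labels: tuple[str, str] = ("event", "non-event")

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        for v in cells:
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise StatsError(f"table entries must be integers, got {v!r}")
            if v < 0:
                raise StatsError(f"table entries must be non-negative, got {v}")
        if sum(cells) == 0:
            raise StatsError("table must have at least one positive entry")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def degenerate(self) -> bool:
        """True when the event column (or any margin) is empty."""
        arr = self.as_array()
        return bool((arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any())

    def swapped_rows(self) -> "ContingencyTable":
        return ContingencyTable(
            self.c, self.d, self.a, self.b,
            row_labels=(self.row_labels[1], self.row_labels[0]),
            col_labels=self.col_labels,
        )


@dataclass(frozen=True)
class AssocResult:
    """Association statistics for one 2x2 comparison."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    p_value: float
    chi2_uncorrected: float
    p_uncorrected: float
    level: float = 0.95
    method_notes: str = ""

    def as_dict(self) -> dict:
        return {
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "chi2_yates": self.chi2,
            "p_yates": self.p_value,
            "chi2_uncorrected": self.chi2_uncorrected,
            "p_uncorrected": self.p_uncorrected,
            "ci_level": self.level,
            "method_notes": self.method_notes,
        }


def transcript_table(carrier: SampleQuant, control: SampleQuant) -> ContingencyTable:
    """Delta events vs non-delta signals, carrier against control."""
    for q in (carrier, control):
        if q.total_delta > q.total_signals:
            raise StatsError(
                f"sample {q.sample}: delta total {q.total_delta} exceeds "
                f"signal total {q.total_signals}"
            )
    return ContingencyTable(
        a=carrier.total_delta,
        b=carrier.total_signals - carrier.total_delta,
        c=control.total_delta,
        d=control.total_signals - control.total_delta,
        row_labels=(carrier.sample, control.sample),
        col_labels=("delta events", "non-delta signals"),
    )


def cell_table(carrier: SampleQuant, control: SampleQuant) -> ContingencyTable:
    """Delta-positive vs delta-negative cells, carrier against control.

    The delta-negative count is always n_cells - n_delta_pos.
    """
    for q in (carrier, control):
        if q.n_delta_pos > q.n_cells:
            raise StatsError(
                f"sample {q.sample}: {q.n_delta_pos} delta-positive cells "
                f"exceed the {q.n_cells} cells scored"
            )
    return ContingencyTable(
        a=carrier.n_delta_pos,
        b=carrier.n_cells - carrier.n_delta_pos,
        c=control.n_delta_pos,
        d=control.n_cells - control.n_delta_pos,
        row_labels=(carrier.sample, control.sample),
        col_labels=("cells with delta event", "cells without delta event"),
    )


def _check_margins(table: ContingencyTable) -> np.ndarray:
    arr = table.as_array()
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    for total, label in zip(rows, table.row_labels):
        if total == 0:
            raise StatsError(f"row margin {label!r} is empty")
    for total, label in zip(cols, table.col_labels):
        if total == 0:
            raise StatsError(f"column margin {label!r} is empty")
    return arr


def yates_chi_square(table: ContingencyTable) -> tuple[float, float]:
    """Continuity-corrected chi-square statistic and two-sided p (df = 1).

    chi2 = sum over cells of (max(|O - E| - 0.5, 0))^2 / E, with E the
    product-of-marginals expectation.  The clamp keeps near-null tables
    (|O - E| < 0.5) from contributing negative-squared terms.
    """
    arr = _check_margins(table)
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    adj = np.maximum(np.abs(arr - expected) - 0.5, 0.0)
    chi2 = float((adj**2 / expected).sum())
    return chi2, float(sps.chi2.sf(chi2, df=1))


def uncorrected_chi_square(table: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square without continuity correction (df = 1)."""
    arr = _check_margins(table)
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    chi2 = float((((arr - expected) ** 2) / expected).sum())
    return chi2, float(sps.chi2.sf(chi2, df=1))


def _cells(table: ContingencyTable, haldane: bool) -> tuple[float, float, float, float]:
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a), float(b), float(c), float(d)


def odds_ratio(table: ContingencyTable, haldane: bool = False) -> float:
    """Cross-product odds ratio ad / bc.

    With a zero in b or c the ratio is undefined; pass ``haldane=True`` to
    add 0.5 to every cell instead of raising.
    """
    a, b, c, d = _cells(table, haldane)
    if b * c == 0:
        raise StatsError(
            "odds ratio undefined with a zero off-diagonal cell; "
            "use haldane=True to apply the 0.5 correction"
        )
    return (a * d) / (b * c)


def woolf_ci(
    table: ContingencyTable, level: float = 0.95, haldane: bool = False
) -> tuple[float, float]:
    """Woolf (logit) confidence interval for the odds ratio.

    exp(ln OR ± z * sqrt(1/a + 1/b + 1/c + 1/d)) with z the exact normal
    quantile for the requested level.  All four cells must be positive
    unless ``haldane=True``.
    """
    if not 0 < level < 1:
        raise StatsError(f"confidence level must be in (0, 1), got {level}")
    a, b, c, d = _cells(table, haldane)
    if min(a, b, c, d) <= 0:
        raise StatsError(
            "Woolf interval requires all four cells positive; "
            "use haldane=True to apply the 0.5 correction"
        )
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + level / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def associate(
    table: ContingencyTable, level: float = 0.95, haldane: bool = False
) -> AssocResult:
    """Full association summary for one 2x2 table."""
    chi2, p = yates_chi_square(table)
    chi2_u, p_u = uncorrected_chi_square(table)
    use_haldane = haldane or min(table.a, table.b, table.c, table.d) == 0
    orr = odds_ratio(table, haldane=use_haldane)
    lo, hi = woolf_ci(table, level=level, haldane=use_haldane)
    notes = ["Yates-corrected and uncorrected chi-square, df=1", "Woolf logit CI"]
    if use_haldane:
        notes.append("Haldane 0.5 correction applied (zero cell present)")
    return AssocResult(
        odds_ratio=orr,
        ci_low=lo,
        ci_high=hi,
        chi2=chi2,
        p_value=p,
        chi2_uncorrected=chi2_u,
        p_uncorrected=p_u,
        level=level,
        method_notes="; ".join(notes),
    )
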