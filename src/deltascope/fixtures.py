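"""Deterministic 50-cell count fixtures reproducing the published summary rows.

The study's raw per-cell counts were never deposited; only the per-sample
marginals were printed (cells expressing, total signals with per-cell range,
total delta events with per-cell range, delta-positive cells, and the
association statistics).  Each fixture here is a hand-constructed 50-cell
table whose summary reproduces its sample's published row, so the scoring
and statistics stages can be exercised end to end on data with the published
marginals.  The individual (c1, c2) pairs are synthetic: any table with the
same marginals would serve.

Known inconsistencies in the published marginals, preserved or resolved here:

* BRCA1 control: 2 expressing cells with totals summing to 13 and a printed
  per-cell maximum of 10 force per-cell totals {10, 3}; but the single
  delta-positive cell needs delta = 5, and c1 + c2 always has the same
  parity as c2 - c1, so no integer cell can have total 10 or 3 with
  delta 5.  The fixture keeps every other quantity exact (2 expressing,
  13 signals, 5 delta, delta range 0-5, 1 delta-positive) with a per-cell
  signal maximum of 9.
* BRCA1 carrier: the published delta-positive (8) and delta-negative (37)
  cells sum to 45, not 50.  Summaries here always use
  n_cells - n_delta_pos = 42 for the complement; the printed cell-level
  2x2 table is available via :data:`PRINTED_CELL_TABLES` for reproducing
  the published statistics as-is.
"""

from __future__ import annotations

from .scoring import CellCount

__all__ = [
    "make_fixture_table1",
    "FIXTURE_SAMPLES",
    "PRINTED_SUMMARY",
    "PRINTED_CELL_TABLES",
]

# (c1, c2) pairs for the expressing cells of each sample; remaining cells up
# to 50 are (0, 0).  Constructed so summarize_sample reproduces the published
# row: see module docstring.
_EXPRESSING: dict[str, list[tuple[int, int]]] = {
    # 22 expressing, 104 signals (max/cell 17), 26 delta (max/cell 8),
    # 8 delta-positive, mean 2.08 -> 2.1
    "BRCA1_carrier": [
        (4, 12), (6, 11), (1, 5), (2, 5), (0, 2), (1, 3), (0, 1), (2, 3),
        (2, 1), (1, 0),
        (3, 3), (3, 3), (3, 3), (3, 3), (2, 2),
        (1, 1), (1, 1), (1, 1), (1, 1), (1, 1), (1, 1), (1, 1),
    ],
    # 2 expressing, 13 signals (max/cell 9, see module docstring), 5 delta
    # (max/cell 5), 1 delta-positive, mean 0.26 -> 0.3
    "BRCA1_control": [
        (2, 7), (2, 2),
    ],
    # 29 expressing, 160 signals (max/cell 29), 71 delta (max/cell 21),
    # 14 delta-positive, mean 3.2
    "BRCA2_carrier": [
        (4, 25), (1, 10), (2, 9), (1, 7), (0, 5), (1, 5), (2, 6),
        (0, 3), (1, 4), (0, 2), (1, 3), (2, 4), (0, 2), (0, 1),
        (2, 1), (1, 0), (3, 2),
        (3, 3), (3, 3), (3, 3), (3, 3),
        (2, 2), (2, 2), (2, 2), (2, 2), (2, 2),
        (1, 1), (1, 1), (1, 1),
    ],
    # 12 expressing, 31 signals (max/cell 5), 7 delta (max/cell 2),
    # 5 delta-positive, mean 0.62 -> 0.6
    "BRCA2_control": [
        (1, 3), (0, 2), (2, 3), (0, 1), (1, 2),
        (2, 2), (2, 2), (1, 1), (1, 1), (1, 1),
        (1, 0), (1, 0),
    ],
}

_N_CELLS = 50

FIXTURE_SAMPLES = tuple(sorted(_EXPRESSING))

# Published per-sample summary values, kept for reference checks in reports.
PRINTED_SUMMARY: dict[str, dict[str, float | int | tuple[int, int]]] = {
    "BRCA1_carrier": {
        "n_expressing": 22, "total_signals": 104, "signal_range": (0, 17),
        "total_delta": 26, "delta_range": (0, 8), "n_delta_pos": 8,
        "n_delta_neg_printed": 37, "mean_signals_per_cell": 2.1,
    },
    "BRCA1_control": {
        "n_expressing": 2, "total_signals": 13, "signal_range": (0, 10),
        "total_delta": 5, "delta_range": (0, 5), "n_delta_pos": 1,
        "n_delta_neg_printed": 49, "mean_signals_per_cell": 0.3,
    },
    "BRCA2_carrier": {
        "n_expressing": 29, "total_signals": 160, "signal_range": (0, 29),
        "total_delta": 71, "delta_range": (0, 21), "n_delta_pos": 14,
        "n_delta_neg_printed": 36, "mean_signals_per_cell": 3.2,
    },
    "BRCA2_control": {
        "n_expressing": 12, "total_signals": 31, "signal_range": (0, 5),
        "total_delta": 7, "delta_range": (0, 2), "n_delta_pos": 5,
        "n_delta_neg_printed": 45, "mean_signals_per_cell": 0.6,
    },
}

# Published cell-level 2x2 tables (delta-positive, delta-negative) exactly as
# printed, including the BRCA1 carrier row that sums to 45 cells rather
# than 50.
PRINTED_CELL_TABLES: dict[str, tuple[int, int, int, int]] = {
    "BRCA1": (8, 37, 1, 49),
    "BRCA2": (14, 36, 5, 45),
}


def make_fixture_table1(sample: str) -> list[CellCount]:
    """Return the deterministic 50-cell fixture for one study sample.

    ``sample`` is one of :data:`FIXTURE_SAMPLES`.  Cells are returned in a
    fixed order (expressing cells first); all summary statistics are
    order-invariant.
    """
    if sample not in _EXPRESSING:
        raise KeyError(
            f"unknown sample {sample!r}; available: {', '.join(FIXTURE_SAMPLES)}"
        )
    pairs = _EXPRESSING[sample] + [(0, 0)] * (_N_CELLS - len(_EXPRESSING[sample]))
    return [
        CellCount(cell_id=f"{sample}_c{i:02d}", sample=sample, c1=c1, c2=c2)
        for i, (c1, c2) in enumerate(pairs)
    ]
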