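"""Per-cell delta-event scoring and per-sample summaries.

A dual-probe single-molecule RNA ISH assay images two probe sets per gene:
the C1 probe binds the exon region that is skipped in the aberrant isoform
(so it marks full-length transcripts only), while the C2 probe binds a
region present in every transcript of the gene.  The per-cell excess of C2
over C1 signals therefore estimates the number of exon-skipping (delta)
transcripts in that cell.

Scoring is strictly per cell: the per-sample delta total is the sum of the
clamped per-cell differences, not the difference of the channel totals.
Cells with more C1 than C2 signals (observed in practice, cause unresolved)
contribute zero delta events and are flagged ``discordant``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

__all__ = [
    "CellCount",
    "CellClass",
    "SampleQuant",
    "delta_events",
    "classify_cell",
    "summarize_sample",
]


@dataclass(frozen=True)
class CellCount:
    """Observed two-channel signal counts for a single cell.

    Parameters
    ----------
    cell_id:
        Identifier, unique within a sample.
    sample:
        Sample label the cell belongs to.
    c1:
        Signals from the probe targeting the skipped exon region
        (present in full-length transcripts only).
    c2:
        Signals from the probe targeting a region shared by all
        transcripts of the gene.
    """

    cell_id: str
    sample: str
    c1: int
    c2: int

    def __post_init__(self) -> None:
        for name in ("c1", "c2"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def discordant(self) -> bool:
        """True when the cell shows more C1 than C2 signals."""
        return self.c1 > self.c2

    @property
    def total_signals(self) -> int:
        return self.c1 + self.c2

    @property
    def delta(self) -> int:
        return delta_events(self.c1, self.c2)


def delta_events(c1: int, c2: int) -> int:
    """Number of exon-skipping (delta) events inferred for one cell.

    Computed as C2 − C1 signals, clamped at zero: a full-length transcript
    produces one signal in each channel, so the C2 excess counts transcripts
    lacking the C1 (skipped-exon) region.  Discordant cells (c1 > c2) score
    zero rather than a negative count.
    """
    if c1 < 0 or c2 < 0:
        raise ValueError(f"signal counts must be non-negative, got ({c1}, {c2})")
    return max(c2 - c1, 0)


@dataclass(frozen=True)
class CellClass:
    expressing: bool
    delta_positive: bool


def classify_cell(
    cell: CellCount, expressing_mode: Literal["any", "c2"] = "any"
) -> CellClass:
    """Classify a cell as expressing and/or delta-positive.

    ``expressing_mode="any"`` (default) calls a cell expressing when either
    channel shows a signal; ``"c2"`` requires a signal from the
    all-transcript probe.
    """
    if expressing_mode == "any":
        expressing = cell.c1 + cell.c2 > 0
    elif expressing_mode == "c2":
        expressing = cell.c2 > 0
    else:
        raise ValueError(f"unknown expressing_mode {expressing_mode!r}")
    return CellClass(expressing=expressing, delta_positive=cell.delta > 0)


@dataclass(frozen=True)
class SampleQuant:
    """Per-sample aggregate of per-cell counts (one summary-table row)."""

    sample: str
    n_cells: int
    n_expressing: int
    total_signals: int
    signal_min: int
    signal_max: int
    total_delta: int
    delta_min: int
    delta_max: int
    n_delta_pos: int
    mean_signals_per_cell: float
    n_discordant: int

    @property
    def pct_expressing(self) -> float:
        return 100.0 * self.n_expressing / self.n_cells

    @property
    def n_delta_neg(self) -> int:
        """Cells without a delta event, always the complement within n_cells."""
        return self.n_cells - self.n_delta_pos


def summarize_sample(
    cells: Sequence[CellCount] | Iterable[CellCount],
    expressing_mode: Literal["any", "c2"] = "any",
) -> SampleQuant:
    """Aggregate one sample's cells into a summary row.

    Order-invariant; rejects an empty list or mixed sample labels.  The mean
    is kept at full precision here and rounded to one decimal only when a
    report is rendered.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("cannot summarize an empty cell list")
    labels = {c.sample for c in cells}
    if len(labels) > 1:
        raise ValueError(f"mixed sample labels in one summary: {sorted(labels)}")

    totals = [c.total_signals for c in cells]
    deltas = [c.delta for c in cells]
    classes = [classify_cell(c, expressing_mode) for c in cells]
    return SampleQuant(
        sample=labels.pop(),
        n_cells=len(cells),
        n_expressing=sum(k.expressing for k in classes),
        total_signals=sum(totals),
        signal_min=min(totals),
        signal_max=max(totals),
        total_delta=sum(deltas),
        delta_min=min(deltas),
        delta_max=max(deltas),
        n_delta_pos=sum(k.delta_positive for k in classes),
        mean_signals_per_cell=sum(totals) / len(cells),
        n_discordant=sum(c.discordant for c in cells),
    )
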