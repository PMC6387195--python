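"""Summary-table report: one carrier/control pair, both 2x2 comparisons.

Renders a Markdown table mirroring the field's standard per-sample layout —
cells expressing, total signals (per-cell range), total delta events
(per-cell range), cell-level delta-positive/negative counts — with the
transcript-level and cell-level association statistics and explanatory
footnotes.  Means are rounded to one decimal and OR/CI/p to two decimals in
the rendered table; the JSON mirror keeps full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fixtures import PRINTED_SUMMARY
from .scoring import SampleQuant
from .stats import AssocResult, associate, cell_table, transcript_table

__all__ = ["ReportResult", "build_report"]


@dataclass(frozen=True)
class ReportResult:
    markdown: str
    transcript: AssocResult
    cell: AssocResult
    notes: tuple[str, ...]

    @property
    def json_payload(self) -> dict:
        return {
            "transcript_level": self.transcript.as_dict(),
            "cell_level": self.cell.as_dict(),
            "notes": list(self.notes),
        }


def _fmt_assoc(r: AssocResult) -> str:
    return (
        f"{r.p_value:.2f} (OR {r.odds_ratio:.2f}; "
        f"CI {r.ci_low:.2f}-{r.ci_high:.2f})"
    )


def _check_reference(quant: SampleQuant, notes: list[str]) -> None:
    """Compare a summary against the published reference row, if one exists."""
    ref = PRINTED_SUMMARY.get(quant.sample)
    if ref is None:
        return
    printed_neg = ref["n_delta_neg_printed"]
    if quant.n_delta_neg != printed_neg:
        notes.append(
            f"{quant.sample}: delta-negative complement computed as "
            f"n_cells - n_delta_pos = {quant.n_delta_neg}, but the published "
            f"table prints {printed_neg} (rows summing to "
            f"{quant.n_delta_pos + printed_neg} of {quant.n_cells} cells); "
            "the computed complement is used throughout."
        )
    printed_max = ref["signal_range"][1]
    if quant.signal_max != printed_max:
        notes.append(
            f"{quant.sample}: per-cell signal maximum {quant.signal_max} "
            f"differs from the published {printed_max}."
        )


def build_report(
    carrier: SampleQuant,
    control: SampleQuant,
    check_reference: bool = True,
    haldane: bool = False,
) -> ReportResult:
    """Build the two-comparison association report for one sample pair."""
    t_assoc = associate(transcript_table(carrier, control), haldane=haldane)
    c_assoc = associate(cell_table(carrier, control), haldane=haldane)

    notes: list[str] = []
    if check_reference:
        for q in (carrier, control):
            _check_reference(q, notes)

    header = (
        "| Sample | Cells expressing (n={n}) | Total signals (range/cell) | "
        "Total delta events (range/cell) | p (OR; CI) | Cells with delta | "
        "Cells without delta | p (OR; CI) |"
    ).format(n=carrier.n_cells)
    rule = "|" + "---|" * 8

    def row(q: SampleQuant, t: str, c: str) -> str:
        return (
            f"| {q.sample} | {q.n_expressing} ({q.pct_expressing:.0f}%) "
            f"| {q.total_signals} ({q.signal_min}-{q.signal_max}) "
            f"| {q.total_delta} ({q.delta_min}-{q.delta_max}) "
            f"| {t} | {q.n_delta_pos} | {q.n_delta_neg} | {c} |"
        )

    lines = [
        header,
        rule,
        row(carrier, _fmt_assoc(t_assoc), _fmt_assoc(c_assoc)),
        row(control, "", ""),
        "",
        "Footnotes:",
        "- Total signals: C1 + C2 probe signals summed over all scored cells.",
        "- Delta events per cell: max(C2 - C1, 0); discordant cells "
        f"(C1 > C2) contribute 0 (carrier: {carrier.n_discordant}, "
        f"control: {control.n_discordant} discordant).",
        "- p-values: Yates-corrected chi-square, df = 1; uncorrected p "
        f"(transcript, cell) = {t_assoc.p_uncorrected:.3f}, "
        f"{c_assoc.p_uncorrected:.3f}.",
        "- CI: Woolf 95% interval for the odds ratio.",
        f"- Mean signals per cell: carrier {carrier.mean_signals_per_cell:.1f}, "
        f"control {control.mean_signals_per_cell:.1f}.",
    ]
    for n in notes:
        lines.append(f"- NOTE: {n}")
    return ReportResult(
        markdown="\n".join(lines) + "\n",
        transcript=t_assoc,
        cell=c_assoc,
        notes=tuple(notes),
    )
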