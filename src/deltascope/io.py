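"""Readers and writers for the pipeline's file formats.

Canonical table dialect: tab-separated, header required, UTF-8, LF line
endings; comma-separated files are accepted on read (sniffed from the
extension).  Per-cell counts use the header ``cell_id  sample  c1  c2``.
Ground-truth spot tables are CSV with header ``x,y,channel,cell_id`` where
x is the column and y the row, 0-based, sub-pixel.  Images are multi-page
TIFF in the rendered page order (labels, C1, C2).  Simulation parameters
and image specs load from YAML or JSON mappings.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .render import GroundTruthSpot, ImageSpec
from .scoring import CellCount, SampleQuant
from .simulate import SimParams
from .stats import AssocResult

__all__ = [
    "write_counts",
    "read_counts",
    "write_summaries",
    "read_summaries",
    "write_truth",
    "read_truth",
    "write_stack",
    "read_stack",
    "load_sim_params",
    "load_image_spec",
    "write_assoc_json",
]

COUNTS_COLUMNS = ["cell_id", "sample", "c1", "c2"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def write_counts(cells: Sequence[CellCount], path: str | Path) -> None:
    """Write per-cell counts as the canonical TSV (CSV if *.csv)."""
    path = Path(path)
    df = pd.DataFrame(
        [(c.cell_id, c.sample, c.c1, c.c2) for c in cells], columns=COUNTS_COLUMNS
    )
    df.to_csv(path, sep=_sep_for(path), index=False, lineterminator="\n")


def read_counts(path: str | Path) -> list[CellCount]:
    """Read a per-cell counts table (TSV canonical, CSV accepted)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        CellCount(
            cell_id=str(r.cell_id), sample=str(r.sample), c1=int(r.c1), c2=int(r.c2)
        )
        for r in df.itertuples()
    ]


def write_summaries(quants: Sequence[SampleQuant], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame([dataclasses.asdict(q) for q in quants])
    df.to_csv(path, sep=_sep_for(path), index=False, lineterminator="\n")


def read_summaries(path: str | Path) -> list[SampleQuant]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    fields = [f.name for f in dataclasses.fields(SampleQuant)]
    out = []
    for r in df.to_dict(orient="records"):
        kwargs = {k: r[k] for k in fields}
        for k, v in kwargs.items():
            if k == "sample":
                kwargs[k] = str(v)
            elif k == "mean_signals_per_cell":
                kwargs[k] = float(v)
            else:
                kwargs[k] = int(v)
        out.append(SampleQuant(**kwargs))
    return out


def write_truth(truth: Sequence[GroundTruthSpot], path: str | Path) -> None:
    """Ground-truth spots as CSV: x (column), y (row), 0-based sub-pixel."""
    df = pd.DataFrame(
        [(s.x, s.y, s.channel, s.cell_id) for s in truth],
        columns=["x", "y", "channel", "cell_id"],
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_truth(path: str | Path) -> list[GroundTruthSpot]:
    df = pd.read_csv(path)
    return [
        GroundTruthSpot(
            x=float(r.x), y=float(r.y), channel=str(r.channel), cell_id=str(r.cell_id)
        )
        for r in df.itertuples()
    ]


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a (pages, H, W) stack as multi-page TIFF.

    Page order: 0 = cell label image, 1 = C1 channel, 2 = C2 channel.
    """
    tifffile.imwrite(
        Path(path),
        np.asarray(stack, dtype=np.float32),
        photometric="minisblack",
    )


def read_stack(path: str | Path) -> np.ndarray:
    stack = tifffile.imread(Path(path))
    if stack.ndim == 2:
        stack = stack[None]
    return np.asarray(stack)


def _load_mapping(path: Path) -> dict[str, Any]:
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def load_sim_params(path: str | Path, **overrides: Any) -> SimParams:
    """Load simulation parameters from a YAML or JSON mapping."""
    data = _load_mapping(Path(path))
    data.update({k: v for k, v in overrides.items() if v is not None})
    return SimParams(**data)


def load_image_spec(path: str | Path, **overrides: Any) -> ImageSpec:
    data = _load_mapping(Path(path))
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "cell_layout" in data:
        data["cell_layout"] = tuple(tuple(d) for d in data["cell_layout"])
    return ImageSpec(**data)


def write_assoc_json(
    results: dict[str, AssocResult], path: str | Path, extra: dict | None = None
) -> None:
    """Machine-readable mirror of an association report."""
    payload: dict[str, Any] = {k: v.as_dict() for k, v in results.items()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
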