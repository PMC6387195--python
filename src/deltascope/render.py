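"""Synthetic two-channel fluorescence image rendering with ground truth.

Cells are non-overlapping discs on a flat background; each observed signal
becomes one Gaussian spot (the microscope point-spread function) at a
uniform-random sub-pixel position inside its cell's disc.  The rendered
stack has three pages: page 0 is an integer label image encoding the cell
masks (background 0, cell i labelled i+1), pages 1 and 2 are the C1 and C2
probe channels.  Coordinates follow the image convention: ``x`` is the
column and ``y`` the row, both 0-based with sub-pixel precision, so pixel
(row r, col c) covers x in [c-0.5, c+0.5).

Spots within one channel of one cell are placed with a minimum pairwise
separation (dart throwing), keeping peaks resolvable so that noise-free
renders can be quantified back to the exact input counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .scoring import CellCount

__all__ = [
    "ImageSpec",
    "GroundTruthSpot",
    "LayoutError",
    "grid_layout",
    "render_image",
    "CHANNEL_PAGES",
]

# Page order of the rendered stack.
CHANNEL_PAGES = {"labels": 0, "C1": 1, "C2": 2}

_STAGE_RENDER = 3


class LayoutError(ValueError):
    """Cell layout cannot accommodate the requested cells or spots."""


@dataclass(frozen=True)
class ImageSpec:
    """Geometry and optics of a rendered synthetic image.

    ``cell_layout`` is a sequence of ``(y, x, radius)`` discs in pixels;
    discs must fit inside the image and must not overlap.
    """

    width: int
    height: int
    cell_layout: tuple[tuple[float, float, float], ...]
    psf_sigma: float = 1.5
    spot_amplitude: float = 1000.0
    noise_sigma: float = 0.0
    background_level: float = 100.0
    min_spot_separation: float | None = None  # default: 4 * psf_sigma

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise LayoutError("image dimensions must be positive")
        for name in ("psf_sigma", "spot_amplitude"):
            if getattr(self, name) <= 0:
                raise LayoutError(f"{name} must be > 0")
        if self.noise_sigma < 0 or self.background_level < 0:
            raise LayoutError("noise_sigma and background_level must be >= 0")
        layout = tuple(tuple(map(float, disc)) for disc in self.cell_layout)
        object.__setattr__(self, "cell_layout", layout)
        for y, x, r in layout:
            if r <= 0:
                raise LayoutError("disc radius must be > 0")
            if not (r <= x <= self.width - r and r <= y <= self.height - r):
                raise LayoutError(f"disc at ({y:.1f}, {x:.1f}) r={r:.1f} exceeds bounds")
        for i in range(len(layout)):
            for j in range(i + 1, len(layout)):
                yi, xi, ri = layout[i]
                yj, xj, rj = layout[j]
                if math.hypot(yi - yj, xi - xj) < ri + rj:
                    raise LayoutError(f"discs {i} and {j} overlap")

    @property
    def spot_separation(self) -> float:
        if self.min_spot_separation is not None:
            return self.min_spot_separation
        return 4.0 * self.psf_sigma


@dataclass(frozen=True)
class GroundTruthSpot:
    """True sub-pixel spot location: x = column, y = row, 0-based."""

    x: float
    y: float
    channel: str
    cell_id: str


def grid_layout(
    n_cells: int, width: int, height: int, radius: float = 18.0, gap: float = 4.0
) -> tuple[tuple[float, float, float], ...]:
    """Pack ``n_cells`` equal discs on a regular grid within the image."""
    pitch = 2 * radius + gap
    per_row = int((width - gap) // pitch)
    n_rows = int((height - gap) // pitch)
    if per_row * n_rows < n_cells:
        raise LayoutError(
            f"cannot place {n_cells} discs of radius {radius} in "
            f"{width}x{height} (capacity {per_row * n_rows})"
        )
    layout = []
    for i in range(n_cells):
        row, col = divmod(i, per_row)
        layout.append(
            (gap + radius + row * pitch, gap + radius + col * pitch, radius)
        )
    return tuple(layout)


def _place_spots(
    rng: np.random.Generator,
    n: int,
    disc: tuple[float, float, float],
    min_sep: float,
    max_tries: int = 2000,
) -> list[tuple[float, float]]:
    """Dart-throw n points uniformly in a disc with pairwise separation."""
    cy, cx, r = disc
    # keep the full PSF-center inside the disc so the rounded center pixel
    # stays within the mask
    r_eff = max(r - 1.5, 0.5)
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise LayoutError(
                f"could not place {n} spots with separation {min_sep:.1f} "
                f"in a disc of radius {r:.1f}"
            )
        tries += 1
        rad = r_eff * math.sqrt(rng.random())
        theta = 2 * math.pi * rng.random()
        y = cy + rad * math.sin(theta)
        x = cx + rad * math.cos(theta)
        if all(math.hypot(y - py, x - px) >= min_sep for py, px in placed):
            placed.append((y, x))
    return placed


def _add_gaussian(img: np.ndarray, y: float, x: float, sigma: float, amp: float) -> None:
    h, w = img.shape
    half = int(math.ceil(6 * sigma))
    r0, r1 = max(int(y) - half, 0), min(int(y) + half + 1, h)
    c0, c1 = max(int(x) - half, 0), min(int(x) + half + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    img[r0:r1, c0:c1] += amp * np.exp(
        -((rows - y) ** 2 + (cols - x) ** 2) / (2 * sigma**2)
    )


def render_image(
    cells: Sequence[CellCount],
    spec: ImageSpec,
    seed: int = 0,
) -> tuple[np.ndarray, list[GroundTruthSpot]]:
    """Render observed counts into a (3, height, width) float32 stack.

    Returns the stack (pages: labels, C1, C2; see :data:`CHANNEL_PAGES`) and
    the ground-truth spot table.  One disc is consumed per cell, in order;
    more cells than discs is an error.
    """
    if len(cells) > len(spec.cell_layout):
        raise LayoutError(
            f"{len(cells)} cells but only {len(spec.cell_layout)} discs in layout"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_RENDER]))

    h, w = spec.height, spec.width
    labels = np.zeros((h, w), dtype=np.float32)
    chan = {
        "C1": np.full((h, w), spec.background_level, dtype=np.float64),
        "C2": np.full((h, w), spec.background_level, dtype=np.float64),
    }
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]

    truth: list[GroundTruthSpot] = []
    for i, cell in enumerate(cells):
        cy, cx, r = spec.cell_layout[i]
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = i + 1
        for channel, count in (("C1", cell.c1), ("C2", cell.c2)):
            for y, x in _place_spots(
                rng, count, spec.cell_layout[i], spec.spot_separation
            ):
                _add_gaussian(chan[channel], y, x, spec.psf_sigma, spec.spot_amplitude)
                truth.append(
                    GroundTruthSpot(x=x, y=y, channel=channel, cell_id=cell.cell_id)
                )
    if spec.noise_sigma > 0:
        for channel in ("C1", "C2"):
            chan[channel] += rng.normal(0.0, spec.noise_sigma, size=(h, w))

    stack = np.stack(
        [labels, chan["C1"].astype(np.float32), chan["C2"].astype(np.float32)]
    )
    return stack, truth
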