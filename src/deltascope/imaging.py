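"""Automated spot counting: segmentation, detection, spot-to-cell assignment.

This is the automated counterpart of counting fluorescent signals by eye:
cell masks come from a label (or nuclei) channel, spots are detected
independently per probe channel — no cross-channel pairing or
colocalisation is attempted — and each spot is assigned to the cell mask
containing its center.  Images are 2D; real z-stacks must be max-projected
before quantification.

Spot detection is a scale-normalised Laplacian-of-Gaussian band-pass at the
expected PSF width, followed by local-maximum extraction, thresholding, and
sub-pixel refinement by centroid of the local response patch.  The default
threshold is a multiple of the robust noise level of the response
(1.4826 * median absolute deviation), which is scale-free across spot
amplitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .scoring import CellCount

__all__ = [
    "CellMask",
    "DetectedSpot",
    "QCLog",
    "SegmentationError",
    "segment_cells",
    "detect_spots",
    "assign_spots",
    "quantify_image",
    "DEFAULT_THRESHOLD_K",
]

logger = logging.getLogger(__name__)

# Threshold multiple of the robust response noise; high enough that pure
# noise maxima over a megapixel stay below it, far below the response of a
# spot at the amplitude/noise ratios the assay produces.
DEFAULT_THRESHOLD_K = 6.0


class SegmentationError(ValueError):
    """Label geometry is inconsistent (e.g. one label in disjoint pieces)."""


@dataclass(frozen=True)
class CellMask:
    """One cell's pixel mask in image coordinates."""

    cell_id: int
    mask: np.ndarray  # bool, image-shaped

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise SegmentationError(f"mask for cell {self.cell_id} is empty")


@dataclass(frozen=True)
class DetectedSpot:
    """Detected spot center (x = column, y = row, 0-based, sub-pixel)."""

    x: float
    y: float
    channel: str
    score: float


@dataclass
class QCLog:
    """Counts of what the pipeline kept and discarded."""

    n_cells: int = 0
    n_border_excluded: int = 0
    discarded_spots: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def render(self) -> str:
        lines = [
            f"cells segmented: {self.n_cells}",
            f"cells excluded at border: {self.n_border_excluded}",
        ]
        for channel, n in sorted(self.discarded_spots.items()):
            lines.append(f"spots outside all masks ({channel}): {n}")
        lines.extend(self.notes)
        return "\n".join(lines) + "\n"


def segment_cells(
    label_image: np.ndarray,
    exclude_border: bool = True,
    qc: QCLog | None = None,
) -> list[CellMask]:
    """Extract disjoint cell masks from an integer label channel.

    Background is label 0.  Every label must form a single connected
    component — two merged or duplicated discs sharing a label are a
    corrupt segmentation and raise :class:`SegmentationError`.  Cells
    touching the image border are excluded (counted in the QC log).  An
    image with no labels yields an empty list with a warning, not an error.
    """
    lab = np.asarray(label_image)
    lab = np.round(lab).astype(np.int64)
    values = np.unique(lab)
    values = values[values > 0]
    if values.size == 0:
        logger.warning("segmentation found no labelled cells")
        return []

    masks: list[CellMask] = []
    n_border = 0
    for v in values:
        mask = lab == v
        _, n_comp = ndimage.label(mask)
        if n_comp != 1:
            raise SegmentationError(
                f"label {v} forms {n_comp} disconnected regions; "
                "duplicate or corrupt label geometry"
            )
        if exclude_border and (
            mask[0, :].any() or mask[-1, :].any()
            or mask[:, 0].any() or mask[:, -1].any()
        ):
            n_border += 1
            logger.info("excluding border-touching cell label %d", v)
            continue
        masks.append(CellMask(cell_id=int(v), mask=mask))
    if qc is not None:
        qc.n_cells = len(masks)
        qc.n_border_excluded = n_border
    return masks


def _robust_sigma(response: np.ndarray) -> float:
    med = np.median(response)
    return 1.4826 * float(np.median(np.abs(response - med)))


def detect_spots(
    channel_image: np.ndarray,
    psf_sigma: float,
    threshold: float | None = None,
    threshold_k: float = DEFAULT_THRESHOLD_K,
    channel: str = "C1",
) -> list[DetectedSpot]:
    """Detect diffraction-limited spots in one channel.

    The detector response is the negated, scale-normalised LoG
    (sigma^2 * -laplace(gaussian(img))), maximal at the center of a Gaussian
    spot of width ``psf_sigma``.  Candidate spots are strict local maxima of
    the response above ``threshold``; when no explicit threshold is given it
    is ``threshold_k`` robust-sigma of the response (plus a tiny floor so a
    perfectly flat image yields nothing).  Centers are refined to sub-pixel
    precision by the centroid of the positive response in a patch around
    each maximum.
    """
    if psf_sigma <= 0:
        raise ValueError(f"psf_sigma must be > 0, got {psf_sigma}")
    img = np.asarray(channel_image, dtype=np.float64)
    response = -(psf_sigma**2) * ndimage.gaussian_laplace(img, sigma=psf_sigma)
    # Center on the median: the truncated LoG kernel does not sum exactly
    # to zero, so a flat background leaves a small constant offset that
    # would otherwise read as an image-wide plateau of peaks.
    response -= np.median(response)

    if threshold is None:
        # Floor at a small fraction of the image dynamic range: keeps
        # quantisation-level ripple (e.g. float32 storage of a flat
        # background) from surfacing as peaks when the robust noise
        # estimate is ~0, yet sits orders of magnitude below any real
        # spot's response (~amplitude/2).
        scale = float(img.max() - img.min())
        floor = 1e-4 * scale if scale > 0 else 1e-9
        threshold = max(threshold_k * _robust_sigma(response), floor)
    elif threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")

    footprint = ndimage.maximum_filter(response, size=3, mode="nearest")
    peaks = (response >= footprint) & (response > threshold)
    half = max(int(round(2 * psf_sigma)), 1)
    spots: list[DetectedSpot] = []
    for r, c in zip(*np.nonzero(peaks)):
        r0, r1 = max(r - half, 0), min(r + half + 1, response.shape[0])
        c0, c1 = max(c - half, 0), min(c + half + 1, response.shape[1])
        patch = np.clip(response[r0:r1, c0:c1], 0.0, None)
        total = patch.sum()
        if total <= 0:
            y, x = float(r), float(c)
        else:
            rows = np.arange(r0, r1)[:, None]
            cols = np.arange(c0, c1)[None, :]
            y = float((patch * rows).sum() / total)
            x = float((patch * cols).sum() / total)
        spots.append(
            DetectedSpot(x=x, y=y, channel=channel, score=float(response[r, c]))
        )
    return spots


def assign_spots(
    spots: Sequence[DetectedSpot],
    masks: Sequence[CellMask],
    sample: str = "quantified",
    qc: QCLog | None = None,
) -> list[CellCount]:
    """Count spots per cell by mask containment of the rounded center.

    Containment is inclusive: a spot whose rounded center lands on any mask
    pixel (boundary included) is counted for that mask.  Spots outside all
    masks go to a discard bin recorded in the QC log.  Every mask yields a
    record, including zero-count cells.
    """
    counts = {m.cell_id: {"C1": 0, "C2": 0} for m in masks}
    discarded: dict[str, int] = {}
    if masks:
        shape = masks[0].mask.shape
        label_map = np.zeros(shape, dtype=np.int64)
        for m in masks:
            label_map[m.mask] = m.cell_id
    for s in spots:
        r, c = int(round(s.y)), int(round(s.x))
        owner = 0
        if masks and 0 <= r < shape[0] and 0 <= c < shape[1]:
            owner = int(label_map[r, c])
        if owner:
            counts[owner][s.channel] += 1
        else:
            discarded[s.channel] = discarded.get(s.channel, 0) + 1
    if discarded:
        logger.info("discarded spots outside all masks: %s", discarded)
    if qc is not None:
        qc.discarded_spots = discarded
    return [
        CellCount(
            cell_id=f"cell_{m.cell_id:03d}",
            sample=sample,
            c1=counts[m.cell_id]["C1"],
            c2=counts[m.cell_id]["C2"],
        )
        for m in masks
    ]


def quantify_image(
    stack_or_labels: np.ndarray,
    c1_image: np.ndarray | None = None,
    c2_image: np.ndarray | None = None,
    psf_sigma: float = 1.5,
    threshold: float | None = None,
    threshold_k: float = DEFAULT_THRESHOLD_K,
    sample: str = "quantified",
    max_cells: int | None = None,
    exclude_border: bool = True,
) -> tuple[list[CellCount], QCLog]:
    """Full image-to-counts pipeline.

    Accepts either a (3, H, W) stack in the rendered page order (labels,
    C1, C2) or three separate 2D arrays.  ``max_cells`` keeps the first N
    masks in label order, mirroring a fixed-size manual count.
    """
    if c1_image is None:
        stack = np.asarray(stack_or_labels)
        if stack.ndim != 3 or stack.shape[0] < 3:
            raise ValueError("expected a (3, H, W) stack or three 2D images")
        labels, c1_img, c2_img = stack[0], stack[1], stack[2]
    else:
        if c2_image is None:
            raise ValueError("c2_image required when passing separate channels")
        labels, c1_img, c2_img = np.asarray(stack_or_labels), c1_image, c2_image

    qc = QCLog()
    masks = segment_cells(labels, exclude_border=exclude_border, qc=qc)
    if max_cells is not None:
        masks = masks[:max_cells]
        qc.n_cells = len(masks)
    spots = detect_spots(
        c1_img, psf_sigma, threshold=threshold, threshold_k=threshold_k, channel="C1"
    ) + detect_spots(
        c2_img, psf_sigma, threshold=threshold, threshold_k=threshold_k, channel="C2"
    )
    counts = assign_spots(spots, masks, sample=sample, qc=qc)
    return counts, qc
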