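"""Segmentation, spot detection and spot-to-cell assignment."""

import numpy as np
import pytest

from conftest import match_spots
from deltascope import (
    CellCount,
    DetectedSpot,
    ImageSpec,
    assign_spots,
    detect_spots,
    grid_layout,
    quantify_image,
    render_image,
    segment_cells,
)
from deltascope.imaging import QCLog, SegmentationError


def disc_labels(shape, discs):
    lab = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for value, (cy, cx, r) in discs:
        lab[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = value
    return lab


def test_segment_label_channel_exact_masks(rendered_scene):
    counts, spec, stack, _ = rendered_scene
    masks = segment_cells(stack[0])
    assert len(masks) == 50
    yy, xx = np.mgrid[: spec.height, : spec.width]
    for i, m in enumerate(masks):
        cy, cx, r = spec.cell_layout[i]
        expected = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        assert np.array_equal(m.mask, expected)


def test_segment_blank_channel_empty_list():
    assert segment_cells(np.zeros((64, 64))) == []


def test_segment_excludes_border_touching_cells():
    lab = disc_labels((64, 64), [(1, (5, 32, 10)), (2, (40, 32, 10))])
    qc = QCLog()
    masks = segment_cells(lab, qc=qc)
    assert [m.cell_id for m in masks] == [2]
    assert qc.n_border_excluded == 1


def test_segment_duplicate_label_geometry_is_error():
    # two separate discs sharing one label: corrupt segmentation
    lab = disc_labels((64, 128), [(1, (32, 30, 10)), (1, (32, 90, 10))])
    with pytest.raises(SegmentationError, match="label 1"):
        segment_cells(lab)


def test_detect_blank_image_no_spots():
    assert detect_spots(np.full((64, 64), 50.0), psf_sigma=1.5) == []


def test_detect_rejects_bad_parameters():
    img = np.zeros((32, 32))
    with pytest.raises(ValueError, match="psf_sigma"):
        detect_spots(img, psf_sigma=-1.0)
    with pytest.raises(ValueError, match="threshold"):
        detect_spots(img, psf_sigma=1.5, threshold=0.0)


def test_detect_single_noise_free_spot_within_one_pixel():
    spec = ImageSpec(width=64, height=64, cell_layout=((32.0, 32.0, 20.0),))
    stack, truth = render_image([CellCount("c", "s", 1, 0)], spec, seed=21)
    [spot] = detect_spots(stack[1], psf_sigma=1.5, channel="C1")
    assert np.hypot(spot.x - truth[0].x, spot.y - truth[0].y) <= 1.0


def test_detect_threshold_monotonicity():
    spec = ImageSpec(
        width=220, height=220,
        cell_layout=grid_layout(25, 220, 220, radius=18.0, gap=4.0),
        noise_sigma=60.0,
    )
    cells = [CellCount(f"c{i}", "s", 2, 2) for i in range(25)]
    stack, _ = render_image(cells, spec, seed=8)
    counts = [
        len(detect_spots(stack[1], 1.5, threshold=thr))
        for thr in (50.0, 150.0, 400.0, 900.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_detect_recall_precision_on_noisy_well_separated_spots():
    # ~200 spots, amplitude/noise = 10, separation >= 4 sigma: recall and
    # precision >= 0.95 at the packaged default threshold
    n_cells = 25
    side = 25 * 25
    spec = ImageSpec(
        width=side, height=side,
        cell_layout=grid_layout(n_cells, side, side, radius=55.0, gap=12.0),
        spot_amplitude=1000.0, noise_sigma=100.0, psf_sigma=1.5,
    )
    cells = [CellCount(f"c{i}", "s", 4, 4) for i in range(n_cells)]
    stack, truth = render_image(cells, spec, seed=31)
    detected = detect_spots(stack[1], 1.5, channel="C1") + detect_spots(
        stack[2], 1.5, channel="C2"
    )
    tp = match_spots(detected, truth, radius=2.0)
    assert len(truth) == 200
    assert tp / len(truth) >= 0.95          # recall
    assert tp / max(len(detected), 1) >= 0.95  # precision


def test_channel_independence():
    counts = [CellCount("a", "s", 3, 4)]
    spec = ImageSpec(width=80, height=80, cell_layout=((40.0, 40.0, 25.0),))
    stack, _ = render_image(counts, spec, seed=12)
    alone = detect_spots(stack[1], 1.5, channel="C1")
    zeroed = stack.copy()
    zeroed[2] = 0.0
    q1, _ = quantify_image(stack)
    q2, _ = quantify_image(zeroed)
    assert [c.c1 for c in q1] == [c.c1 for c in q2]
    assert len(alone) == q1[0].c1 == 3


def test_assign_no_spots_yields_zero_records():
    lab = disc_labels((128, 128), [(i + 1, (30 + 60 * (i // 2), 30 + 60 * (i % 2), 12)) for i in range(4)])
    masks = segment_cells(lab)
    counts = assign_spots([], masks)
    assert len(counts) == 4
    assert all(c.c1 == 0 and c.c2 == 0 for c in counts)


def test_assign_boundary_pixel_inclusive_and_discard_bin():
    lab = np.zeros((32, 32), dtype=int)
    lab[10:20, 10:20] = 1
    masks = segment_cells(lab)
    qc = QCLog()
    spots = [
        DetectedSpot(x=10.2, y=19.3, channel="C1", score=1.0),  # boundary pixel
        DetectedSpot(x=2.0, y=2.0, channel="C2", score=1.0),    # outside: discard
    ]
    [count] = assign_spots(spots, masks, qc=qc)
    assert (count.c1, count.c2) == (1, 0)
    assert qc.discarded_spots == {"C2": 1}


def test_end_to_end_noise_free_counts_exact(rendered_scene):
    counts, _, stack, _ = rendered_scene
    quantified, qc = quantify_image(stack, sample="sim")
    assert len(quantified) == len(counts)
    assert [(q.c1, q.c2) for q in quantified] == [(c.c1, c.c2) for c in counts]
    assert qc.discarded_spots == {}


def test_max_cells_limits_in_label_order(rendered_scene):
    _, _, stack, _ = rendered_scene
    quantified, qc = quantify_image(stack, max_cells=10)
    assert len(quantified) == 10 and qc.n_cells == 10
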