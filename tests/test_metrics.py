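"""Dice, tolerance-based centerline counts, sensitivity/specificity, visual scores."""

import numpy as np
import pytest

from tubeval import (
    CenterlineCounts,
    EmptyInputError,
    GridMismatchError,
    MaskRole,
    StructureClass,
    StructureMask,
    ToleranceParams,
    UndefinedMetricError,
    ValidationError,
    VisualScore,
    VolumeGrid,
    aggregate_visual_scores,
    centerline_counts,
    cross_class_tn,
    dice_centerline,
    dice_volumetric,
    sensitivity_centerline,
    specificity_centerline,
)

from conftest import brute_centerline_counts, brute_dice, centerline_from_points


def _mask(grid, idx, cls=StructureClass.PANCREAS, role=MaskRole.CORRECT):
    voxels = np.zeros(grid.shape, bool)
    for i in idx:
        voxels[tuple(i)] = True
    return StructureMask(grid, voxels, cls, role)


# ---------------------------------------------------------------------------
# volumetric Dice


def test_dice_identity_and_disjoint(unit_grid):
    a = _mask(unit_grid, [(1, 1, 1), (1, 2, 1), (3, 3, 3)])
    assert dice_volumetric(a, a).dice == 1.0
    b = _mask(unit_grid, [(8, 8, 8)], role=MaskRole.EXTRACTED)
    assert dice_volumetric(a, b).dice == 0.0


def test_dice_hand_counted_overlap():
    """TP=6, FP=2, FN=2 on a 4x4x4 grid: Dice = 12/16 = 0.75."""
    grid = VolumeGrid((4, 4, 4), (1, 1, 1))
    correct_idx = [(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1), (1, 0, 0), (1, 0, 1), (2, 0, 0), (2, 0, 1)]
    extracted_idx = correct_idx[:6] + [(3, 3, 3), (3, 3, 2)]
    correct = _mask(grid, correct_idx)
    extracted = _mask(grid, extracted_idx, role=MaskRole.EXTRACTED)
    rep = dice_volumetric(correct, extracted)
    assert (rep.confusion.TP, rep.confusion.FP, rep.confusion.FN) == (6, 2, 2)
    assert rep.dice == pytest.approx(0.75)
    assert rep.dice == pytest.approx(brute_dice(correct, extracted))


def test_dice_both_empty_convention(unit_grid):
    empty = _mask(unit_grid, [])
    rep = dice_volumetric(empty, empty)
    assert rep.dice == 1.0
    assert any("convention" in n for n in rep.notes)


def test_dice_is_symmetric(unit_grid):
    rng = np.random.default_rng(11)
    a = StructureMask(unit_grid, rng.random(unit_grid.shape) < 0.3, StructureClass.PANCREAS, MaskRole.CORRECT)
    b = StructureMask(unit_grid, rng.random(unit_grid.shape) < 0.3, StructureClass.PANCREAS, MaskRole.EXTRACTED)
    assert dice_volumetric(a, b).dice == pytest.approx(dice_volumetric(b, a).dice)


def test_grid_mismatch_error_names_spacings(unit_grid):
    other = VolumeGrid(unit_grid.shape, (0.75, 0.75, 1.0))
    a = _mask(unit_grid, [(1, 1, 1)])
    b = _mask(other, [(1, 1, 1)])
    with pytest.raises(GridMismatchError, match=r"0\.75"):
        dice_volumetric(a, b)


# ---------------------------------------------------------------------------
# centerline counts


def _line_centerline(grid, n, radius=1.5, role=MaskRole.CORRECT, offset=(0, 0, 0)):
    pts = [(5 + offset[0], 5 + offset[1], k + offset[2]) for k in range(n)]
    return centerline_from_points(grid, pts, [radius] * n, role)


def test_counts_identity(unit_grid):
    gc = _line_centerline(unit_grid, 10)
    pc = _line_centerline(unit_grid, 10, role=MaskRole.EXTRACTED)
    c = centerline_counts(gc, pc, ToleranceParams(2.0))
    assert (c.TPc, c.FPc, c.FNc) == (10, 0, 0)
    assert dice_centerline(c) == 1.0
    assert sensitivity_centerline(c) == 1.0


def test_counts_translation_within_half_delta(unit_grid):
    """Pc shifted by 0.5 δ along x: every Gc voxel still matches within δ."""
    delta = 2.0
    gc = _line_centerline(unit_grid, 10)
    pc = _line_centerline(unit_grid, 10, role=MaskRole.EXTRACTED, offset=(1, 0, 0))  # 1 mm = 0.5δ
    c = centerline_counts(gc, pc, ToleranceParams(delta), roi_margin_mm=5.0)
    assert c.TPc == 10 and c.FNc == 0 and c.FPc == 0
    tpc, fpc, fnc = brute_centerline_counts(
        gc.points_mm, pc.points_mm, delta, 5.0, gc.points_mm
    )
    assert (c.TPc, c.FPc, c.FNc) == (tpc, fpc, fnc)


def test_counts_match_brute_force_on_random_instance(unit_grid):
    rng = np.random.default_rng(42)
    n_g, n_p = 240, 250
    gc_idx = rng.integers(0, 16, size=(n_g, 3))
    pc_idx = rng.integers(0, 16, size=(n_p, 3))
    gc = centerline_from_points(unit_grid, gc_idx, rng.uniform(0.5, 2, n_g))
    pc = centerline_from_points(unit_grid, pc_idx, rng.uniform(0.5, 2, n_p), MaskRole.EXTRACTED)
    correct_mask = _mask(unit_grid, gc_idx)
    delta, margin = 1.7, 2.3
    c = centerline_counts(gc, pc, ToleranceParams(delta), roi_margin_mm=margin, correct_mask=correct_mask)
    tpc, fpc, fnc = brute_centerline_counts(
        gc.points_mm, pc.points_mm, delta, margin, correct_mask.grid.world_coords(gc_idx)
    )
    assert (c.TPc, c.FPc, c.FNc) == (tpc, fpc, fnc)
    assert c.TPc + c.FNc == len(gc)


def test_far_spurious_branch_outside_roi_excluded():
    """Extracted peripheral vessels outside the correct-mask region do not
    count as false positives — they are excluded from the evaluation."""
    grid = VolumeGrid((40, 12, 12), (1, 1, 1))
    gc_idx = [(k, 5, 5) for k in range(8)]
    gc = centerline_from_points(grid, gc_idx, [1.0] * 8)
    spur = [(k, 5, 5) for k in range(30, 38)]
    pc = centerline_from_points(grid, list(gc_idx) + spur, [1.0] * 16, MaskRole.EXTRACTED)
    correct_mask = _mask(grid, gc_idx)
    c = centerline_counts(gc, pc, ToleranceParams(1.5), roi_margin_mm=2.0, correct_mask=correct_mask)
    assert c.FPc == 0
    assert c.n_pc_excluded == len(spur)
    # without the ROI restriction the spur would be penalized
    c_wide = centerline_counts(gc, pc, ToleranceParams(1.5), roi_margin_mm=100.0, correct_mask=correct_mask)
    assert c_wide.FPc == len(spur)


def test_counts_empty_pc_and_empty_gc(unit_grid):
    gc = _line_centerline(unit_grid, 6)
    pc = centerline_from_points(unit_grid, np.empty((0, 3)), [], MaskRole.EXTRACTED)
    c = centerline_counts(gc, pc, ToleranceParams(1.0))
    assert (c.TPc, c.FPc, c.FNc) == (0, 0, 6)
    with pytest.raises(EmptyInputError):
        centerline_counts(pc, gc, ToleranceParams(1.0))


def test_centerline_dice_is_not_symmetric(unit_grid):
    """δ comes from the correct side and the ROI from the correct mask, so
    swapping roles changes the result."""
    gc = _line_centerline(unit_grid, 12, radius=1.0)
    pc_idx = [(5, 5, k) for k in range(4)] + [(12, 12, k) for k in range(8)]
    pc = centerline_from_points(unit_grid, pc_idx, [1.0] * 12, MaskRole.EXTRACTED)
    tol = ToleranceParams(1.5)
    d_forward = dice_centerline(centerline_counts(gc, pc, tol, roi_margin_mm=30.0))
    d_swapped = dice_centerline(centerline_counts(pc, gc, tol, roi_margin_mm=30.0))
    assert d_forward != d_swapped


def test_dscc_monotone_in_delta(unit_grid):
    rng = np.random.default_rng(3)
    gc = centerline_from_points(unit_grid, rng.integers(0, 16, (60, 3)), np.ones(60))
    pc = centerline_from_points(unit_grid, rng.integers(0, 16, (60, 3)), np.ones(60), MaskRole.EXTRACTED)
    vals = [
        dice_centerline(centerline_counts(gc, pc, ToleranceParams(d), roi_margin_mm=4.0))
        for d in np.linspace(0.5, 8.0, 10)
    ]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


@pytest.mark.parametrize(
    "counts, expected",
    [((10, 0, 0), 1.0), ((0, 5, 5), 0.0), ((8, 2, 2), 0.8)],
)
def test_centerline_dice_arithmetic(counts, expected):
    tpc, fpc, fnc = counts
    c = CenterlineCounts(TPc=tpc, FPc=fpc, FNc=fnc, delta_mm=1.0)
    assert dice_centerline(c) == pytest.approx(expected)


def test_centerline_dice_all_zero_convention():
    assert dice_centerline(CenterlineCounts(0, 0, 0, delta_mm=1.0)) == 1.0


@pytest.mark.parametrize("tpc, fnc, expected", [(10, 0, 1.0), (0, 7, 0.0), (17, 3, 0.85)])
def test_sensitivity_arithmetic(tpc, fnc, expected):
    c = CenterlineCounts(TPc=tpc, FPc=0, FNc=fnc, delta_mm=1.0)
    assert sensitivity_centerline(c) == pytest.approx(expected)


def test_sensitivity_undefined_when_gc_empty():
    with pytest.raises(UndefinedMetricError):
        sensitivity_centerline(CenterlineCounts(0, 3, 0, delta_mm=1.0))


# ---------------------------------------------------------------------------
# cross-class true negatives and specificity


def test_cross_class_tn_separation_and_confusion(unit_grid):
    artery_pc = _line_centerline(unit_grid, 10, role=MaskRole.EXTRACTED)
    far_vein = centerline_from_points(
        unit_grid, [(14, 14, k) for k in range(10)], np.ones(10)
    )
    tol = ToleranceParams(2.0)
    assert cross_class_tn(artery_pc, far_vein, tol) == 10  # full separation
    on_top = centerline_from_points(unit_grid, artery_pc.voxels, np.ones(10))
    assert cross_class_tn(artery_pc, on_top, tol) == 0  # full confusion


def test_cross_class_tn_mixed_counts_match_brute_force(unit_grid):
    """7 of 10 artery centers lie beyond δ of the vein centerline."""
    delta = 2.0
    vein_gc = centerline_from_points(unit_grid, [(5, 5, k) for k in range(16)], np.ones(16))
    near = [(5, 6, k) for k in range(3)]  # 1 mm away: within δ
    far = [(5, 12, k) for k in range(7)]  # 7 mm away: beyond δ
    artery_pc = centerline_from_points(unit_grid, near + far, np.ones(10), MaskRole.EXTRACTED)
    tn = cross_class_tn(artery_pc, vein_gc, ToleranceParams(delta))
    assert tn == 7
    d = np.sqrt(((artery_pc.points_mm[:, None] - vein_gc.points_mm[None]) ** 2).sum(-1)).min(1)
    assert tn == int(np.sum(d >= delta))


def test_cross_class_tn_against_mask_and_empty_pc(unit_grid):
    vein_mask = _mask(unit_grid, [(5, 5, k) for k in range(16)], StructureClass.VEIN)
    artery_pc = centerline_from_points(unit_grid, [(5, 12, 4)], [1.0], MaskRole.EXTRACTED)
    assert cross_class_tn(artery_pc, vein_mask, ToleranceParams(2.0)) == 1
    empty = centerline_from_points(unit_grid, np.empty((0, 3)), [], MaskRole.EXTRACTED)
    assert cross_class_tn(empty, vein_mask, ToleranceParams(2.0)) == 0


@pytest.mark.parametrize("tnc, fnc, expected", [(10, 0, 1.0), (0, 5, 0.0), (41, 9, 0.82)])
def test_specificity_as_printed(tnc, fnc, expected):
    assert specificity_centerline(tnc, fnc=fnc) == pytest.approx(expected)


def test_specificity_conventional_form_behind_flag():
    assert specificity_centerline(30, fpc=10, form="conventional") == pytest.approx(0.75)
    with pytest.raises(ValidationError):
        specificity_centerline(30, form="conventional")  # needs FPc
    with pytest.raises(UndefinedMetricError):
        specificity_centerline(0, fnc=0)


# ---------------------------------------------------------------------------
# visual scores


def test_visual_score_aggregation_arithmetic():
    scores = [VisualScore("IPDA", s) for s in (1.0, 1.0, 0.5, 0.0)]
    out = aggregate_visual_scores(scores)
    assert out.loc[0, "mean_score"] == pytest.approx(0.625)
    assert out.loc[0, "n"] == 4
    allones = [VisualScore("LGV", 1.0) for _ in range(5)]
    assert aggregate_visual_scores(allones)["mean_score"].iloc[0] == 1.0


def test_visual_score_simulated_mean_near_expectation():
    rng = np.random.default_rng(17)
    draws = rng.choice([1.0, 0.5], size=100, p=[0.9, 0.1])
    scores = [VisualScore("ASPDV", float(s), group="pancreatic_cancer") for s in draws]
    out = aggregate_visual_scores(scores, by="group")
    assert 0.9 <= out["mean_score"].iloc[0] <= 1.0  # expectation 0.95


def test_visual_score_validation():
    with pytest.raises(ValidationError):
        VisualScore("GDA", 0.7)
    with pytest.raises(ValidationError):
        aggregate_visual_scores([VisualScore("GDA", 1.0)], by="rater")
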