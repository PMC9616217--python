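"""Volumetric Dice, tolerance-based centerline Dice, sensitivity, specificity.

The volumetric Dice similarity coefficient is DSC = 2·TP/(2·TP+FP+FN) over
voxels.  For thin tubular structures volumetric overlap is unforgiving, so
the centerline variant matches center-voxel sets Gc (correct) and Pc
(extracted) within a distance tolerance δ, in world mm:

- TPc: Gc voxels whose distance to Pc is < δ,
- FNc: the complement (distance ≥ δ), so TPc + FNc = |Gc| exactly,
- FPc: Pc voxels at distance ≥ δ from Gc, counted only inside the
  evaluation ROI (the correct mask dilated by a margin) — extracted
  peripheral vessels outside the clinically annotated region are excluded
  rather than penalized,
- DSCc = 2·TPc/(2·TPc+FPc+FNc), Sens = TPc/(TPc+FNc).

Specificity uses a cross-structure true negative: an extracted center voxel
of one vessel class counts as TNc when it is at least the *other* class's δ
away from that other class's correct structure (an artery center correctly
not attributable to the vein tree, and vice versa).  The headline form is
Spec = TNc/(TNc+FNc) as reported in this evaluation protocol; the
conventional TNc/(TNc+FPc) is available behind ``form="conventional"`` and
the form used is always recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .centerline import CenterlineSet, ToleranceParams
from .errors import (
    EmptyInputError,
    GridMismatchError,
    UndefinedMetricError,
    ValidationError,
)
from .model import ConfusionCounts, StructureMask

VALID_VISUAL_SCORES = (1.0, 0.5, 0.0)


@dataclass(frozen=True)
class CenterlineCounts:
    """Tolerance-matched centerline tallies plus the δ and ROI margin used."""

    TPc: int
    FPc: int
    FNc: int
    delta_mm: float
    TNc: Optional[int] = None
    roi_margin_mm: float = 0.0
    n_pc_excluded: int = 0  # Pc voxels outside the evaluation ROI

    def __post_init__(self) -> None:
        if min(self.TPc, self.FPc, self.FNc) < 0 or (self.TNc is not None and self.TNc < 0):
            raise ValidationError("centerline counts must be non-negative")
        if self.delta_mm <= 0:
            raise ValidationError("delta_mm must be > 0")
        if self.roi_margin_mm < 0:
            raise ValidationError("roi_margin_mm must be >= 0")


@dataclass
class MetricReport:
    """Per-structure metric bundle; the row content of Table-style outputs."""

    dice: Optional[float] = None
    dice_centerline: Optional[float] = None
    sens: Optional[float] = None
    spec: Optional[float] = None
    specificity_form: Optional[str] = None
    confusion: Optional[ConfusionCounts] = None
    centerline_counts: Optional[CenterlineCounts] = None
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out: dict = {
            "dice": self.dice,
            "dice_centerline": self.dice_centerline,
            "sens": self.sens,
            "spec": self.spec,
            "specificity_form": self.specificity_form,
        }
        if self.confusion is not None:
            out["confusion"] = {"TP": self.confusion.TP, "FP": self.confusion.FP, "FN": self.confusion.FN}
        if self.centerline_counts is not None:
            c = self.centerline_counts
            out["centerline_counts"] = {
                "TPc": c.TPc, "FPc": c.FPc, "FNc": c.FNc, "TNc": c.TNc,
                "delta_mm": c.delta_mm, "roi_margin_mm": c.roi_margin_mm,
                "n_pc_excluded": c.n_pc_excluded,
            }
        if self.notes:
            out["notes"] = list(self.notes)
        return out


@dataclass(frozen=True)
class VisualScore:
    """Surgeon-assigned three-stage score for one vessel: 1.0 fully
    extracted, 0.5 interrupted or branch-only, 0.0 missed."""

    vessel_label: str
    score: float
    rater_id: str = "rater1"
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.score not in VALID_VISUAL_SCORES:
            raise ValidationError(
                f"visual score must be one of {VALID_VISUAL_SCORES}, got {self.score}"
            )


def _require_same_grid(a, b) -> None:
    if not a.grid.approx_equal(b.grid):
        raise GridMismatchError(
            f"masks are not on the same grid: shape/spacing {a.grid.shape}/{a.grid.spacing} "
            f"vs {b.grid.shape}/{b.grid.spacing}"
        )


def dice_volumetric(correct: StructureMask, extracted: StructureMask) -> MetricReport:
    """Voxelwise Dice between a correct and an extracted mask.

    Both masks empty is reported as Dice 1.0 (nothing to find, nothing
    found); the convention is flagged in the report notes.
    """
    _require_same_grid(correct, extracted)
    tp = int(np.count_nonzero(correct.voxels & extracted.voxels))
    fp = int(np.count_nonzero(~correct.voxels & extracted.voxels))
    fn = int(np.count_nonzero(correct.voxels & ~extracted.voxels))
    counts = ConfusionCounts(TP=tp, FP=fp, FN=fn)
    denom = 2 * tp + fp + fn
    report = MetricReport(confusion=counts)
    if denom == 0:
        report.dice = 1.0
        report.notes.append("both masks empty: Dice defined as 1.0 by convention")
    else:
        report.dice = 2.0 * tp / denom
    return report


def _min_dist_to_set(query_pts: np.ndarray, ref_pts: np.ndarray) -> np.ndarray:
    if len(ref_pts) == 0:
        return np.full(len(query_pts), np.inf)
    tree = cKDTree(ref_pts)
    d, _ = tree.query(query_pts, k=1)
    return np.asarray(d, float)


def _roi_membership(
    pc: CenterlineSet,
    gc: CenterlineSet,
    roi_margin_mm: float,
    correct_mask: Optional[StructureMask],
) -> np.ndarray:
    """Boolean membership of Pc points in the FPc-evaluation ROI.

    With the correct mask available the ROI is the mask volume dilated by
    the margin (membership = spacing-aware distance to the mask ≤ margin).
    Without it, the mask is approximated by the union of maximum inscribed
    spheres along Gc: a Pc point is inside when its distance to some Gc
    voxel is ≤ that voxel's radius + margin.
    """
    pts = pc.points_mm
    if correct_mask is not None:
        if correct_mask.is_empty:
            return np.zeros(len(pts), dtype=bool)
        # distance (mm) from every voxel to the correct mask
        dist = ndimage.distance_transform_edt(
            ~correct_mask.voxels, sampling=correct_mask.grid.spacing
        )
        return dist[tuple(pc.voxels.T)] <= roi_margin_mm
    tree = cKDTree(gc.points_mm)
    # conservative upper bound on relevant neighbours
    reach = float(np.max(gc.radius_mm)) + roi_margin_mm
    inside = np.zeros(len(pts), dtype=bool)
    for i, p in enumerate(pts):
        for j in tree.query_ball_point(p, reach):
            if np.linalg.norm(p - gc.points_mm[j]) <= gc.radius_mm[j] + roi_margin_mm:
                inside[i] = True
                break
    return inside


def centerline_counts(
    gc: CenterlineSet,
    pc: CenterlineSet,
    tol: ToleranceParams,
    roi_margin_mm: Optional[float] = None,
    correct_mask: Optional[StructureMask] = None,
) -> CenterlineCounts:
    """Tolerance-matched TPc/FPc/FNc between correct and extracted centerlines.

    Distances are Euclidean in world mm.  TPc counts Gc voxels strictly
    within δ of Pc; the complement (≥ δ) is FNc, so TPc+FNc=|Gc|.  FPc
    counts Pc voxels at ≥ δ from Gc, restricted to the evaluation ROI
    (``roi_margin_mm`` defaults to δ); Pc voxels outside the ROI are
    excluded entirely and tallied in ``n_pc_excluded``.
    """
    if len(gc) == 0:
        raise EmptyInputError("Gc (correct centerline) must be non-empty")
    if not gc.grid.approx_equal(pc.grid):
        raise GridMismatchError(
            f"centerlines are not on the same grid: spacing {gc.grid.spacing} vs {pc.grid.spacing}"
        )
    delta = tol.delta_mm
    margin = delta if roi_margin_mm is None else float(roi_margin_mm)
    if margin < 0:
        raise ValidationError("roi_margin_mm must be >= 0")

    if len(pc) == 0:
        return CenterlineCounts(
            TPc=0, FPc=0, FNc=len(gc), delta_mm=delta, roi_margin_mm=margin
        )
    d_gc = _min_dist_to_set(gc.points_mm, pc.points_mm)
    tpc = int(np.count_nonzero(d_gc < delta))
    fnc = len(gc) - tpc

    in_roi = _roi_membership(pc, gc, margin, correct_mask)
    d_pc = _min_dist_to_set(pc.points_mm[in_roi], gc.points_mm)
    fpc = int(np.count_nonzero(d_pc >= delta))
    return CenterlineCounts(
        TPc=tpc,
        FPc=fpc,
        FNc=fnc,
        delta_mm=delta,
        roi_margin_mm=margin,
        n_pc_excluded=int(np.count_nonzero(~in_roi)),
    )


def dice_centerline(counts: CenterlineCounts) -> float:
    """DSCc = 2·TPc/(2·TPc+FPc+FNc); all-zero counts → 1.0 by convention."""
    denom = 2 * counts.TPc + counts.FPc + counts.FNc
    if denom == 0:
        return 1.0
    return 2.0 * counts.TPc / denom


def sensitivity_centerline(counts: CenterlineCounts) -> float:
    """Sens = TPc/(TPc+FNc), the matched fraction of the correct centerline."""
    denom = counts.TPc + counts.FNc
    if denom == 0:
        raise UndefinedMetricError("sensitivity undefined: TPc+FNc = 0")
    return counts.TPc / denom


def cross_class_tn(
    pc_this: CenterlineSet,
    gc_other: Union[CenterlineSet, StructureMask],
    tol_other: ToleranceParams,
) -> int:
    """Count extracted center voxels of one class correctly NOT attributable
    to the other class.

    A Pc voxel of this class (say artery) is a true negative when its world
    distance to the other class's correct structure (vein centerline or
    mask) is at least the other class's δ.  An empty Pc yields 0.
    """
    if len(pc_this) == 0:
        return 0
    if not pc_this.grid.approx_equal(gc_other.grid):
        raise GridMismatchError(
            f"grids differ: spacing {pc_this.grid.spacing} vs {gc_other.grid.spacing}"
        )
    pts = pc_this.points_mm
    if isinstance(gc_other, StructureMask):
        if gc_other.is_empty:
            return len(pc_this)
        dist = ndimage.distance_transform_edt(~gc_other.voxels, sampling=gc_other.grid.spacing)
        # distance 0 inside the mask; EDT measures center-to-center distances
        d = dist[tuple(pc_this.voxels.T)]
    else:
        d = _min_dist_to_set(pts, gc_other.points_mm)
    return int(np.count_nonzero(d >= tol_other.delta_mm))


def specificity_centerline(
    tnc: int, fnc: Optional[int] = None, fpc: Optional[int] = None, form: str = "as_printed"
) -> float:
    """Cross-structure specificity.

    ``form="as_printed"`` computes TNc/(TNc+FNc), the form this evaluation
    protocol reports; ``form="conventional"`` computes the textbook
    TNc/(TNc+FPc).  The caller should record which form was used.
    """
    if form == "as_printed":
        if fnc is None:
            raise ValidationError("as_printed specificity requires FNc")
        denom = tnc + fnc
    elif form == "conventional":
        if fpc is None:
            raise ValidationError("conventional specificity requires FPc")
        denom = tnc + fpc
    else:
        raise ValidationError(f"unknown specificity form {form!r}")
    if denom == 0:
        raise UndefinedMetricError(f"specificity ({form}) undefined: zero denominator")
    return tnc / denom


def aggregate_visual_scores(
    scores: Sequence[VisualScore], by: str = "vessel_label"
) -> pd.DataFrame:
    """Mean three-stage score per vessel label or per group, with counts."""
    if by not in ("vessel_label", "group"):
        raise ValidationError(f"unknown aggregation key {by!r}")
    for s in scores:
        if s.score not in VALID_VISUAL_SCORES:  # defensive: frozen dataclass validates too
            raise ValidationError(f"invalid visual score {s.score}")
    frame = pd.DataFrame(
        {
            "vessel_label": [s.vessel_label for s in scores],
            "group": [s.group for s in scores],
            "score": [s.score for s in scores],
        }
    )
    if frame.empty:
        return pd.DataFrame(columns=[by, "mean_score", "n"])
    out = frame.groupby(by, dropna=False)["score"].agg(mean_score="mean", n="count")
    return out.reset_index()
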