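"""Per-case evaluation pipeline: masks in, metric reports out.

For each structure class the volumetric Dice is computed; tubular classes
(duct, artery, vein) additionally get the tolerance-based centerline
metrics.  The artery/vein specificity is cross-structural: extracted artery
centers are tested against the correct *vein* structure (and vice versa),
using the other class's δ.  The mask-derived main-duct diameter is twice
the mean inscribed radius along the extracted duct centerline.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .centerline import CenterlineSet, ToleranceParams, estimate_delta, measure_diameter, skeletonize
from .errors import ValidationError
from .metrics import (
    MetricReport,
    centerline_counts,
    cross_class_tn,
    dice_centerline,
    dice_volumetric,
    sensitivity_centerline,
    specificity_centerline,
)
from .model import MaskRole, StructureClass, StructureMask, TUBULAR_CLASSES

#: cross-structure partner used for the specificity true negatives
_SPEC_PARTNER = {StructureClass.ARTERY: StructureClass.VEIN, StructureClass.VEIN: StructureClass.ARTERY}


@dataclass
class EvalConfig:
    """Knobs of the evaluation protocol, all recorded in every output."""

    delta_mode: str = "auto_from_correct"
    delta_mm: Optional[float] = None  # required when delta_mode == "fixed"
    roi_margin_mm: Optional[float] = None  # None -> margin = delta
    specificity_form: str = "as_printed"  # or "conventional"
    prune_below_mm: Optional[float] = None
    diameter_summary: str = "mean"

    def __post_init__(self) -> None:
        if self.delta_mode not in ("auto_from_correct", "fixed"):
            raise ValidationError(f"unknown delta_mode {self.delta_mode!r}")
        if self.delta_mode == "fixed" and (self.delta_mm is None or self.delta_mm <= 0):
            raise ValidationError("delta_mode='fixed' requires delta_mm > 0")
        if self.specificity_form not in ("as_printed", "conventional"):
            raise ValidationError(f"unknown specificity_form {self.specificity_form!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CaseEvaluation:
    reports: dict = field(default_factory=dict)  # class value -> MetricReport
    measured_duct_diameter_mm: Optional[float] = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "measured_duct_diameter_mm": self.measured_duct_diameter_mm,
            "metrics": {cls: rep.to_dict() for cls, rep in self.reports.items()},
        }


def _empty_centerline(like: StructureMask) -> CenterlineSet:
    return CenterlineSet(
        grid=like.grid,
        voxels=np.empty((0, 3), dtype=int),
        radius_mm=np.empty(0),
        source_role=like.role,
    )


def _skeleton_or_empty(mask: StructureMask, prune_below_mm: Optional[float]) -> CenterlineSet:
    if mask.is_empty:
        return _empty_centerline(mask)
    return skeletonize(mask, prune_below_mm=prune_below_mm)


def evaluate_case(
    masks: dict[StructureClass, tuple[StructureMask, StructureMask]],
    config: Optional[EvalConfig] = None,
) -> CaseEvaluation:
    """Evaluate one case's correct/extracted pairs.

    ``masks`` maps each structure class to its (correct, extracted) pair on
    a shared grid.  Classes may be missing; specificity is only reported
    when the cross-class partner's correct mask is present.
    """
    config = config or EvalConfig()
    out = CaseEvaluation(config=config.to_dict())

    # pre-extract centerlines and tolerances of the tubular correct masks so
    # cross-class specificity can reuse them
    skeletons: dict[StructureClass, dict] = {}
    for cls in TUBULAR_CLASSES:
        if cls not in masks:
            continue
        correct, extracted = masks[cls]
        gc = _skeleton_or_empty(correct, config.prune_below_mm)
        pc = _skeleton_or_empty(extracted, config.prune_below_mm)
        tol = None
        if len(gc):
            tol = (
                ToleranceParams(config.delta_mm, "fixed")
                if config.delta_mode == "fixed"
                else estimate_delta(gc)
            )
        skeletons[cls] = {"gc": gc, "pc": pc, "tol": tol, "correct": correct}

    for cls, (correct, extracted) in masks.items():
        report = dice_volumetric(correct, extracted)
        if cls in skeletons and skeletons[cls]["tol"] is not None:
            gc, pc, tol = skeletons[cls]["gc"], skeletons[cls]["pc"], skeletons[cls]["tol"]
            counts = centerline_counts(
                gc, pc, tol, roi_margin_mm=config.roi_margin_mm, correct_mask=correct
            )
            report.dice_centerline = dice_centerline(counts)
            report.sens = sensitivity_centerline(counts)
            partner = _SPEC_PARTNER.get(cls)
            if partner is not None and partner in skeletons and skeletons[partner]["tol"] is not None:
                tnc = cross_class_tn(pc, skeletons[partner]["correct"], skeletons[partner]["tol"])
                counts = type(counts)(
                    TPc=counts.TPc, FPc=counts.FPc, FNc=counts.FNc, TNc=tnc,
                    delta_mm=counts.delta_mm, roi_margin_mm=counts.roi_margin_mm,
                    n_pc_excluded=counts.n_pc_excluded,
                )
                report.spec = specificity_centerline(
                    tnc, fnc=counts.FNc, fpc=counts.FPc, form=config.specificity_form
                ) if (tnc + (counts.FNc if config.specificity_form == "as_printed" else counts.FPc)) > 0 else None
                report.specificity_form = config.specificity_form
            report.centerline_counts = counts
        out.reports[cls.value] = report

    if StructureClass.DUCT in skeletons and len(skeletons[StructureClass.DUCT]["pc"]):
        out.measured_duct_diameter_mm = measure_diameter(
            skeletons[StructureClass.DUCT]["pc"], summary=config.diameter_summary
        )
    return out
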