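"""Core data model: grids, masks, confusion counts and case records.

The geometric frame is a :class:`VolumeGrid` — a 3D voxel lattice with
anisotropic spacing in mm (clinical CT series in this setting have in-plane
spacing around 0.75 mm and slice widths of 0.75–1.00 mm).  Axis order is
fixed internally as ``(x, y, z)``; readers normalize file orientation to
this convention so downstream distance computations are orientation
independent.  Voxel coordinates are 0-based indices and world coordinates
are voxel-center positions in mm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

#: Grids are considered equal when spacing and origin agree within this (mm).
GRID_TOL_MM = 1e-6


class StructureClass(str, enum.Enum):
    """Anatomical structure a mask segments."""

    PANCREAS = "pancreas"
    DUCT = "duct"
    ARTERY = "artery"
    VEIN = "vein"
    TUMOR = "tumor"
    OTHER = "other"


#: Structure classes evaluated with the tolerance-based centerline metrics.
TUBULAR_CLASSES = (StructureClass.DUCT, StructureClass.ARTERY, StructureClass.VEIN)


class MaskRole(str, enum.Enum):
    """Whether a mask is the expert ground truth or the engine output."""

    CORRECT = "correct"
    EXTRACTED = "extracted"


class Group(str, enum.Enum):
    PANCREATIC_CANCER = "pancreatic_cancer"
    CONTROL = "control"


class Location(str, enum.Enum):
    HEAD = "head"
    BODY = "body"
    TAIL = "tail"


#: UICC stage labels accepted in cohort tables.
STAGES = ("0", "IA", "IB", "IIA", "IIB", "III", "IV")


@dataclass(frozen=True)
class VolumeGrid:
    """Shape, spacing and origin of a voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels per axis, order ``(x, y, z)``; all entries >= 1.
    spacing
        mm per voxel per axis; all entries > 0.
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValidationError("VolumeGrid requires 3D shape/spacing/origin")
        if any(s < 1 for s in self.shape):
            raise ValidationError(f"grid shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"grid spacing must be > 0 mm, got {self.spacing}")

    def approx_equal(self, other: "VolumeGrid", tol_mm: float = GRID_TOL_MM) -> bool:
        """Two grids are comparable iff shapes match and spacing/origin agree within ``tol_mm``."""
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol_mm for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol_mm for a, b in zip(self.origin, other.origin))
        )

    @property
    def min_spacing(self) -> float:
        return min(self.spacing)

    @property
    def voxel_diagonal_mm(self) -> float:
        """Length of one voxel's body diagonal in mm."""
        return float(np.linalg.norm(self.spacing))

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map integer voxel indices ``(N, 3)`` to world mm coordinates ``(N, 3)``."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


@dataclass
class StructureMask:
    """One binary 3D mask for one structure class on a shared grid."""

    grid: VolumeGrid
    voxels: np.ndarray
    structure_class: StructureClass
    role: MaskRole

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.structure_class = StructureClass(self.structure_class)
        self.role = MaskRole(self.role)
        if self.voxels.shape != self.grid.shape:
            raise ValidationError(
                f"mask shape {self.voxels.shape} does not match grid shape {self.grid.shape}"
            )

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def indices(self) -> np.ndarray:
        """Integer voxel indices of the foreground, shape ``(N, 3)``."""
        return np.argwhere(self.voxels)


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise confusion counts between a correct and an extracted mask."""

    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValidationError("confusion counts must be non-negative")


# CaseRecord metric slots are nested per structure class, e.g.
# record.metrics["duct"]["dice_centerline"].
_METRIC_SLOTS = ("dice", "dice_centerline", "sens", "spec")


@dataclass
class CaseRecord:
    """Per-case covariates plus computed metrics; the row type of cohort tables.

    Tumor covariates are only meaningful in the pancreatic-cancer group;
    control records must leave them unset.
    """

    case_id: str
    group: Group
    tumor_size_mm: Optional[float] = None
    location: Optional[Location] = None
    stage: Optional[str] = None
    manual_duct_diameter_mm: Optional[float] = None
    measured_duct_diameter_mm: Optional[float] = None
    metrics: dict = field(default_factory=dict)
    visual_scores: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValidationError("case_id must be a non-empty string")
        self.group = Group(self.group)
        if self.location is not None:
            self.location = Location(self.location)
        if self.stage is not None:
            stage = str(self.stage)
            if stage not in STAGES:
                raise ValidationError(f"unknown stage {stage!r}; expected one of {STAGES}")
            self.stage = stage
        if self.group is Group.CONTROL:
            if any(v is not None for v in (self.tumor_size_mm, self.location, self.stage)):
                raise ValidationError(
                    f"case {self.case_id}: control cases must not carry tumor covariates"
                )
        if self.tumor_size_mm is not None and self.tumor_size_mm < 0:
            raise ValidationError(f"case {self.case_id}: tumor_size_mm must be >= 0")
        for name in ("manual_duct_diameter_mm", "measured_duct_diameter_mm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"case {self.case_id}: {name} must be > 0")
        for cls, slots in self.metrics.items():
            for slot, value in slots.items():
                if slot in _METRIC_SLOTS and value is not None and not 0.0 <= value <= 1.0:
                    raise ValidationError(
                        f"case {self.case_id}: metric {cls}.{slot}={value} outside [0, 1]"
                    )
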