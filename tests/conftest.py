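"""Shared fixtures: analytic tube masks and brute-force distance oracles.

The oracles here are deliberately naive (all-pairs numpy distances, python
set arithmetic) so they stay independent of the KD-tree / distance-transform
implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from tubeval import (
    CenterlineSet,
    MaskRole,
    StructureClass,
    StructureMask,
    VolumeGrid,
)


def make_cylinder(
    radius_mm: float,
    length_mm: float = 40.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    structure_class: StructureClass = StructureClass.DUCT,
    role: MaskRole = MaskRole.CORRECT,
    pad_vox: int = 3,
) -> StructureMask:
    """Axis-aligned (z) solid cylinder centered on a voxel column.

    The cross-section grid has odd extent so the true axis passes through
    voxel centers; a voxel belongs to the tube when its center lies within
    ``radius_mm`` of the axis.
    """
    half_vox = int(np.ceil(radius_mm / min(spacing[0], spacing[1]))) + pad_vox
    nx = ny = 2 * half_vox + 1
    nz = int(round(length_mm / spacing[2]))
    grid = VolumeGrid((nx, ny, nz), spacing)
    x = (np.arange(nx) - half_vox) * spacing[0]
    y = (np.arange(ny) - half_vox) * spacing[1]
    xx, yy = np.meshgrid(x, y, indexing="ij")
    disc = (xx**2 + yy**2) <= radius_mm**2
    voxels = np.repeat(disc[:, :, None], nz, axis=2)
    return StructureMask(grid, voxels, structure_class, role)


def cylinder_axis_indices(mask: StructureMask) -> np.ndarray:
    """Voxel indices of the analytic axis of a make_cylinder mask."""
    cx = (mask.grid.shape[0] - 1) // 2
    return np.array([[cx, cx, k] for k in range(mask.grid.shape[2])])


def centerline_from_points(
    grid: VolumeGrid, voxels, radii, role: MaskRole = MaskRole.CORRECT
) -> CenterlineSet:
    return CenterlineSet(
        grid=grid,
        voxels=np.asarray(voxels, int).reshape(-1, 3),
        radius_mm=np.asarray(radii, float).reshape(-1),
        source_role=role,
    )


# ---------------------------------------------------------------------------
# brute-force oracles


def pairwise_min_dist(a_pts: np.ndarray, b_pts: np.ndarray) -> np.ndarray:
    """Min distance from each point in a to the set b, by full pairwise matrix."""
    a_pts = np.atleast_2d(a_pts)
    b_pts = np.atleast_2d(b_pts)
    if len(b_pts) == 0:
        return np.full(len(a_pts), np.inf)
    d = np.sqrt(((a_pts[:, None, :] - b_pts[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1)


def brute_centerline_counts(
    gc_pts_mm: np.ndarray,
    pc_pts_mm: np.ndarray,
    delta_mm: float,
    roi_margin_mm: float,
    correct_mask_pts_mm: np.ndarray,
) -> tuple[int, int, int]:
    """All-pairs reference for (TPc, FPc, FNc).

    TPc: Gc points strictly within delta of Pc; FNc the complement.  FPc:
    Pc points at >= delta from Gc, counted only when within roi_margin of
    the correct-mask voxel centers.
    """
    d_gc = pairwise_min_dist(gc_pts_mm, pc_pts_mm)
    tpc = int(np.sum(d_gc < delta_mm))
    fnc = len(gc_pts_mm) - tpc
    if len(pc_pts_mm) == 0:
        return tpc, 0, fnc
    in_roi = pairwise_min_dist(pc_pts_mm, correct_mask_pts_mm) <= roi_margin_mm
    d_pc = pairwise_min_dist(pc_pts_mm[in_roi], gc_pts_mm)
    fpc = int(np.sum(d_pc >= delta_mm))
    return tpc, fpc, fnc


def brute_dice(correct: StructureMask, extracted: StructureMask) -> float:
    """Set-arithmetic Dice reference (python sets of voxel index tuples)."""
    a = set(map(tuple, np.argwhere(correct.voxels)))
    b = set(map(tuple, np.argwhere(extracted.voxels)))
    tp = len(a & b)
    denom = 2 * tp + len(b - a) + len(a - b)
    return 1.0 if denom == 0 else 2 * tp / denom


@pytest.fixture(scope="session")
def unit_grid() -> VolumeGrid:
    return VolumeGrid((16, 16, 16), (1.0, 1.0, 1.0))
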