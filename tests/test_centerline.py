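"""Centerline extraction, δ estimation and diameter measurement."""

import numpy as np
import pytest
from scipy import ndimage

from tubeval import (
    EmptyInputError,
    MaskRole,
    StructureClass,
    StructureMask,
    ValidationError,
    VolumeGrid,
    estimate_delta,
    measure_diameter,
    skeletonize,
)
from tubeval.centerline import CONN_26

from conftest import make_cylinder


def _single_voxel_mask(spacing=(0.75, 0.75, 1.0)):
    grid = VolumeGrid((5, 5, 5), spacing)
    voxels = np.zeros(grid.shape, bool)
    voxels[2, 2, 2] = True
    return StructureMask(grid, voxels, StructureClass.DUCT, MaskRole.CORRECT)


def test_single_voxel_degenerate_tube():
    mask = _single_voxel_mask()
    cl = skeletonize(mask)
    assert len(cl) == 1
    assert tuple(cl.voxels[0]) == (2, 2, 2)
    half_min = 0.5 * min(mask.grid.spacing)
    assert cl.radius_mm[0] == pytest.approx(half_min)
    assert estimate_delta(cl).delta_mm == pytest.approx(half_min)  # mean of one
    assert measure_diameter(cl, "mean") == pytest.approx(min(mask.grid.spacing))


def test_skeletonize_empty_mask_raises():
    grid = VolumeGrid((4, 4, 4), (1, 1, 1))
    empty = StructureMask(grid, np.zeros(grid.shape, bool), StructureClass.DUCT, MaskRole.CORRECT)
    with pytest.raises(EmptyInputError):
        skeletonize(empty)


def test_cylinder_centerline_tracks_analytic_axis():
    """Centerline of a solid r=2 mm, 40 mm cylinder stays within 1 voxel of the axis."""
    mask = make_cylinder(2.0, length_mm=40, spacing=(1, 1, 1))
    cl = skeletonize(mask)
    axis_xy = (mask.grid.shape[0] - 1) // 2
    dev = np.abs(cl.voxels[:, :2] - axis_xy).max()
    assert dev <= 1.0
    assert cl.to_mask_array()[mask.voxels.__invert__()].sum() == 0  # inside the mask


def test_two_disjoint_cylinders_give_two_components():
    m1 = make_cylinder(1.5, length_mm=20, spacing=(1, 1, 1))
    n = m1.grid.shape[0]
    grid = VolumeGrid((2 * n + 4, n, m1.grid.shape[2]), (1, 1, 1))
    voxels = np.zeros(grid.shape, bool)
    voxels[:n] = m1.voxels
    voxels[n + 4:] = m1.voxels
    mask = StructureMask(grid, voxels, StructureClass.ARTERY, MaskRole.CORRECT)
    cl = skeletonize(mask)
    # flood-fill oracle on the centerline voxel set
    _, n_comp = ndimage.label(cl.to_mask_array(), structure=CONN_26)
    assert n_comp == 2


@pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (0.75, 0.75, 1.0)])
@pytest.mark.parametrize("radius", [1.0, 2.0, 3.0, 4.0])
def test_delta_and_diameter_recovery_on_cylinders(radius, spacing):
    mask = make_cylinder(radius, length_mm=40, spacing=spacing)
    cl = skeletonize(mask)
    tol = estimate_delta(cl)
    assert tol.delta_mode == "auto_from_correct"
    assert tol.delta_mm == pytest.approx(radius, abs=0.5 * min(spacing))
    diam = measure_diameter(cl, "mean")
    assert diam == pytest.approx(2 * radius, abs=float(np.linalg.norm(spacing)))


def test_delta_of_two_unequal_tubes_is_voxelwise_mean():
    """Two equal-length tubes r=1 and r=3 average to ~2 mm, matching a
    brute-force average of the radius map."""
    thin = make_cylinder(1.0, length_mm=30, spacing=(1, 1, 1), pad_vox=6)
    thick = make_cylinder(3.0, length_mm=30, spacing=(1, 1, 1), pad_vox=4)
    n = thin.grid.shape[0]
    assert thick.grid.shape[0] == n  # same cross-section extent by construction
    grid = VolumeGrid((2 * n + 6, n, thin.grid.shape[2]), (1, 1, 1))
    voxels = np.zeros(grid.shape, bool)
    voxels[:n] = thin.voxels
    voxels[n + 6:] = thick.voxels
    mask = StructureMask(grid, voxels, StructureClass.VEIN, MaskRole.CORRECT)
    cl = skeletonize(mask)
    brute_mean = sum(float(r) for r in cl.radius_mm) / len(cl)
    est = estimate_delta(cl).delta_mm
    assert est == pytest.approx(brute_mean)
    assert est == pytest.approx(2.0, abs=0.5)


def test_tapered_tube_max_diameter():
    """Tube tapering 1→3 mm: max diameter ≈ 6 mm within one voxel step."""
    spacing = (1.0, 1.0, 1.0)
    nz = 40
    grid = VolumeGrid((11, 11, nz), spacing)
    x = (np.arange(11) - 5)[:, None, None]
    y = (np.arange(11) - 5)[None, :, None]
    r_z = np.linspace(1.0, 3.0, nz)[None, None, :]
    voxels = (x**2 + y**2) <= r_z**2
    mask = StructureMask(grid, voxels, StructureClass.DUCT, MaskRole.CORRECT)
    cl = skeletonize(mask)
    assert measure_diameter(cl, "max") == pytest.approx(6.0, abs=min(spacing))


def test_diameter_at_position_uses_nearest_centerline_voxel():
    mask = make_cylinder(2.0, length_mm=30, spacing=(1, 1, 1))
    cl = skeletonize(mask)
    target = cl.points_mm[len(cl) // 2]
    d = measure_diameter(cl, "at_position", position=tuple(target))
    assert d == pytest.approx(2 * cl.radius_mm[len(cl) // 2])
    with pytest.raises(ValidationError):
        measure_diameter(cl, "at_position")


@pytest.mark.parametrize("k", [0.5, 2.0])
def test_unit_covariance_under_spacing_scaling(k):
    """Scaling all spacing components by k scales δ and diameters by k."""
    base = make_cylinder(2.0, length_mm=24, spacing=(1, 1, 1))
    scaled_grid = VolumeGrid(base.grid.shape, tuple(k * s for s in base.grid.spacing))
    scaled = StructureMask(scaled_grid, base.voxels, base.structure_class, base.role)
    cl0, cl1 = skeletonize(base), skeletonize(scaled)
    assert estimate_delta(cl1).delta_mm == pytest.approx(k * estimate_delta(cl0).delta_mm)
    assert measure_diameter(cl1, "mean") == pytest.approx(k * measure_diameter(cl0, "mean"))


def test_skeleton_invariant_under_axis_relabeling():
    """Transposing the volume (and spacing) permutes the centerline geometry.

    Voxel-exact equality is not guaranteed by lattice thinning (endpoint
    retention can differ), so the check is mutual one-voxel proximity of the
    two centerline sets after mapping back through the permutation.
    """
    mask = make_cylinder(1.5, length_mm=16, spacing=(1, 1, 1))
    perm = (2, 0, 1)
    grid_t = VolumeGrid(
        tuple(mask.grid.shape[p] for p in perm), tuple(mask.grid.spacing[p] for p in perm)
    )
    mask_t = StructureMask(
        grid_t, np.transpose(mask.voxels, perm), mask.structure_class, mask.role
    )
    a = np.array([[v[p] for p in perm] for v in skeletonize(mask).voxels])
    b = skeletonize(mask_t).voxels
    cheb_ab = np.abs(a[:, None, :] - b[None, :, :]).max(-1).min(1)
    cheb_ba = np.abs(b[:, None, :] - a[None, :, :]).max(-1).min(1)
    assert cheb_ab.max() <= 1 and cheb_ba.max() <= 1


def test_spur_pruning_removes_short_branch():
    mask = make_cylinder(1.5, length_mm=24, spacing=(1, 1, 1))
    # bolt a 3-voxel lateral spur onto the tube wall mid-length
    cx = (mask.grid.shape[0] - 1) // 2
    z = mask.grid.shape[2] // 2
    voxels = mask.voxels.copy()
    for dx in (2, 3, 4):
        voxels[cx + dx, cx, z] = True
    spurred = StructureMask(mask.grid, voxels, mask.structure_class, mask.role)
    raw = skeletonize(spurred)
    pruned = skeletonize(spurred, prune_below_mm=5.0)
    assert len(pruned) < len(raw)
    # pruning never removes the main axis run
    axis_kept = sum(1 for v in pruned.voxels if v[0] == cx and v[1] == cx)
    assert axis_kept >= mask.grid.shape[2] - 4


def test_centerline_tsv_export(tmp_path):
    cl = skeletonize(make_cylinder(1.0, length_mm=10, spacing=(1, 1, 1)))
    out = tmp_path / "cl.tsv"
    cl.to_tsv(out)
    lines = out.read_text().strip().splitlines()
    assert lines[0] == "x_mm\ty_mm\tz_mm\tradius_mm"
    assert len(lines) == len(cl) + 1
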