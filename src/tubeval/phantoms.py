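"""Synthetic phantom cohorts: paired correct/extracted mask sets.

No public imaging archive exists for this evaluation setting (the source
data are patient CTs plus a commercial engine's outputs), so the package
ships a generator that emulates the *geometry* the metrics see: an
ellipsoidal parenchyma, a curved main duct of known radius, and simple
stochastic binary-branching vessel trees for the artery and portal-vein
systems.  "Extracted" masks are the clean geometry passed through failure
modes reported for this kind of engine — tumor replacement of parenchyma,
parenchymal atrophy, cystic carving, over/under-segmentation
(erosion/dilation), duct/vessel interruptions, missing branches, and
boundary roughness — applied in a fixed, documented order::

    tumor/atrophy/cyst -> erosion/dilation -> interruptions -> branch drop -> boundary noise

Every draw goes through one ``numpy`` Generator seeded from the spec, so a
fixed seed gives bit-identical masks.  Masks only: no CT intensities are
simulated (the engine that turns CT into masks is out of scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import GenerationError, ValidationError
from .model import (
    CaseRecord,
    Group,
    Location,
    MaskRole,
    StructureClass,
    StructureMask,
    VolumeGrid,
)

#: Peripancreatic vessel labels used for interface testing of visual-score
#: tables; generated branches are tagged with these, no anatomy is implied.
ARTERY_LABELS = ("hepatic artery", "splenic artery", "GDA", "LGA", "IPDA", "jejunal artery", "MCA")
VEIN_LABELS = (
    "jejunal vein", "ICV", "IMV", "GCT", "RGEA", "ASPDV", "accessory RCV", "MCV", "LGV",
)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def default_grid() -> VolumeGrid:
    """48 mm cube at typical dynamic-CT resolution (0.75 mm in-plane, 1 mm slices)."""
    return VolumeGrid(shape=(64, 64, 48), spacing=(0.75, 0.75, 1.0))


# ---------------------------------------------------------------------------
# geometry specs


@dataclass(frozen=True)
class ParenchymaParams:
    axes_mm: tuple[float, float, float] = (18.0, 9.0, 7.0)  # semi-axes


@dataclass(frozen=True)
class DuctParams:
    """Curved tube through the parenchyma axis.

    ``radius_end_mm`` permits a linear taper; equal radii give a constant
    tube (the default 2 mm radius matches a 4 mm median duct diameter).
    """

    radius_mm: float = 2.0
    radius_end_mm: Optional[float] = None
    length_mm: float = 34.0
    wiggle_amp_mm: float = 2.0
    wiggle_periods: float = 1.25


@dataclass(frozen=True)
class VesselTreeParams:
    root_radius_mm: float = 2.2
    root_length_mm: float = 28.0
    depth: int = 3  # root = depth 0; children down to this depth
    branch_angle_deg: float = 35.0
    length_decay: float = 0.6
    radius_decay: float = 0.75
    jitter_mm: float = 0.8  # lateral waviness of each branch


@dataclass(frozen=True)
class EllipsoidLesion:
    """Carving lesion (tumor or cyst) placed at a fractional position of the
    parenchyma bounding box."""

    center_frac: tuple[float, float, float] = (0.35, 0.5, 0.5)
    axes_mm: tuple[float, float, float] = (8.0, 6.0, 5.0)


@dataclass(frozen=True)
class PerturbationSpec:
    """Failure-mode operators applied to correct masks.

    The all-zero spec is the identity: extracted == correct for every class.
    """

    boundary_noise_mm: float = 0.0
    erosion_rounds: int = 0
    dilation_rounds: int = 0
    interruption_count: int = 0
    interruption_length_mm: float = 3.0
    branch_drop_fraction: float = 0.0
    tumor_replacement: Optional[EllipsoidLesion] = None
    atrophy_scale: float = 1.0
    cyst_spec: Optional[EllipsoidLesion] = None

    def __post_init__(self) -> None:
        if self.boundary_noise_mm < 0 or self.erosion_rounds < 0 or self.dilation_rounds < 0:
            raise ValidationError("perturbation magnitudes must be non-negative")
        if self.interruption_count < 0 or self.interruption_length_mm <= 0:
            raise ValidationError("interruption_count >= 0 and interruption_length_mm > 0 required")
        if not 0.0 <= self.branch_drop_fraction <= 1.0:
            raise ValidationError("branch_drop_fraction must lie in [0, 1]")
        if not 0.0 < self.atrophy_scale <= 1.0:
            raise ValidationError("atrophy_scale must lie in (0, 1]")

    @property
    def is_identity(self) -> bool:
        return (
            self.boundary_noise_mm == 0
            and self.erosion_rounds == 0
            and self.dilation_rounds == 0
            and self.interruption_count == 0
            and self.branch_drop_fraction == 0
            and self.tumor_replacement is None
            and self.atrophy_scale == 1.0
            and self.cyst_spec is None
        )


@dataclass(frozen=True)
class PhantomSpec:
    grid: VolumeGrid = field(default_factory=default_grid)
    parenchyma: ParenchymaParams = ParenchymaParams()
    duct: DuctParams = DuctParams()
    artery: VesselTreeParams = VesselTreeParams()
    vein: VesselTreeParams = VesselTreeParams()
    perturbation: PerturbationSpec = PerturbationSpec()
    seed: int = 0
    #: maximum tolerated overlap between distinct tubular structures,
    #: as a fraction of the smaller structure's volume
    overlap_tolerance: float = 0.05


# ---------------------------------------------------------------------------
# rasterization primitives


def _ellipsoid(grid: VolumeGrid, center_mm: np.ndarray, axes_mm: np.ndarray) -> np.ndarray:
    coords = np.meshgrid(
        *[np.arange(n) * s + o for n, s, o in zip(grid.shape, grid.spacing, grid.origin)],
        indexing="ij",
    )
    q = sum(((c - m) / a) ** 2 for c, m, a in zip(coords, center_mm, axes_mm))
    return q <= 1.0


def _tube(grid: VolumeGrid, path_mm: np.ndarray, radius_mm: np.ndarray) -> np.ndarray:
    """Rasterize a tube (varying radius) around a densely sampled polyline."""
    from scipy.spatial import cKDTree

    path_mm = np.atleast_2d(path_mm)
    radius_mm = np.broadcast_to(np.asarray(radius_mm, float), (len(path_mm),))
    rmax = float(radius_mm.max())
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    lo = np.maximum(np.floor((path_mm.min(0) - rmax - origin) / spacing).astype(int), 0)
    hi = np.minimum(
        np.ceil((path_mm.max(0) + rmax - origin) / spacing).astype(int) + 1,
        np.asarray(grid.shape),
    )
    out = np.zeros(grid.shape, dtype=bool)
    if np.any(lo >= hi):
        return out
    sub = np.stack(
        np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    pts = sub * spacing + origin
    d, idx = cKDTree(path_mm).query(pts, k=1)
    keep = d <= radius_mm[idx]
    out[tuple(sub[keep].T)] = True
    return out


def _sample_path(points_mm: np.ndarray, step_mm: float) -> np.ndarray:
    """Resample a polyline at roughly uniform arc-length steps."""
    seg = np.diff(points_mm, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    n = max(int(math.ceil(total / step_mm)) + 1, 2)
    t = np.linspace(0.0, total, n)
    return np.stack([np.interp(t, s, points_mm[:, k]) for k in range(3)], axis=1)


def _duct_path(spec: PhantomSpec) -> np.ndarray:
    grid = spec.grid
    center = np.asarray(grid.shape) * np.asarray(grid.spacing) / 2.0 + np.asarray(grid.origin)
    half = spec.duct.length_mm / 2.0
    x = np.linspace(-half, half, 200)
    y = spec.duct.wiggle_amp_mm * np.sin(2 * np.pi * spec.duct.wiggle_periods * (x + half) / spec.duct.length_mm)
    pts = np.stack([center[0] + x, center[1] + y, np.full_like(x, center[2])], axis=1)
    return _sample_path(pts, 0.4 * grid.min_spacing)


def _duct_radii(spec: PhantomSpec, n: int) -> np.ndarray:
    r0 = spec.duct.radius_mm
    r1 = spec.duct.radius_mm if spec.duct.radius_end_mm is None else spec.duct.radius_end_mm
    return np.linspace(r0, r1, n)


@dataclass
class _Branch:
    branch_id: int
    parent_id: Optional[int]
    depth: int
    path_mm: np.ndarray
    radius_mm: float
    label: str = ""


def _grow_tree(
    spec: VesselTreeParams,
    start_mm: np.ndarray,
    direction: np.ndarray,
    rng: np.random.Generator,
    labels: Sequence[str],
    bounds_mm: tuple[np.ndarray, np.ndarray],
) -> list[_Branch]:
    """Binary-branching tube tree; paths are wavy straight runs, clamped to
    the volume with a margin so branches do not leave the grid."""
    lo, hi = bounds_mm
    branches: list[_Branch] = []
    counter = [0]

    def clamp(p: np.ndarray, r: float) -> np.ndarray:
        return np.clip(p, lo + r, hi - r)

    def wavy_path(p0: np.ndarray, d: np.ndarray, length: float, r: float) -> np.ndarray:
        n = 24
        t = np.linspace(0.0, length, n)
        perp = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(d, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        amp = spec.jitter_mm * rng.uniform(0.5, 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        pts = p0[None, :] + t[:, None] * d[None, :] + (amp * np.sin(2 * np.pi * t / length + phase))[:, None] * perp[None, :]
        return np.array([clamp(p, r) for p in pts])

    def rotate(d: np.ndarray, angle_rad: float, axis: np.ndarray) -> np.ndarray:
        axis = axis / np.linalg.norm(axis)
        c, s = math.cos(angle_rad), math.sin(angle_rad)
        return d * c + np.cross(axis, d) * s + axis * np.dot(axis, d) * (1 - c)

    def grow(p0, d, length, radius, depth, parent_id):
        bid = counter[0]
        counter[0] += 1
        path = wavy_path(p0, d, length, radius)
        label = labels[bid % len(labels)]
        branches.append(_Branch(bid, parent_id, depth, path, radius, label))
        if depth >= spec.depth:
            return
        tip = path[-1]
        tip_dir = path[-1] - path[-3]
        tip_dir /= np.linalg.norm(tip_dir)
        perp = np.cross(tip_dir, rng.normal(size=3))
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(tip_dir, [1.0, 0.0, 0.0])
        angle = math.radians(spec.branch_angle_deg) * rng.uniform(0.8, 1.2)
        for sign in (+1, -1):
            child_dir = rotate(tip_dir, sign * angle, perp)
            grow(
                tip,
                child_dir / np.linalg.norm(child_dir),
                length * spec.length_decay,
                radius * spec.radius_decay,
                depth + 1,
                bid,
            )

    d0 = direction / np.linalg.norm(direction)
    grow(np.asarray(start_mm, float), d0, spec.root_length_mm, spec.root_radius_mm, 0, None)
    return branches


def _tree_mask(grid: VolumeGrid, branches: Sequence[_Branch]) -> np.ndarray:
    out = np.zeros(grid.shape, dtype=bool)
    for b in branches:
        path = _sample_path(b.path_mm, 0.4 * grid.min_spacing)
        out |= _tube(grid, path, np.full(len(path), b.radius_mm))
    return out


# ---------------------------------------------------------------------------
# correct geometry


def _build_geometry(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    grid = spec.grid
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    center = origin + extent / 2.0
    bounds = (origin + 0.5, origin + extent - 0.5)

    parenchyma = _ellipsoid(grid, center, np.asarray(spec.parenchyma.axes_mm))
    duct_path = _duct_path(spec)
    duct_radii = _duct_radii(spec, len(duct_path))
    duct = _tube(grid, duct_path, duct_radii)

    artery_start = origin + np.array([0.1 * extent[0], 0.85 * extent[1], 0.5 * extent[2]])
    vein_start = origin + np.array([0.1 * extent[0], 0.15 * extent[1], 0.5 * extent[2]])
    artery_branches = _grow_tree(spec.artery, artery_start, np.array([1.0, -0.08, 0.05]), rng, ARTERY_LABELS, bounds)
    vein_branches = _grow_tree(spec.vein, vein_start, np.array([1.0, 0.08, -0.05]), rng, VEIN_LABELS, bounds)
    artery = _tree_mask(grid, artery_branches)
    vein = _tree_mask(grid, vein_branches)

    return {
        "pancreas": {"mask": parenchyma, "center_mm": center},
        "duct": {"mask": duct, "path_mm": duct_path, "radii_mm": duct_radii},
        "artery": {"mask": artery, "branches": artery_branches},
        "vein": {"mask": vein, "branches": vein_branches},
    }


def _check_overlaps(geo: dict, tol_frac: float) -> None:
    pairs = (("duct", "artery"), ("duct", "vein"), ("artery", "vein"))
    for a, b in pairs:
        ma, mb = geo[a]["mask"], geo[b]["mask"]
        smaller = min(ma.sum(), mb.sum())
        if smaller == 0:
            continue
        frac = (ma & mb).sum() / smaller
        if frac > tol_frac:
            raise GenerationError(
                f"{a} and {b} overlap on {frac:.1%} of the smaller structure "
                f"(tolerance {tol_frac:.1%}); adjust the layout or geometry params"
            )


# ---------------------------------------------------------------------------
# perturbation operators (fixed order)


def _carve_lesion(mask: np.ndarray, grid: VolumeGrid, lesion: EllipsoidLesion) -> np.ndarray:
    idx = np.argwhere(mask)
    if len(idx) == 0:
        return mask
    lo = idx.min(0) * np.asarray(grid.spacing) + np.asarray(grid.origin)
    hi = idx.max(0) * np.asarray(grid.spacing) + np.asarray(grid.origin)
    center = lo + np.asarray(lesion.center_frac) * (hi - lo)
    return mask & ~_ellipsoid(grid, center, np.asarray(lesion.axes_mm))


def _apply_atrophy(mask: np.ndarray, grid: VolumeGrid, scale: float) -> np.ndarray:
    if scale >= 1.0 or not mask.any():
        return mask
    edt = ndimage.distance_transform_edt(mask, sampling=grid.spacing)
    return mask & (edt >= (1.0 - scale) * edt.max())


def _interrupt_tube(
    mask: np.ndarray,
    grid: VolumeGrid,
    path_mm: np.ndarray,
    count: int,
    length_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cut ``count`` transverse gaps of ``length_mm`` out of a tube.

    Each mask voxel is assigned the arc-length of its nearest path sample;
    a gap removes one arc-length window, severing the tube cleanly so
    ``count`` interior gaps give ``count + 1`` components.
    """
    from scipy.spatial import cKDTree

    if count == 0 or not mask.any():
        return mask
    seg = np.linalg.norm(np.diff(path_mm, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    usable_lo, usable_hi = 0.15 * total, 0.85 * total
    min_sep = length_mm + 2.0 * grid.voxel_diagonal_mm
    if usable_hi - usable_lo < count * min_sep:
        raise GenerationError(
            f"tube of length {total:.1f} mm cannot host {count} interruptions of {length_mm} mm"
        )
    # rejection-sample cut centers with pairwise separation >= min_sep
    for _ in range(1000):
        centers = np.sort(rng.uniform(usable_lo, usable_hi, size=count))
        if count == 1 or np.all(np.diff(centers) >= min_sep):
            break
    else:  # fall back to an even deterministic placement
        centers = np.linspace(usable_lo, usable_hi, count + 2)[1:-1]
    idx = np.argwhere(mask)
    pts = idx * np.asarray(grid.spacing) + np.asarray(grid.origin)
    _, nearest = cKDTree(path_mm).query(pts, k=1)
    voxel_s = s[nearest]
    remove = np.zeros(len(idx), dtype=bool)
    for c in centers:
        remove |= np.abs(voxel_s - c) < length_mm / 2.0
    out = mask.copy()
    out[tuple(idx[remove].T)] = False
    return out


def _drop_branches(
    mask: np.ndarray,
    grid: VolumeGrid,
    branches: Sequence[_Branch],
    fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Remove a fraction of non-root branches (descendants follow their parent)."""
    if fraction <= 0 or not mask.any():
        return mask
    droppable = [b for b in branches if b.parent_id is not None]
    if not droppable:
        return mask
    n_drop = int(round(fraction * len(droppable)))
    if n_drop == 0:
        return mask
    chosen = set(
        b.branch_id for b in rng.choice(droppable, size=n_drop, replace=False)
    )
    # propagate to descendants
    changed = True
    while changed:
        changed = False
        for b in droppable:
            if b.parent_id in chosen and b.branch_id not in chosen:
                chosen.add(b.branch_id)
                changed = True
    out = mask.copy()
    for b in branches:
        if b.branch_id not in chosen:
            continue
        path = _sample_path(b.path_mm, 0.4 * grid.min_spacing)
        # spare the junction neighbourhood so the parent tube keeps its caliber
        parent = next((p for p in branches if p.branch_id == b.parent_id), None)
        if parent is not None:
            keep_from = np.linalg.norm(path - path[0], axis=1) > parent.radius_mm + b.radius_mm
            path = path[keep_from]
        if len(path):
            out &= ~_tube(grid, path, np.full(len(path), b.radius_mm + 0.25 * grid.min_spacing))
    return out


def _boundary_noise(
    mask: np.ndarray, grid: VolumeGrid, noise_mm: float, rng: np.random.Generator, flip_p: float = 0.3
) -> np.ndarray:
    if noise_mm <= 0 or not mask.any():
        return mask
    edt_in = ndimage.distance_transform_edt(mask, sampling=grid.spacing)
    edt_out = ndimage.distance_transform_edt(~mask, sampling=grid.spacing)
    shell = (mask & (edt_in <= noise_mm)) | (~mask & (edt_out <= noise_mm))
    flips = shell & (rng.random(mask.shape) < flip_p)
    return mask ^ flips


def _perturb_class(
    cls: StructureClass,
    correct: np.ndarray,
    geo: dict,
    pert: PerturbationSpec,
    grid: VolumeGrid,
    rng: np.random.Generator,
) -> np.ndarray:
    m = correct.copy()
    if cls is StructureClass.PANCREAS:
        if pert.tumor_replacement is not None:
            m = _carve_lesion(m, grid, pert.tumor_replacement)
        m = _apply_atrophy(m, grid, pert.atrophy_scale)
        if pert.cyst_spec is not None:
            m = _carve_lesion(m, grid, pert.cyst_spec)
    for _ in range(pert.erosion_rounds):
        m = ndimage.binary_erosion(m, structure=_STRUCT6)
    for _ in range(pert.dilation_rounds):
        m = ndimage.binary_dilation(m, structure=_STRUCT6)
    if pert.interruption_count and cls is StructureClass.DUCT:
        m = _interrupt_tube(
            m, grid, geo["duct"]["path_mm"], pert.interruption_count, pert.interruption_length_mm, rng
        )
    if pert.interruption_count and cls in (StructureClass.ARTERY, StructureClass.VEIN):
        root = next(b for b in geo[cls.value]["branches"] if b.parent_id is None)
        m = _interrupt_tube(
            m, grid, _sample_path(root.path_mm, 0.4 * grid.min_spacing),
            pert.interruption_count, pert.interruption_length_mm, rng,
        )
    if pert.branch_drop_fraction and cls in (StructureClass.ARTERY, StructureClass.VEIN):
        m = _drop_branches(m, grid, geo[cls.value]["branches"], pert.branch_drop_fraction, rng)
    m = _boundary_noise(m, grid, pert.boundary_noise_mm, rng)
    return m


_CLASS_ORDER = (
    StructureClass.PANCREAS,
    StructureClass.DUCT,
    StructureClass.ARTERY,
    StructureClass.VEIN,
)


def generate_case(
    spec: PhantomSpec, return_geometry: bool = False
) -> dict[StructureClass, tuple[StructureMask, StructureMask]]:
    """Generate one case: per structure class a (correct, extracted) pair.

    Deterministic under a fixed ``spec.seed``.  Structures beyond their
    intended contacts (the duct runs inside the parenchyma by design) must
    not overlap beyond ``spec.overlap_tolerance``.
    """
    rng = np.random.default_rng(spec.seed)
    geo = _build_geometry(spec, rng)
    _check_overlaps(geo, spec.overlap_tolerance)
    out: dict[StructureClass, tuple[StructureMask, StructureMask]] = {}
    for cls in _CLASS_ORDER:
        correct = geo[cls.value]["mask"]
        if spec.perturbation.is_identity:
            extracted = correct.copy()
        else:
            extracted = _perturb_class(cls, correct, geo, spec.perturbation, spec.grid, rng)
        out[cls] = (
            StructureMask(spec.grid, correct, cls, MaskRole.CORRECT),
            StructureMask(spec.grid, extracted, cls, MaskRole.EXTRACTED),
        )
    if return_geometry:
        return out, geo  # type: ignore[return-value]
    return out


# ---------------------------------------------------------------------------
# cohort-level generation


#: UICC stage frequencies of the emulated cancer cohort.
STAGE_WEIGHTS = {"0": 7, "IA": 18, "IB": 7, "IIA": 27, "IIB": 16, "III": 11, "IV": 14}
#: head/body/tail frequencies of the emulated cancer cohort.
LOCATION_WEIGHTS = {Location.HEAD: 56, Location.BODY: 31, Location.TAIL: 13}

#: Duct diameters are log-normal with median 4 mm, truncated to the
#: clinically observed 1–15 mm range; sigma is set so ~15 mm sits near the
#: 99.5th percentile of the untruncated law.
DUCT_DIAMETER_MEDIAN_MM = 4.0
DUCT_DIAMETER_SIGMA_LOG = 0.512
DUCT_DIAMETER_RANGE_MM = (1.0, 15.0)
TUMOR_SIZE_RANGE_MM = (5.0, 80.0)


def draw_duct_diameters(n: int, rng: np.random.Generator) -> np.ndarray:
    d = rng.lognormal(mean=math.log(DUCT_DIAMETER_MEDIAN_MM), sigma=DUCT_DIAMETER_SIGMA_LOG, size=n)
    return np.clip(d, *DUCT_DIAMETER_RANGE_MM)


def simulate_diameter_pairs(
    n: int,
    target_r: float = 0.61,
    seed: int = 0,
    bias_mm: float = 0.0,
    median_mm: float = DUCT_DIAMETER_MEDIAN_MM,
    sigma_log: float = DUCT_DIAMETER_SIGMA_LOG,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (manual, measured) duct-diameter pairs with a target Pearson r.

    Both margins are log-normal with the given median; the underlying
    Gaussian-copula correlation is solved in closed form so the Pearson
    correlation of the mm-scale pair equals ``target_r``:
    rho = ln(1 + r (e^{sigma^2} - 1)) / sigma^2.  ``bias_mm`` shifts the
    measured margin additively (a systematic measurement offset).
    """
    if not -1.0 < target_r < 1.0:
        raise ValidationError("target_r must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    s2 = sigma_log**2
    arg = 1.0 + target_r * (math.exp(s2) - 1.0)
    if arg <= 0:
        raise ValidationError(f"target_r={target_r} unreachable for sigma_log={sigma_log}")
    rho = min(math.log(arg) / s2, 1.0)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    mu = math.log(median_mm)
    manual = np.exp(mu + sigma_log * z[:, 0])
    measured = np.exp(mu + sigma_log * z[:, 1]) + bias_mm
    return manual, measured


def _perturbation_for(severity: float, rng: np.random.Generator) -> PerturbationSpec:
    """Map a severity in [0, 1] to a failure-mode draw.

    Severity 0 is the mild baseline shared by unaffected cases; growing
    severity switches on tumor replacement, atrophy and duct interruptions
    with the relative prevalences reported for hard cases (tumor
    replacement ahead of atrophy ahead of cysts).
    """
    severity = float(np.clip(severity, 0.0, 1.0))
    tumor = None
    cyst = None
    atrophy = 1.0
    if severity > 0:
        u = rng.random()
        if u < 0.40 * severity:
            size = 4.0 + 8.0 * severity
            tumor = EllipsoidLesion(
                center_frac=(rng.uniform(0.25, 0.75), 0.5, 0.5),
                axes_mm=(size, 0.75 * size, 0.6 * size),
            )
        elif u < 0.75 * severity:
            atrophy = 1.0 - 0.4 * severity
        elif u < 0.95 * severity:
            cyst = EllipsoidLesion(
                center_frac=(rng.uniform(0.3, 0.7), 0.5, 0.5),
                axes_mm=(3.0 + 3.0 * severity,) * 3,
            )
    return PerturbationSpec(
        # baseline of ~one voxel: sub-voxel noise amplitudes cannot move any
        # boundary on the lattice and would leave extractions bit-perfect
        boundary_noise_mm=0.8 + 0.8 * severity,
        erosion_rounds=1 if severity > 0.6 else 0,
        interruption_count=int(rng.poisson(1.5 * severity)),
        interruption_length_mm=3.0,
        branch_drop_fraction=float(np.clip(0.3 * severity, 0.0, 0.9)),
        tumor_replacement=tumor,
        atrophy_scale=atrophy,
        cyst_spec=cyst,
    )


def generate_cohort(
    n_cancer: int,
    n_control: int,
    out_dir: Optional[Path] = None,
    seed: int = 0,
    severity_coefficient: float = 1.0,
    grid: Optional[VolumeGrid] = None,
    diameter_target_r: float = 0.61,
) -> tuple[list[CaseRecord], list[PhantomSpec]]:
    """Draw a cohort of phantom cases with covariates.

    Cancer cases receive tumor-linked perturbations whose severity grows
    linearly with tumor size scaled by ``severity_coefficient``; controls
    receive the mild baseline only (severity 0).  With
    ``severity_coefficient=0`` the two groups' perturbation distributions
    coincide.  When ``out_dir`` is given, masks are written as
    ``<case_id>/<class>_<role>.nii.gz`` plus a ``cohort.csv``.

    Returns the case records (covariates; manual duct diameters) and the
    per-case phantom specs (so callers can regenerate or evaluate lazily).
    """
    if n_cancer < 1 or n_control < 1:
        raise ValidationError("need at least one case per group")
    rng = np.random.default_rng(seed)
    grid = grid or default_grid()
    records: list[CaseRecord] = []
    specs: list[PhantomSpec] = []
    stages = list(STAGE_WEIGHTS)
    stage_p = np.array(list(STAGE_WEIGHTS.values()), float)
    stage_p /= stage_p.sum()
    locs = list(LOCATION_WEIGHTS)
    loc_p = np.array(list(LOCATION_WEIGHTS.values()), float)
    loc_p /= loc_p.sum()

    # correlated manual diameter draws (manual vs what a perfect measurement
    # of the generated tube would give); the tube is built at `true/2` radius
    manual_all, true_all = simulate_diameter_pairs(
        n_cancer + n_control, target_r=diameter_target_r, seed=int(rng.integers(2**31 - 1))
    )

    for i in range(n_cancer + n_control):
        is_cancer = i < n_cancer
        case_id = f"{'PC' if is_cancer else 'CT'}{i + 1:03d}"
        true_d = float(np.clip(true_all[i], *DUCT_DIAMETER_RANGE_MM))
        manual_d = float(np.clip(manual_all[i], *DUCT_DIAMETER_RANGE_MM))
        if is_cancer:
            tumor_size = float(rng.uniform(*TUMOR_SIZE_RANGE_MM))
            severity = severity_coefficient * (tumor_size - TUMOR_SIZE_RANGE_MM[0]) / (
                TUMOR_SIZE_RANGE_MM[1] - TUMOR_SIZE_RANGE_MM[0]
            )
            record = CaseRecord(
                case_id=case_id,
                group=Group.PANCREATIC_CANCER,
                tumor_size_mm=tumor_size,
                location=locs[rng.choice(len(locs), p=loc_p)],
                stage=stages[rng.choice(len(stages), p=stage_p)],
                manual_duct_diameter_mm=manual_d,
            )
        else:
            severity = 0.0
            record = CaseRecord(case_id=case_id, group=Group.CONTROL, manual_duct_diameter_mm=manual_d)
        pert = _perturbation_for(severity, rng)
        spec = PhantomSpec(
            grid=grid,
            # floor keeps a thin duct 26-connected on the lattice (any point
            # further than half a voxel diagonal from all voxel centers
            # would leave gaps)
            duct=DuctParams(radius_mm=max(true_d / 2.0, 0.55 * grid.voxel_diagonal_mm)),
            perturbation=pert,
            seed=int(rng.integers(2**31 - 1)),
        )
        records.append(record)
        specs.append(spec)

    if out_dir is not None:
        from .io import write_cohort_table, write_mask

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for record, spec in zip(records, specs):
            case_dir = out_dir / record.case_id
            case_dir.mkdir(exist_ok=True)
            case = generate_case(spec)
            for cls, (correct, extracted) in case.items():
                write_mask(correct, case_dir / f"{cls.value}_correct.nii.gz")
                write_mask(extracted, case_dir / f"{cls.value}_extracted.nii.gz")
        write_cohort_table(records, out_dir / "cohort.csv")
    return records, specs
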