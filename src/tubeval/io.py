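"""Reading and writing masks (NIfTI) and cohort tables (CSV/TSV).

Masks are read with nibabel and normalized to the closest canonical (RAS)
orientation, so the internal ``(x, y, z)`` axis convention holds regardless
of how the file was stored.  Grid spacing and origin come from the header;
re-reading a written mask reproduces voxels, spacing and origin exactly.

Cohort tables are delimited text with a header row.  Recognized columns::

    case_id, group, tumor_size_mm, location, stage,
    manual_duct_diameter_mm, measured_duct_diameter_mm,
    dice_<class>, dice_centerline_<class>, sens_<class>, spec_<class>

Unknown columns are preserved as opaque per-case annotations.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .model import (
    CaseRecord,
    Group,
    Location,
    MaskRole,
    StructureClass,
    StructureMask,
    VolumeGrid,
)

PathLike = Union[str, Path]

_METRIC_COL = re.compile(r"^(dice_centerline|dice|sens|spec)_(pancreas|duct|artery|vein)$")

_CORE_COLUMNS = (
    "case_id",
    "group",
    "tumor_size_mm",
    "location",
    "stage",
    "manual_duct_diameter_mm",
    "measured_duct_diameter_mm",
)


def read_mask(
    path: PathLike,
    structure_class: StructureClass,
    role: MaskRole,
    label: Optional[int] = None,
) -> StructureMask:
    """Read a binary mask from a NIfTI volume.

    Parameters
    ----------
    path
        ``.nii`` or ``.nii.gz`` file holding integer (or boolean) voxel data.
    structure_class, role
        Attached to the returned :class:`StructureMask`.
    label
        For multi-label files, the single label value to select.  Files with
        labels beyond {0, 1} are rejected unless ``label`` is given — there
        is no guessing which label maps to which structure.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.floating):
        if not np.all(np.isfinite(data)) or np.any(data != np.round(data)):
            raise FormatError(
                f"{path}: voxel data of dtype {data.dtype} contains non-integer labels; "
                "masks must be integer or boolean"
            )
        data = data.astype(np.int64)
    labels = np.unique(data)
    if label is None:
        extra = [int(v) for v in labels if v not in (0, 1)]
        if extra:
            raise FormatError(
                f"{path}: multi-label volume (labels {sorted(int(v) for v in labels)}); "
                "pass label=<value> to select one structure"
            )
        voxels = data != 0
    else:
        voxels = data == label
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    grid = VolumeGrid(
        shape=tuple(int(s) for s in data.shape),
        spacing=tuple(float(z) for z in zooms),
        origin=tuple(float(o) for o in origin),
    )
    return StructureMask(grid=grid, voxels=voxels, structure_class=structure_class, role=role)


def write_mask(mask: StructureMask, path: PathLike) -> None:
    """Write a mask as uint8 NIfTI; round-trips exactly through :func:`read_mask`."""
    path = Path(path)
    affine = np.diag(list(mask.grid.spacing) + [1.0])
    affine[:3, 3] = mask.grid.origin
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(mask.grid.spacing)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise FormatError(f"cannot write mask to {path}: {exc}") from exc


def _parse_float(value, column: str, row: int) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise FormatError(f"row {row}: non-numeric value {value!r} in column {column!r}")


def _parse_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_cohort_table(path: PathLike) -> list[CaseRecord]:
    """Parse a cohort CSV/TSV into :class:`CaseRecord` rows.

    The delimiter is taken from the extension (``.tsv`` → tab, else comma).
    Row numbers in error messages are 1-based over data rows.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str)
    except OSError as exc:
        raise FormatError(f"cannot read cohort table {path}: {exc}") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed delimited text: {exc}") from exc
    if "case_id" not in frame.columns or "group" not in frame.columns:
        raise FormatError(f"{path}: header must name at least case_id and group")

    records: list[CaseRecord] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(frame.to_dict(orient="records"), start=1):
        case_id = _parse_str(row.get("case_id"))
        if case_id is None:
            raise FormatError(f"row {i}: missing case_id")
        if case_id in seen:
            raise FormatError(f"row {i}: duplicated case_id {case_id!r} (first seen in row {seen[case_id]})")
        seen[case_id] = i
        group = _parse_str(row.get("group"))
        if group not in (g.value for g in Group):
            raise FormatError(f"row {i}: unknown group {group!r}")
        metrics: dict[str, dict[str, float]] = {}
        extras: dict[str, str] = {}
        for col, value in row.items():
            if col in _CORE_COLUMNS:
                continue
            m = _METRIC_COL.match(col)
            if m:
                v = _parse_float(value, col, i)
                if v is not None:
                    metrics.setdefault(m.group(2), {})[m.group(1)] = v
            elif _parse_str(value) is not None:
                extras[col] = str(value).strip()
        records.append(
            CaseRecord(
                case_id=case_id,
                group=Group(group),
                tumor_size_mm=_parse_float(row.get("tumor_size_mm"), "tumor_size_mm", i),
                location=_parse_str(row.get("location")),
                stage=_parse_str(row.get("stage")),
                manual_duct_diameter_mm=_parse_float(
                    row.get("manual_duct_diameter_mm"), "manual_duct_diameter_mm", i
                ),
                measured_duct_diameter_mm=_parse_float(
                    row.get("measured_duct_diameter_mm"), "measured_duct_diameter_mm", i
                ),
                metrics=metrics,
                extras=extras,
            )
        )
    return records


def records_to_frame(records: Sequence[CaseRecord]) -> pd.DataFrame:
    """Flatten case records into a table with one column per metric slot."""
    rows = []
    for r in records:
        row = {
            "case_id": r.case_id,
            "group": r.group.value,
            "tumor_size_mm": r.tumor_size_mm,
            "location": r.location.value if r.location else None,
            "stage": r.stage,
            "manual_duct_diameter_mm": r.manual_duct_diameter_mm,
            "measured_duct_diameter_mm": r.measured_duct_diameter_mm,
        }
        for cls, slots in r.metrics.items():
            for slot, value in slots.items():
                row[f"{slot}_{cls}"] = value
        row.update(r.extras)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_table(records: Sequence[CaseRecord], path: PathLike) -> None:
    """Write case records as CSV/TSV readable by :func:`read_cohort_table`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    records_to_frame(records).to_csv(path, sep=sep, index=False)
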