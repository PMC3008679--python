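"""Standard-format I/O: NIfTI-1 volumes and masks, SPM-style motion text
files (with an explicit rotation-unit declaration), and the subject CSV.

On disk data are float32; all computation upstream is float64.  Motion
files are 6 whitespace-separated columns per volume (3 translations in
mm, then 3 rotations); because SPM realignment files store rotations in
radians while the exclusion limits are stated in degrees, reading a
motion file requires a unit declaration (``"deg"`` or ``"rad"``) —
either explicit or from a YAML sidecar — and converts to degrees
internally.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .preprocess import MotionTrace

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_motion",
    "write_motion",
    "read_subject_table",
    "write_subject_table",
]

SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "lsas_total",
    "lsas_fear",
    "lsas_avoidance",
    "hamd",
    "hama",
    "stai_t",
    "stai_s_pre",
    "stai_s_post",
    "sex",
    "age",
    "education",
]


def write_volume(
    path: str | Path,
    data: np.ndarray,
    affine: np.ndarray | None = None,
    tr_seconds: float | None = None,
) -> Path:
    """Write a 3-D or 4-D array as NIfTI-1 (float32 for 4-D data)."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise ValueError("expected a 3-D or 4-D array")
    affine = np.eye(4) if affine is None else np.asarray(affine)
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    if data.ndim == 4 and tr_seconds is not None:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr_seconds
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, path)
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Read a NIfTI volume; returns ``(data_float64, affine, tr_or_None)``."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    tr = None
    if data.ndim == 4:
        zooms = img.header.get_zooms()
        if len(zooms) > 3 and zooms[3] > 0:
            tr = float(zooms[3])
    return data, img.affine, tr


def write_mask(path: str | Path, mask: np.ndarray, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask).astype(np.uint8), np.eye(4) if affine is None else affine)
    nib.save(img, path)
    return path


def read_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0, img.affine


def check_grid(
    shape_a: tuple, shape_b: tuple, what_a: str = "volume", what_b: str = "mask"
) -> None:
    """Hard error naming both shapes on a grid mismatch."""
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(
            f"grid mismatch: {what_a} has shape {tuple(shape_a)} but "
            f"{what_b} has shape {tuple(shape_b)}"
        )


def write_motion(
    path: str | Path, trace: MotionTrace, rotation_unit: str = "deg"
) -> Path:
    """Write a 6-column motion file plus a YAML sidecar recording the unit."""
    if rotation_unit not in ("deg", "rad"):
        raise ValueError("rotation_unit must be 'deg' or 'rad'")
    path = Path(path)
    rot = trace.rotations if rotation_unit == "deg" else np.deg2rad(trace.rotations)
    np.savetxt(path, np.hstack([trace.translations, rot]), fmt="%.10g")
    sidecar = path.with_suffix(".yaml")
    sidecar.write_text(yaml.safe_dump({"rotation_unit": rotation_unit}))
    return path


def read_motion(path: str | Path, rotation_unit: str | None = None) -> MotionTrace:
    """Read a 6-column motion file; rotations converted to degrees.

    The rotation unit must be declared, either via ``rotation_unit``
    ("deg" or "rad") or a ``<name>.yaml`` sidecar with a
    ``rotation_unit`` key next to the file.
    """
    path = Path(path)
    if rotation_unit is None:
        sidecar = path.with_suffix(".yaml")
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text()) or {}
            rotation_unit = meta.get("rotation_unit")
    if rotation_unit not in ("deg", "rad"):
        raise ValueError(
            "rotation unit undeclared: pass rotation_unit='deg'|'rad' or provide "
            "a YAML sidecar with a rotation_unit key"
        )
    table = np.loadtxt(path, dtype=float)
    table = np.atleast_2d(table)
    if table.shape[1] != 6:
        raise ValueError(
            f"motion file must have 6 columns, found {table.shape[1]}: {path}"
        )
    rot = table[:, 3:6]
    if rotation_unit == "rad":
        rot = np.rad2deg(rot)
    return MotionTrace(table[:, 0:3], rot)


def write_subject_table(path: str | Path, records) -> Path:
    """Write subject records (list of SubjectRecord or DataFrame) as CSV."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame([vars(r) for r in records])
    frame = frame[[c for c in SUBJECT_COLUMNS if c in frame.columns]]
    frame.to_csv(path, index=False)
    return Path(path)


def read_subject_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"subject_id", "group"} - set(frame.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    return frame
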