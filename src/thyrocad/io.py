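"""Volume/mask I/O, dataset manifests, and shared validation errors.

On-disk format is NIfTI-1 (``.nii``/``.nii.gz``) with a fixed ``(x, y, slice)``
axis order and 0-based indexing throughout the package.  A dataset is described
by a *manifest* — a CSV (or mirrored JSON) table with one row per patient::

    patient_id,label,b0,b500,b1000,b1500,mask

``label`` is ``benign``/``malignant`` (or ``0``/``1``).  The b=0 column is
mandatory (it doubles as the T2-weighted reference); non-zero b-value columns
may be empty, in which case ADC computation for that b-value fails fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "VolumeGrid",
    "NoduleMask",
    "CaseRecord",
    "Manifest",
    "B_VALUES",
    "load_volume",
    "save_volume",
    "load_dicom_series",
    "load_mask",
    "save_mask",
    "load_manifest",
    "save_manifest",
]

#: Diffusion gradient factors (s/mm^2) used by the acquisition protocol.
B_VALUES = (0, 500, 1000, 1500)

LABEL_TOKENS = {"benign": 0, "malignant": 1, "0": 0, "1": 1}
MANIFEST_COLUMNS = ("patient_id", "label", "b0", "b500", "b1000", "b1500", "mask")


class ValidationError(ValueError):
    """Input violates a documented contract (shapes, labels, manifest schema)."""


class FormatError(ValueError):
    """File payload is structurally wrong (e.g. not a 3D volume)."""


@dataclass
class VolumeGrid:
    """A 3D scalar intensity field with voxel spacing in mm, axes (x, y, slice)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise FormatError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume intensities must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class NoduleMask:
    """Binary nodule segmentation aligned to a :class:`VolumeGrid`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FormatError(f"mask must be 3D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("mask values must be in {0, 1}")
        if arr.sum() < 1:
            raise ValidationError("mask must contain at least one foreground voxel")
        self.data = arr.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class CaseRecord:
    """One patient: per-b-value volume paths, mask path and benign/malignant label."""

    patient_id: str
    label: int
    volume_paths: dict[int, Path]
    mask_path: Path

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 (benign) or 1 (malignant), got {self.label}")
        if 0 not in self.volume_paths:
            raise ValidationError(f"case {self.patient_id}: b=0 volume is mandatory")
        if not any(b > 0 for b in self.volume_paths):
            raise ValidationError(f"case {self.patient_id}: need at least one non-zero b-value")
        unknown = set(self.volume_paths) - set(B_VALUES)
        if unknown:
            raise ValidationError(f"case {self.patient_id}: unsupported b-values {sorted(unknown)}")


@dataclass
class Manifest:
    """Ordered collection of cases plus free-text provenance."""

    cases: list[CaseRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [c.patient_id for c in self.cases]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_ids in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.cases], dtype=int)


# ---------------------------------------------------------------------------
# Volumes


def load_volume(path: str | Path) -> VolumeGrid:
    """Load a NIfTI volume; intensities are returned unmodified."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D payload, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(data=np.asarray(data), spacing=spacing)


def save_volume(grid: VolumeGrid, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with spacing stored in the header zooms."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(grid.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(grid.data), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
    return path


def load_dicom_series(paths: Sequence[str | Path]) -> VolumeGrid:
    """Convenience import of a single-frame DICOM series, stacked by slice position.

    Converted to the package's internal (x, y, slice) array representation; the
    primary on-disk format remains NIfTI.
    """
    import pydicom

    if not paths:
        raise ValidationError("empty DICOM series")
    datasets = [pydicom.dcmread(str(p)) for p in paths]

    def _zpos(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=_zpos)
    slices = [ds.pixel_array.T.astype(np.float64) for ds in datasets]  # row/col -> (x, y)
    data = np.stack(slices, axis=-1)
    ds0 = datasets[0]
    px = [float(v) for v in getattr(ds0, "PixelSpacing", [1.0, 1.0])]
    dz = float(getattr(ds0, "SpacingBetweenSlices", getattr(ds0, "SliceThickness", 1.0)))
    return VolumeGrid(data=data, spacing=(px[1], px[0], dz))


def load_mask(path: str | Path) -> NoduleMask:
    grid = load_volume(path)
    return NoduleMask(data=grid.data > 0.5, spacing=grid.spacing)


def save_mask(mask: NoduleMask, path: str | Path) -> Path:
    return save_volume(VolumeGrid(mask.data.astype(np.uint8), mask.spacing), path)


# ---------------------------------------------------------------------------
# Manifests


def _record_from_row(row: Mapping[str, object], base: Path) -> CaseRecord:
    label_token = str(row["label"]).strip().lower()
    if label_token not in LABEL_TOKENS:
        raise ValidationError(f"unknown label token {row['label']!r}")

    def _path(v: object) -> Path | None:
        s = "" if v is None else str(v).strip()
        if s in ("", "nan", "none"):
            return None
        p = Path(s)
        return p if p.is_absolute() else base / p

    volume_paths: dict[int, Path] = {}
    for b in B_VALUES:
        p = _path(row.get(f"b{b}"))
        if p is not None:
            volume_paths[b] = p
    mask = _path(row.get("mask"))
    if mask is None:
        raise ValidationError(f"case {row.get('patient_id')}: mask path is required")
    return CaseRecord(
        patient_id=str(row["patient_id"]),
        label=LABEL_TOKENS[label_token],
        volume_paths=volume_paths,
        mask_path=mask,
    )


def load_manifest(path: str | Path, check_files: bool = True) -> Manifest:
    """Load a CSV or JSON manifest, preserving row order.

    Raises :class:`ValidationError` on duplicate patient ids, a missing b=0
    column, unknown label tokens or (with ``check_files``) dangling paths.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    base = path.parent
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        rows = payload["cases"] if isinstance(payload, dict) else payload
        provenance = payload.get("provenance", "") if isinstance(payload, dict) else ""
    else:
        frame = pd.read_csv(path, dtype=str)
        missing = set(MANIFEST_COLUMNS[:3]) | {"mask"}
        missing -= set(frame.columns)
        if missing:
            raise ValidationError(f"manifest missing required columns: {sorted(missing)}")
        rows = frame.to_dict(orient="records")
        provenance = ""
    cases = [_record_from_row(r, base) for r in rows]
    manifest = Manifest(cases=cases, provenance=provenance)
    if check_files:
        for case in manifest:
            for b, p in case.volume_paths.items():
                if not Path(p).exists():
                    raise ValidationError(f"case {case.patient_id}: missing b={b} file {p}")
            if not Path(case.mask_path).exists():
                raise ValidationError(f"case {case.patient_id}: missing mask file {case.mask_path}")
    return manifest


def save_manifest(manifest: Manifest, path: str | Path) -> Path:
    """Write the manifest as CSV with paths stored relative to the CSV location."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    base = path.parent

    def _rel(p: Path) -> str:
        try:
            return str(Path(p).relative_to(base))
        except ValueError:
            return str(p)

    rows = []
    for case in manifest:
        row = {
            "patient_id": case.patient_id,
            "label": "malignant" if case.label == 1 else "benign",
            "mask": _rel(case.mask_path),
        }
        for b in B_VALUES:
            row[f"b{b}"] = _rel(case.volume_paths[b]) if b in case.volume_paths else ""
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    frame.to_csv(path, index=False)
    return path
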