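"""NIfTI volume and attribute-table I/O plus pipeline configuration."""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import Grid3D, GridError
from .labels import DEFAULT_EXCLUDED_ORGANS, DEFAULT_LABELS
from .phantom import Study, StudyAttributes

__all__ = [
    "read_volume",
    "write_volume",
    "read_attributes",
    "write_attributes",
    "write_study",
    "read_study",
    "PipelineConfig",
]

_ATTRIBUTE_FIELDS = [f.name for f in dataclasses.fields(StudyAttributes)]


def write_volume(grid: Grid3D, path: str | Path) -> Path:
    """Write a grid as NIfTI; spacing and origin go into the affine."""
    path = Path(path)
    affine = np.diag([*grid.spacing, 1.0])
    affine[:3, 3] = grid.origin
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def read_volume(path: str | Path) -> Grid3D:
    """Read a NIfTI volume; fails loudly on corrupt files or missing spacing."""
    path = Path(path)
    if not path.exists():
        raise GridError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # corrupt header/payload
        raise GridError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise GridError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise GridError(f"{path}: missing or invalid voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Grid3D(data, tuple(float(z) for z in zooms), origin)


def write_attributes(attributes: list[StudyAttributes], path: str | Path,
                     study_ids: list[str] | None = None) -> Path:
    path = Path(path)
    rows = [dataclasses.asdict(a) for a in attributes]
    frame = pd.DataFrame(rows, columns=_ATTRIBUTE_FIELDS)
    if study_ids is not None:
        frame.insert(0, "study_id", study_ids)
    frame.to_csv(path, index=False)
    return path


def read_attributes(path: str | Path) -> list[StudyAttributes]:
    """Read an attribute CSV into typed records.

    Unknown columns are ignored with a warning; a missing mandatory column
    or an unparseable row fails with the offending name or row number.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in _ATTRIBUTE_FIELDS if c not in frame.columns]
    if missing:
        raise GridError(f"{path}: missing mandatory columns {missing}")
    extra = [c for c in frame.columns if c not in _ATTRIBUTE_FIELDS + ["study_id"]]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}")
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(StudyAttributes(**{
                name: row[name] for name in _ATTRIBUTE_FIELDS
            }))
        except (ValueError, TypeError) as exc:
            raise GridError(f"{path}: row {i}: {exc}") from exc
    return records


_STUDY_VOLUMES = {
    "ct": "ct.nii.gz",
    "pet": "pet.nii.gz",
    "organ_labels": "labels.nii.gz",
    "body_mask": "body_mask.nii.gz",
    "exclusion_mask": "exclusion_mask.nii.gz",
    "lesion_mask": "lesion_mask.nii.gz",
}


def write_study(study: Study, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _STUDY_VOLUMES.items():
        grid = getattr(study, attr)
        if grid is not None:
            write_volume(grid, out_dir / fname)
    write_attributes([study.attributes], out_dir / "attributes.csv",
                     study_ids=[study.id])
    return out_dir


def read_study(study_dir: str | Path) -> Study:
    study_dir = Path(study_dir)
    grids = {}
    for attr, fname in _STUDY_VOLUMES.items():
        p = study_dir / fname
        grids[attr] = read_volume(p) if p.exists() else None
    for required in ("ct", "pet", "organ_labels", "body_mask"):
        if grids[required] is None:
            raise GridError(f"{study_dir}: missing {_STUDY_VOLUMES[required]}")
    attrs = read_attributes(study_dir / "attributes.csv")
    return Study(id=study_dir.name, attributes=attrs[0], **grids)


@dataclasses.dataclass
class PipelineConfig:
    """Serializable end-to-end pipeline configuration."""

    out_dir: str = "ntpet_out"
    n_studies: int = 20
    seed: int = 0
    model: str = "regression"  # constant | regression | conv
    shape: tuple[int, int, int] = (48, 48, 80)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    threshold: float = 1.8
    smoothing_mm: float = 4.0
    lesion_fraction: float = 0.5
    excluded_organs: tuple[str, ...] = DEFAULT_EXCLUDED_ORGANS
    labels: dict[str, int] = dataclasses.field(default_factory=lambda: dict(DEFAULT_LABELS))
    version: int = 1

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        for key in ("shape", "spacing", "excluded_organs"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)
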