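"""Volume/mask I/O, the cohort manifest, and enrollment bookkeeping.

Volumes travel as NIfTI on disk. Voxel indices are 0-based everywhere; crop
ranges are half-open when slicing while bounding boxes store inclusive
min/max indices. One segmentation mask per case, drawn on a declared
reference modality; other modalities may sit on different grids and are
cropped by mapping the cube's physical extent (see preprocessing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

MODALITIES = ("t2wi", "nonfs_t1wi", "d1", "d2", "d4", "d6")
LABELS = ("benign", "malignant")

MANIFEST_COLUMNS = ["case_id", "label", *MODALITIES, "mask", "reference_modality"]


@dataclass
class ModalityVolume:
    voxels: np.ndarray          # 3D scalar array, raw intensity units
    spacing: tuple[float, float, float]  # mm per axis
    modality: str
    case_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"volume must be 3D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class SegmentationMask:
    voxels: np.ndarray          # 3D binary array
    case_id: str = ""
    reference_modality: str = "d2"

    def __post_init__(self) -> None:
        self.voxels = (np.asarray(self.voxels) != 0).astype(np.uint8)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.voxels.sum() == 0:
            raise ValueError("empty mask: no nonzero voxels")
        if self.reference_modality not in MODALITIES:
            raise ValueError(f"unknown reference modality {self.reference_modality!r}")


@dataclass
class CaseRecord:
    case_id: str
    label: str
    paths: dict[str, Path]      # modality -> volume file
    mask_path: Path
    reference_modality: str = "d2"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass
class CohortManifest:
    records: list[CaseRecord]
    enrolled: int | None = None
    excluded: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.case_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("case_ids must be unique")
        if self.enrolled is None:
            self.enrolled = len(self.records)
        self._check_counts()

    def _check_counts(self) -> None:
        if self.retained != self.enrolled - sum(self.excluded.values()):
            raise ValueError("retained count inconsistent with enrolled minus exclusions")

    @property
    def retained(self) -> int:
        return self.enrolled - sum(self.excluded.values())

    def labels(self) -> dict[str, str]:
        return {r.case_id: r.label for r in self.records}


def save_volume(volume: ModalityVolume, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.voxels), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path, modality: str, case_id: str = "") -> ModalityVolume:
    """Read a NIfTI volume; no intensity rescaling beyond the header scl slope."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {path} has {data.ndim} dimensions")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ModalityVolume(voxels=data, spacing=spacing, modality=modality,
                          case_id=case_id)


def load_mask(path: str | Path, reference: ModalityVolume) -> SegmentationMask:
    """Read a mask drawn on ``reference``; any nonzero label binarizes to 1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"non-3D mask: {path}")
    if data.shape != reference.shape:
        raise ValueError(
            f"mask shape {data.shape} does not match reference {reference.shape}")
    if not (data != 0).any():
        raise ValueError(f"empty mask: {path}")
    return SegmentationMask(voxels=data, case_id=reference.case_id,
                            reference_modality=reference.modality)


def apply_exclusions(manifest: CohortManifest,
                     exclusion_counts: dict[str, int]) -> CohortManifest:
    """Record per-reason exclusion counts; retained = enrolled - sum(counts)."""
    merged = dict(manifest.excluded)
    for reason, count in exclusion_counts.items():
        if count < 0:
            raise ValueError("exclusion counts must be non-negative")
        merged[reason] = merged.get(reason, 0) + count
    if sum(merged.values()) > manifest.enrolled:
        raise ValueError(
            f"exclusions ({sum(merged.values())}) exceed enrolled ({manifest.enrolled})")
    return CohortManifest(records=list(manifest.records), enrolled=manifest.enrolled,
                          excluded=merged)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in manifest.records:
        row = {"case_id": r.case_id, "label": r.label}
        for mod in MODALITIES:
            row[mod] = str(r.paths[mod]) if mod in r.paths else ""
        row["mask"] = str(r.mask_path)
        row["reference_modality"] = r.reference_modality
        rows.append(row)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".counts.json")
    sidecar.write_text(json.dumps(
        {"enrolled": manifest.enrolled, "excluded": manifest.excluded}, indent=2))
    return path


def read_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        paths = {mod: Path(row[mod]) for mod in MODALITIES if row[mod]}
        records.append(CaseRecord(case_id=row["case_id"], label=row["label"],
                                  paths=paths, mask_path=Path(row["mask"]),
                                  reference_modality=row["reference_modality"]))
    enrolled, excluded = len(records), {}
    sidecar = path.with_suffix(path.suffix + ".counts.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        enrolled, excluded = meta["enrolled"], meta["excluded"]
    return CohortManifest(records=records, enrolled=enrolled, excluded=excluded)


def dicom_series_to_nifti(series_dir: str | Path, out_path: str | Path,
                          modality: str) -> Path:
    """Convert a single DICOM series directory to one NIfTI volume.

    Requires the optional ``pydicom`` dependency; the rest of the package is
    NIfTI-native and does not need it.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "DICOM conversion requires the optional 'pydicom' package; "
            "install it or convert the series to NIfTI externally") from exc
    series_dir = Path(series_dir)
    files = sorted(series_dir.glob("*.dcm")) or sorted(
        p for p in series_dir.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no DICOM files in {series_dir}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda s: float(getattr(s, "SliceLocation",
                                            s.InstanceNumber)))
    vol = np.stack([s.pixel_array for s in slices], axis=-1)
    px = [float(v) for v in slices[0].PixelSpacing]
    dz = float(getattr(slices[0], "SliceThickness", 1.0))
    volume = ModalityVolume(voxels=vol, spacing=(px[0], px[1], dz),
                            modality=modality)
    return save_volume(volume, out_path)
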