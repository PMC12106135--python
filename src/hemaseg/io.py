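"""Readers/writers for the pipeline's on-disk formats.

DICOM series (one file per slice, sorted by InstanceNumber, falling back to
the ImagePositionPatient z coordinate), NIfTI or per-slice PNG masks, YAML
configuration, JSON-lines run logs.  Mask pairing is by filename stem
equality.  All DICOM writing is deterministic: UIDs derive from the caller's
seeded generator and no date/time attributes are set.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from PIL import Image
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian

from .preprocess import CTVolume

__all__ = [
    "read_ct_series", "write_ct_series", "read_mask", "write_mask",
    "read_mask_dir", "load_yaml", "dump_yaml", "config_hash",
    "JsonlLogger", "substream",
]

_UID_ROOT = "1.2.826.0.1.3680043.8.498"
_IMPLEMENTATION_UID = _UID_ROOT + ".1"


def substream(seed: int, name: str) -> np.random.Generator:
    """Named deterministic child stream of one global seed."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def write_ct_series(directory, raw: np.ndarray, slope: float, intercept: float,
                    scan_id: str, rng: np.random.Generator,
                    spacing: tuple = (0.5, 0.5, 5.0)) -> list:
    """Write an (H, W, C) int16 stored-value volume as one DICOM per slice."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    raw = np.asarray(raw)
    if raw.dtype != np.int16:
        raise ValueError("stored values must be int16")
    series_uid = f"{_UID_ROOT}.{rng.integers(1, 10**9)}.{rng.integers(1, 10**9)}"
    study_uid = f"{_UID_ROOT}.{rng.integers(1, 10**9)}.{rng.integers(1, 10**9)}"
    paths = []
    for z in range(raw.shape[2]):
        sop_uid = f"{series_uid}.{z + 1}"
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = sop_uid
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.ImplementationClassUID = _IMPLEMENTATION_UID

        ds = Dataset()
        ds.file_meta = meta
        ds.preamble = b"\x00" * 128
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.PatientID = scan_id
        ds.PatientName = scan_id
        ds.InstanceNumber = z + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(z) * spacing[2]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [float(spacing[0]), float(spacing[1])]
        ds.SliceThickness = float(spacing[2])
        ds.Rows, ds.Columns = raw.shape[0], raw.shape[1]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = str(slope)
        ds.RescaleIntercept = str(intercept)
        ds.PixelData = np.ascontiguousarray(raw[:, :, z]).tobytes()
        path = directory / f"slice{z:04d}.dcm"
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        paths.append(path)
    return paths


def read_ct_series(directory) -> CTVolume:
    """Load a one-file-per-slice DICOM series into a CTVolume.

    Slices are ordered by InstanceNumber (ImagePositionPatient z as
    fallback); mixed SeriesInstanceUIDs or inconsistent slice shapes are
    rejected; missing rescale tags raise naming the absent field.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"mixed series UIDs in {directory}: {sorted(uids)}")

    def sort_key(ds):
        if hasattr(ds, "InstanceNumber") and ds.InstanceNumber is not None:
            return (0, int(ds.InstanceNumber))
        if hasattr(ds, "ImagePositionPatient"):
            return (1, float(ds.ImagePositionPatient[2]))
        raise ValueError("cannot sort series: no InstanceNumber or ImagePositionPatient")

    datasets.sort(key=sort_key)
    first = datasets[0]
    for ds in datasets:
        for tag in ("RescaleSlope", "RescaleIntercept"):
            if not hasattr(ds, tag):
                raise ValueError(f"missing rescale metadata: {tag}")
    shape = (int(first.Rows), int(first.Columns))
    arrays = []
    for ds in datasets:
        arr = ds.pixel_array
        if arr.shape != shape:
            raise ValueError(
                f"inconsistent slice shapes in series: {arr.shape} vs {shape}")
        arrays.append(arr)
    raw = np.stack(arrays, axis=2)
    spacing = None
    if hasattr(first, "PixelSpacing"):
        thickness = float(getattr(first, "SliceThickness", 1.0))
        spacing = (float(first.PixelSpacing[0]), float(first.PixelSpacing[1]), thickness)
    return CTVolume(raw=raw, slope=float(first.RescaleSlope),
                    intercept=float(first.RescaleIntercept), spacing=spacing,
                    scan_id=str(getattr(first, "PatientID", directory.name)))


# ---------------------------------------------------------------------------
# masks (NIfTI volume or per-slice PNG)
# ---------------------------------------------------------------------------

def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask: .nii/.nii.gz volume or .png slice (0/255)."""
    path = Path(path)
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary {0, 1}")
    if path.suffix == ".png":
        if mask.ndim != 2:
            raise ValueError("PNG masks are per-slice (2-D)")
        Image.fromarray((mask * 255).astype(np.uint8)).save(path)
    elif path.name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), str(path))
    else:
        raise ValueError(f"unsupported mask format: {path.name}")


def read_mask(path) -> np.ndarray:
    """Read a binary mask, coercing 0/255 PNGs to {0, 1}."""
    path = Path(path)
    if path.suffix == ".png":
        arr = np.asarray(Image.open(path))
        values = np.unique(arr)
        if not np.isin(values, (0, 255)).all() and not np.isin(values, (0, 1)).all():
            raise ValueError(f"non-binary PNG mask values in {path.name}: {values[:10]}")
        return (arr > arr.max() / 2 if arr.max() > 1 else arr > 0).astype(np.uint8)
    if path.name.endswith((".nii", ".nii.gz")):
        arr = np.asarray(nib.load(str(path)).dataobj)
        if not np.isin(np.round(arr, 6), (0.0, 1.0)).all():
            raise ValueError(f"non-binary NIfTI mask values in {path.name}")
        return (arr > 0.5).astype(np.uint8)
    raise ValueError(f"unsupported mask format: {path.name}")


def read_mask_dir(directory) -> dict:
    """Stem → mask for every mask file in a directory (filename pairing)."""
    directory = Path(directory)
    out = {}
    for path in sorted(directory.iterdir()):
        if path.suffix == ".png" or path.name.endswith((".nii", ".nii.gz")):
            stem = path.name.split(".")[0]
            out[stem] = read_mask(path)
    return out


# ---------------------------------------------------------------------------
# config and logging
# ---------------------------------------------------------------------------

def load_yaml(path) -> dict:
    import yaml
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    """Stable hash of a config dict: changes iff any constant changes."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


class JsonlLogger:
    """Append-only JSON-lines run log (seeds, config hash, loss curves)."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def log(self, record: dict) -> None:
        with open(self.path, "a") as fh:
            fh.write(json.dumps(record, sort_keys=True, default=str) + "\n")
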