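"""Volume, mask, manifest and report I/O.

Volumes are stored as NIfTI (.nii / .nii.gz).  In memory everything uses the
axis order (Z, Y, X) -- slice index first -- with an optional trailing channel
axis for multi-channel sequences (e.g. the phases of a dynamic contrast series
as channels).  On load, volumes are reoriented to a canonical (RAS) axis order
from the header, so the in-memory orientation never depends on how a file was
written.

The cohort manifest is a JSON file listing one entry per patient/timepoint
with explicit sequence ordering (first sequence feeds pathway one).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

TIMEPOINTS = ("baseline", "followup")
SPLITS = ("train", "val", "test")


@dataclasses.dataclass
class AnnotatedCase:
    """One patient-timepoint: sequences, organ mask, optional lesion mask.

    sequences : list of (Z, Y, X, C) float32 arrays, one per MRI sequence,
        ordered; the first sequence feeds the first network pathway.
    organ_mask : (Z, Y, X) uint8 binary mask of the organ of interest.
    lesion_mask : (Z, Y, X) uint8 binary lesion annotation, or None
        (follow-up scans under evaluation may lack one at prediction time).
    spacing_mm : (z, y, x) voxel spacing in millimetres.
    """

    patient_id: str
    timepoint: str
    sequences: list
    organ_mask: np.ndarray
    lesion_mask: np.ndarray | None
    spacing_mm: tuple

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}, "
                             f"got {self.timepoint!r}")
        if not self.sequences:
            raise ValueError("at least one sequence is required")
        self.sequences = [_as_sequence(s) for s in self.sequences]
        shape = self.sequences[0].shape[:3]
        for i, s in enumerate(self.sequences):
            if s.shape[:3] != shape:
                raise ValueError(
                    f"sequence {i} shape {s.shape[:3]} does not match "
                    f"sequence 0 shape {shape}")
        self.organ_mask = _as_mask(self.organ_mask, "organ_mask")
        if self.organ_mask.shape != shape:
            raise ValueError(f"organ_mask shape {self.organ_mask.shape} "
                             f"does not match volume shape {shape}")
        if self.lesion_mask is not None:
            self.lesion_mask = _as_mask(self.lesion_mask, "lesion_mask")
            if self.lesion_mask.shape != shape:
                raise ValueError(
                    f"lesion_mask shape {self.lesion_mask.shape} does not "
                    f"match volume shape {shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be three positive reals, "
                             f"got {self.spacing_mm}")

    @property
    def shape(self) -> tuple:
        return self.sequences[0].shape[:3]

    @property
    def n_slices(self) -> int:
        return self.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        z, y, x = self.spacing_mm
        return z * y * x


def _as_sequence(arr) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[..., None]
    if arr.ndim != 4 or arr.shape[-1] < 1:
        raise ValueError("sequence arrays must be (Z, Y, X) or (Z, Y, X, C)")
    return arr


def _as_mask(arr, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    values = np.unique(arr)
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"{name} must be binary; found values "
                         f"{values[~np.isin(values, (0, 1))][:5].tolist()}")
    return arr.astype(np.uint8)


# -- NIfTI -------------------------------------------------------------------

def save_volume(arr: np.ndarray, spacing_mm, path) -> None:
    """Write a (Z, Y, X[, C]) array as NIfTI with the given (z, y, x) spacing."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        disk = arr.transpose(2, 1, 0)
    elif arr.ndim == 4:
        disk = arr.transpose(2, 1, 0, 3)
    else:
        raise ValueError("volume must be 3D or 4D")
    z, y, x = (float(s) for s in spacing_mm)
    affine = np.diag([x, y, z, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(disk), affine)
    img.header.set_zooms((x, y, z) + ((1.0,) if arr.ndim == 4 else ()))
    nib.save(img, str(path))


def load_volume(path) -> tuple:
    """Read a NIfTI volume; returns ((Z, Y, X[, C]) array, (z, y, x) spacing).

    The image is reoriented to canonical (RAS) axes first, so in-memory axis
    order is independent of on-disk orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        arr = data.transpose(2, 1, 0)
    elif data.ndim == 4:
        arr = data.transpose(2, 1, 0, 3)
    else:
        raise ValueError(f"{path}: expected 3D or 4D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return arr, spacing


# -- cases and manifests -----------------------------------------------------

def save_case(case: AnnotatedCase, out_dir, split: str = "test") -> dict:
    """Write a case's volumes under out_dir; return its manifest entry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{case.patient_id}_{case.timepoint}"
    entry = {"patient_id": case.patient_id, "timepoint": case.timepoint,
             "split": split, "sequences": [], "organ_mask": None,
             "lesion_mask": None}
    for i, seq in enumerate(case.sequences):
        name = f"{stem}_seq{i}.nii.gz"
        save_volume(seq, case.spacing_mm, out_dir / name)
        entry["sequences"].append(name)
    name = f"{stem}_organ.nii.gz"
    save_volume(case.organ_mask, case.spacing_mm, out_dir / name)
    entry["organ_mask"] = name
    if case.lesion_mask is not None:
        name = f"{stem}_lesion.nii.gz"
        save_volume(case.lesion_mask, case.spacing_mm, out_dir / name)
        entry["lesion_mask"] = name
    return entry


def load_case(entry: dict, base_dir=".") -> AnnotatedCase:
    """Materialize an AnnotatedCase from a manifest entry.

    Spacing is read from the (first) volume header; all invariants of
    AnnotatedCase are enforced.
    """
    base = Path(base_dir)
    sequences, spacing = [], None
    for rel in entry["sequences"]:
        arr, sp = load_volume(base / rel)
        sequences.append(arr)
        spacing = spacing or sp
    organ, _ = load_volume(base / entry["organ_mask"])
    lesion = None
    if entry.get("lesion_mask"):
        lesion, _ = load_volume(base / entry["lesion_mask"])
    return AnnotatedCase(patient_id=entry["patient_id"],
                         timepoint=entry["timepoint"],
                         sequences=sequences, organ_mask=organ,
                         lesion_mask=lesion, spacing_mm=spacing)


def save_manifest(entries: list, path) -> None:
    _validate_manifest(entries)
    with open(path, "w") as fh:
        json.dump({"cases": entries}, fh, indent=1)


def load_manifest(path) -> list:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    with open(path) as fh:
        entries = json.load(fh)["cases"]
    _validate_manifest(entries)
    for e in entries:
        for rel in e["sequences"] + [e["organ_mask"]] + (
                [e["lesion_mask"]] if e.get("lesion_mask") else []):
            p = path.parent / rel
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
    return entries


def _validate_manifest(entries: list) -> None:
    by_patient: dict = {}
    for e in entries:
        if e["split"] not in SPLITS:
            raise ValueError(f"unknown split {e['split']!r}")
        if e["timepoint"] not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {e['timepoint']!r}")
        if e["split"] == "test":
            by_patient.setdefault(e["patient_id"], []).append(e["timepoint"])
    for pid, tps in by_patient.items():
        if sorted(tps) != ["baseline", "followup"]:
            raise ValueError(
                f"test patient {pid} must have exactly one baseline and one "
                f"followup entry, got {tps}")


def split_entries(entries: list, split: str) -> list:
    return [e for e in entries if e["split"] == split]


# -- reports and configs ------------------------------------------------------

def write_report(table, path) -> None:
    """Write a per-patient metrics table as CSV with a header row."""
    df = pd.DataFrame(table)
    df.to_csv(path, index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"run config must be a mapping: {path}")
    return cfg


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
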