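"""Synthetic longitudinal cohort generator.

Produces paired baseline/follow-up multi-sequence phantoms with the
statistical structure that patient-specific fine-tuning exploits: the two
scans of one patient share an anatomy texture and a lesion contrast drawn
once per patient, while different patients differ in both.  Between
timepoints, lesions grow or shrink, may disappear, and new ones may appear;
the whole follow-up volume is additionally rotated in-plane by a few degrees
to emulate repositioning.

Two "sequences" are produced as distinct nonlinear mappings of one latent
anatomy (lesions bright in the first, dark in the second), mimicking the
complementarity of DCE/DW or FLAIR/T1 pairs.  Lesions are Gaussian-profile
blobs; the annotation mask is the blob thresholded at half maximum, so mask
edges sit on soft intensity transitions.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .io import AnnotatedCase, save_case, save_manifest


class SimulationError(RuntimeError):
    pass


@dataclasses.dataclass
class SyntheticCohortConfig:
    """Cohort-level simulation parameters (defaults define the study conditions).

    patient_signature_sd sets the between-patient spread of organ texture and
    lesion contrast; within_patient_noise_sd the residual per-scan appearance
    noise.  The generator requires within_patient_noise_sd <
    patient_signature_sd, which is exactly the premise that makes a patient's
    baseline scan informative about their follow-up scan.
    """

    n_train_patients: int = 12
    n_test_patients: int = 10
    volume_shape: tuple = (24, 128, 128)
    spacing_mm: tuple = (3.0, 1.0, 1.0)
    channels_per_sequence: tuple = (2, 1)
    lesion_count_range: tuple = (2, 6)
    lesion_radius_range_vox: tuple = (2.0, 5.0)
    patient_signature_sd: float = 0.35
    within_patient_noise_sd: float = 0.08
    followup_growth_factor_range: tuple = (0.7, 1.4)
    new_lesion_rate: float = 1.0
    disappear_rate: float = 0.15
    global_intensity_shift_sd: float = 0.05
    rotation_max_deg: float = 5.0
    acquisition_noise_sd: float = 0.02
    lesion_contrast_mean: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.within_patient_noise_sd >= self.patient_signature_sd:
            raise ValueError(
                "within_patient_noise_sd must be smaller than "
                "patient_signature_sd (the baseline scan must carry "
                "patient-specific signal)")
        if not 0.0 <= self.disappear_rate <= 1.0:
            raise ValueError("disappear_rate must be in [0, 1]")
        if self.new_lesion_rate < 0:
            raise ValueError("new_lesion_rate must be >= 0")
        lo, hi = self.lesion_radius_range_vox
        if lo <= 0 or hi < lo:
            raise ValueError("invalid lesion_radius_range_vox")
        lo, hi = self.lesion_count_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid lesion_count_range")
        if any(s < 8 for s in self.volume_shape):
            raise ValueError("volume_shape too small to host an organ")


@dataclasses.dataclass
class _Lesion:
    center: np.ndarray  # (z, y, x) voxel coordinates, float
    radius_mm: float


class _Patient:
    """Per-patient latent state shared by both timepoints."""

    def __init__(self, pid: str, cfg: SyntheticCohortConfig,
                 rng: np.random.Generator):
        self.pid = pid
        shape = cfg.volume_shape
        center = (np.asarray(shape) - 1) / 2.0
        semi = np.array([rng.uniform(0.66, 0.82) * (s / 2 - 1.5)
                         for s in shape])
        self.center = center
        self.semi_axes = semi
        # appearance signature: smooth texture + lesion contrast, both reused
        # at follow-up
        noise = rng.normal(size=shape)
        tex = ndimage.gaussian_filter(noise, sigma=(1.2, 3.5, 3.5))
        tex /= tex.std() + 1e-9
        self.texture = (tex * cfg.patient_signature_sd).astype(np.float32)
        self.lesion_contrast = float(np.clip(
            rng.normal(cfg.lesion_contrast_mean, cfg.patient_signature_sd),
            0.35, None))
        self.organ = _ellipsoid_mask(shape, center, semi)

    def sample_lesion(self, cfg: SyntheticCohortConfig,
                      rng: np.random.Generator) -> _Lesion:
        radius_vox = rng.uniform(*cfg.lesion_radius_range_vox)
        radius_mm = radius_vox * cfg.spacing_mm[2]
        margin = radius_mm / np.array(cfg.spacing_mm)  # per-axis voxels
        avail = self.semi_axes - margin
        if np.any(avail <= 0):
            raise SimulationError(
                f"patient {self.pid}: organ semi-axes {self.semi_axes} too "
                f"small for lesion radius {radius_vox:.1f} vox")
        while True:
            u = rng.uniform(-1, 1, size=3)
            if (u ** 2).sum() <= 1.0:
                break
        return _Lesion(self.center + u * avail, radius_mm)


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return (acc <= 1.0).astype(np.uint8)


def _render_lesions(shape, spacing, lesions) -> tuple:
    """Sum of Gaussian blobs (half max at radius) and the half-max mask."""
    field = np.zeros(shape, np.float32)
    if not lesions:
        return field, np.zeros(shape, np.uint8)
    zz, yy, xx = np.ogrid[tuple(slice(0, s) for s in shape)]
    sz, sy, sx = spacing
    ln2 = math.log(2.0)
    for les in lesions:
        cz, cy, cx = les.center
        d2 = (((zz - cz) * sz) ** 2 + ((yy - cy) * sy) ** 2
              + ((xx - cx) * sx) ** 2)
        field += np.exp(-ln2 * d2 / les.radius_mm ** 2).astype(np.float32)
    mask = (field >= 0.5).astype(np.uint8)
    return np.clip(field, 0.0, 1.2).astype(np.float32), mask


def _rotate_center(center, pivot_yx, theta_deg) -> np.ndarray:
    """In-plane rotation of a (z, y, x) point about the volume axis."""
    th = math.radians(theta_deg)
    dy, dx = center[1] - pivot_yx[0], center[2] - pivot_yx[1]
    # matches scipy.ndimage.rotate(axes=(1, 2)) mapping of content
    cy = pivot_yx[0] + dy * math.cos(th) - dx * math.sin(th)
    cx = pivot_yx[1] + dy * math.sin(th) + dx * math.cos(th)
    return np.array([center[0], cy, cx])


def _compose_sequences(anatomy, lesion_field, organ, contrast, cfg, rng):
    """Map latent anatomy + lesion field to the two observed sequences."""
    c1, c2 = cfg.channels_per_sequence
    inside = organ.astype(np.float32)
    background = 0.15 + 0.4 * np.abs(anatomy) * 0.3
    latent = 0.55 + anatomy
    seq1 = np.empty(cfg.volume_shape + (c1,), np.float32)
    for k in range(c1):
        phase = 1.0 - 0.12 * k
        img = inside * (latent + contrast * lesion_field) * phase \
            + (1 - inside) * background
        img += rng.normal(0, cfg.acquisition_noise_sd, cfg.volume_shape)
        seq1[..., k] = img
    seq2 = np.empty(cfg.volume_shape + (c2,), np.float32)
    for k in range(c2):
        mapped = np.tanh(1.6 * latent) * (1.0 - 0.1 * k)
        img = inside * (mapped - 0.55 * contrast * lesion_field) \
            + (1 - inside) * background * 0.8
        img += rng.normal(0, cfg.acquisition_noise_sd, cfg.volume_shape)
        seq2[..., k] = img
    return [seq1, seq2]


def simulate_patient(pid: str, cfg: SyntheticCohortConfig,
                     seed_seq: np.random.SeedSequence) -> tuple:
    """One baseline/follow-up AnnotatedCase pair."""
    s_patient, s_base, s_follow = seed_seq.spawn(3)
    rng = np.random.default_rng(s_patient)
    patient = _Patient(pid, cfg, rng)

    n_lesions = int(rng.integers(cfg.lesion_count_range[0],
                                 cfg.lesion_count_range[1] + 1))
    lesions = [patient.sample_lesion(cfg, rng) for _ in range(n_lesions)]

    # follow-up lesion evolution (decided from the patient stream so the
    # baseline rendering does not perturb it)
    theta = float(rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg)) \
        if cfg.rotation_max_deg > 0 else 0.0
    pivot = ((cfg.volume_shape[1] - 1) / 2.0, (cfg.volume_shape[2] - 1) / 2.0)
    fu_lesions = []
    for les in lesions:
        if rng.uniform() < cfg.disappear_rate:
            continue
        growth = float(rng.uniform(*cfg.followup_growth_factor_range))
        center = _rotate_center(les.center, pivot, theta)
        fu_lesions.append(_Lesion(center, les.radius_mm * growth))
    for _ in range(rng.poisson(cfg.new_lesion_rate)):
        les = patient.sample_lesion(cfg, rng)
        les.center = _rotate_center(les.center, pivot, theta)
        fu_lesions.append(les)

    cases = []
    for timepoint, tp_lesions, tp_seed in (
            ("baseline", lesions, s_base), ("followup", fu_lesions, s_follow)):
        tp_rng = np.random.default_rng(tp_seed)
        texture, organ = patient.texture, patient.organ
        if timepoint == "followup" and theta != 0.0:
            texture = ndimage.rotate(texture, -theta, axes=(1, 2),
                                     reshape=False, order=1, mode="nearest")
            organ = ndimage.rotate(organ, -theta, axes=(1, 2),
                                   reshape=False, order=0)
        field, mask = _render_lesions(cfg.volume_shape, cfg.spacing_mm,
                                      tp_lesions)
        mask &= organ
        if mask.sum() == 0 and tp_lesions:
            raise SimulationError(
                f"patient {pid} {timepoint}: all lesions fell outside the "
                f"organ mask")
        shift = float(tp_rng.normal(0, cfg.global_intensity_shift_sd))
        scan_noise = ndimage.gaussian_filter(
            tp_rng.normal(size=cfg.volume_shape), sigma=1.2)
        scan_noise /= scan_noise.std() + 1e-9
        anatomy = (texture + cfg.within_patient_noise_sd * scan_noise
                   + shift).astype(np.float32)
        sequences = _compose_sequences(anatomy, field, organ,
                                       patient.lesion_contrast, cfg, tp_rng)
        cases.append(AnnotatedCase(
            patient_id=pid, timepoint=timepoint, sequences=sequences,
            organ_mask=organ, lesion_mask=mask, spacing_mm=cfg.spacing_mm))
    return cases[0], cases[1]


def simulate_cohort(cfg: SyntheticCohortConfig) -> list:
    """All patients' (baseline, followup) pairs; train patients come first."""
    cfg.validate()
    n = cfg.n_train_patients + cfg.n_test_patients
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(n)
    return [simulate_patient(f"p{i:03d}", cfg, children[i]) for i in range(n)]


def write_cohort(cohort: list, cfg: SyntheticCohortConfig, out_dir) -> str:
    """Persist a cohort as NIfTI volumes + JSON manifest; returns manifest path."""
    from pathlib import Path
    out_dir = Path(out_dir)
    entries = []
    for i, (base, follow) in enumerate(cohort):
        split = "train" if i < cfg.n_train_patients else "test"
        entries.append(save_case(base, out_dir, split))
        entries.append(save_case(follow, out_dir, split))
    path = out_dir / "manifest.json"
    save_manifest(entries, path)
    return str(path)


# -- summaries ----------------------------------------------------------------

def _case_feature_vector(case: AnnotatedCase, grid=(6, 12, 12)) -> np.ndarray:
    """Sequence-0 intensities resampled on a fixed grid inside the organ box.

    Gives every case a comparable fixed-length appearance vector so intensity
    correlations can be computed within and between patients.
    """
    vol = case.sequences[0][..., 0]
    idx = np.argwhere(case.organ_mask > 0)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    coords = np.meshgrid(*[np.linspace(l, h, g)
                           for l, h, g in zip(lo, hi, grid)], indexing="ij")
    pts = np.stack([c.ravel() for c in coords])
    return ndimage.map_coordinates(vol, pts, order=1)


def appearance_correlations(cohort: list) -> tuple:
    """(mean within-patient, mean between-patient) appearance correlation."""
    vecs = [(p, _case_feature_vector(b), _case_feature_vector(f))
            for p, (b, f) in enumerate(cohort)]
    within = [np.corrcoef(vb, vf)[0, 1] for _, vb, vf in vecs]
    between = []
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            between.append(np.corrcoef(vecs[i][1], vecs[j][1])[0, 1])
    return float(np.mean(within)), float(np.mean(between))


def cohort_summary(cohort: list) -> "object":
    """Per-patient lesion burden table plus cohort appearance correlations.

    Returns a pandas DataFrame with one row per patient-timepoint and the
    correlations attached in ``df.attrs``.
    """
    import pandas as pd
    from scipy.ndimage import label

    if not cohort:
        raise ValueError("cohort must be nonempty")
    rows = []
    structure = np.ones((3, 3, 3), int)
    for base, follow in cohort:
        for case in (base, follow):
            _, n_objects = label(case.lesion_mask, structure=structure)
            organ_slices = np.flatnonzero(case.organ_mask.any(axis=(1, 2)))
            lesion_slices = np.flatnonzero(case.lesion_mask.any(axis=(1, 2)))
            fractions = [case.lesion_mask[z].sum() / max(case.organ_mask[z].sum(), 1)
                         for z in lesion_slices]
            rows.append({
                "patient_id": case.patient_id,
                "timepoint": case.timepoint,
                "lesion_count": int(n_objects),
                "lesion_volume_mm3": float(case.lesion_mask.sum()
                                           * case.voxel_volume_mm3),
                "n_organ_slices": int(organ_slices.size),
                "n_lesion_slices": int(lesion_slices.size),
                "lesion_slice_fraction": float(lesion_slices.size
                                               / max(organ_slices.size, 1)),
                "mean_lesion_voxel_fraction": float(np.mean(fractions))
                if fractions else 0.0,
            })
    df = pd.DataFrame(rows)
    within, between = appearance_correlations(cohort)
    df.attrs["within_patient_correlation"] = within
    df.attrs["between_patient_correlation"] = between
    return df
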