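"""Reading and writing cohort inputs: NIfTI volumes, bounding-box annotation
tables, tumor-marker tables and clinical tables; marker normalization and
target-lesion selection.

CSV schemas
-----------
annotations: patient_id, lesion_id, site, timepoint, slice_index, x, y,
             width, height, phase
markers:     patient_id, timepoint, marker_name, value (empty = missing)
clinical:    patient_id, sex, her2_status, therapy_line, os_months, event
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .data import (LesionAnnotation, LesionTrack, PatientRecord,
                   MAX_TARGET_LESIONS, MAX_TIMEPOINTS, MIN_TARGET_DIAMETER_MM)
from .preprocess import PATCH_SIZE, build_patch, measure_lesion

ANNOTATION_COLUMNS = ("patient_id", "lesion_id", "site", "timepoint",
                      "slice_index", "x", "y", "width", "height", "phase")


# ---------------------------------------------------------------------------
# marker normalization
# ---------------------------------------------------------------------------

@dataclass
class MarkerStats:
    """Per-marker mean and standard deviation, computed on the training cohort."""

    mean: dict
    sd: dict


def compute_marker_stats(markers: pd.DataFrame) -> MarkerStats:
    stats = markers.dropna(subset=["value"]).groupby("marker_name")["value"]
    mean, sd = stats.mean().to_dict(), stats.std(ddof=0).to_dict()
    for name, s in sd.items():
        if not np.isfinite(s) or s == 0.0:
            raise ValueError(f"marker {name!r} has zero variance in the training cohort")
    return MarkerStats(mean=mean, sd=sd)


def normalize_markers(markers: pd.DataFrame,
                      stats: MarkerStats | None = None
                      ) -> tuple[pd.DataFrame, MarkerStats]:
    """Standardize marker values with training-cohort statistics.

    If ``stats`` is None they are computed from ``markers`` itself (training
    mode); otherwise the supplied (training) statistics are applied, as is
    required for any validation cohort.  Missing values stay missing.
    """
    if stats is None:
        stats = compute_marker_stats(markers)
    out = markers.copy()
    mu = out["marker_name"].map(stats.mean)
    sd = out["marker_name"].map(stats.sd)
    if mu.isna().any() and not out.loc[mu.isna(), "value"].isna().all():
        unknown = sorted(out.loc[mu.isna(), "marker_name"].unique())
        raise ValueError(f"markers without training statistics: {unknown}")
    out["value"] = (out["value"] - mu) / sd
    return out, stats


def denormalize_markers(markers: pd.DataFrame, stats: MarkerStats) -> pd.DataFrame:
    out = markers.copy()
    mu = out["marker_name"].map(stats.mean)
    sd = out["marker_name"].map(stats.sd)
    out["value"] = out["value"] * sd + mu
    return out


# ---------------------------------------------------------------------------
# target-lesion selection
# ---------------------------------------------------------------------------

def select_target_ids(lesion_ids, baseline_diameters_mm,
                      max_targets: int = MAX_TARGET_LESIONS,
                      min_diameter_mm: float = MIN_TARGET_DIAMETER_MM) -> list:
    """RECIST-style selection: keep the primary (id 0) unconditionally, and
    among target lesions keep at most ``max_targets`` with baseline diameter
    strictly above ``min_diameter_mm`` — the largest first, ties broken by
    lesion id."""
    ids = list(lesion_ids)
    diam = {i: float(d) for i, d in zip(ids, baseline_diameters_mm)}
    kept = [i for i in ids if i == 0]
    targets = [i for i in ids if i != 0 and diam[i] > min_diameter_mm]
    targets.sort(key=lambda i: (-diam[i], i))
    return kept + sorted(targets[:max_targets])


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _phase_rule(annotations: list[LesionAnnotation]) -> list[LesionAnnotation]:
    """One contrast phase per lesion: liver uses the venous phase only; other
    sites prefer venous and fall back to arterial."""
    phases = {a.phase for a in annotations}
    site = annotations[0].site
    if site == "liver" or "venous" in phases:
        return [a for a in annotations if a.phase == "venous"]
    return [a for a in annotations if a.phase == "arterial"]


def assemble_record(patient_id: str,
                    annotations: list[LesionAnnotation],
                    volumes: dict,
                    markers: np.ndarray,
                    marker_names: tuple,
                    clinical: dict,
                    patch_size: int = PATCH_SIZE,
                    spacing: float = 1.0,
                    n_timepoints: int = MAX_TIMEPOINTS,
                    keep_volumes: bool = False,
                    apply_selection: bool = True) -> PatientRecord:
    """Build a :class:`PatientRecord` from raw inputs.

    Shared by the phantom generator and :func:`load_cohort`, so that a
    written-then-loaded cohort reproduces the in-memory one exactly.
    """
    by_lesion: dict[int, list[LesionAnnotation]] = {}
    for a in annotations:
        by_lesion.setdefault(a.lesion_id, []).append(a)

    tracks = []
    for lesion_id in sorted(by_lesion):
        anns = _phase_rule(sorted(by_lesion[lesion_id], key=lambda a: a.timepoint))
        if not anns:
            continue
        sizes = {(a.width, a.height) for a in anns}
        if len(sizes) > 1:
            raise ValueError(
                f"patient {patient_id} lesion {lesion_id}: bounding-box size "
                f"varies across timepoints ({sorted(sizes)}); boxes must keep "
                "their baseline size")
        track = LesionTrack(
            lesion_id=lesion_id, site=anns[0].site, phase=anns[0].phase,
            patches=[None] * n_timepoints,
            diameters_mm=np.full(n_timepoints, np.nan),
            areas_mm2=np.full(n_timepoints, np.nan),
            box=anns[0].box, slice_index=anns[0].slice_index)
        for a in anns:
            if a.timepoint not in volumes:
                raise FileNotFoundError(
                    f"annotation for patient {patient_id} lesion {lesion_id} "
                    f"timepoint {a.timepoint} references a missing volume")
            vol = volumes[a.timepoint]
            track.patches[a.timepoint] = build_patch(vol, a, spacing=spacing,
                                                     out_size=patch_size)
            d, ar = measure_lesion(vol, a, spacing=spacing)
            track.diameters_mm[a.timepoint] = d
            track.areas_mm2[a.timepoint] = ar
        tracks.append(track)

    baseline = [t for t in tracks if t.patches[0] is not None]
    if not baseline:
        raise ValueError(f"patient {patient_id} has no baseline bounding boxes")

    if apply_selection:
        kept = set(select_target_ids(
            [t.lesion_id for t in baseline],
            [t.diameters_mm[0] for t in baseline]))
        tracks = [t for t in tracks if t.lesion_id in kept]

    tracks.sort(key=lambda t: (not t.is_primary, t.lesion_id))
    return PatientRecord(
        patient_id=patient_id, lesions=tracks,
        markers=np.asarray(markers, dtype=float),
        marker_names=tuple(marker_names),
        sex=str(clinical["sex"]), her2_status=str(clinical["her2_status"]),
        therapy_line=int(clinical.get("therapy_line", 1)),
        os_months=float(clinical["os_months"]), event=int(clinical["event"]),
        volumes=dict(volumes) if keep_volumes else None)


def read_annotations(path) -> list[LesionAnnotation]:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    annotations = []
    for idx, row in df.iterrows():
        try:
            annotations.append(LesionAnnotation(
                patient_id=str(row.patient_id), lesion_id=int(row.lesion_id),
                site=str(row.site), timepoint=int(row.timepoint),
                slice_index=int(row.slice_index), x=int(row.x), y=int(row.y),
                width=int(row.width), height=int(row.height),
                phase=str(row.phase)))
        except ValueError as err:
            raise ValueError(f"annotation row {idx}: {err}") from err
    return annotations


def _markers_wide(markers: pd.DataFrame, patient_id: str, marker_names: tuple,
                  n_timepoints: int) -> np.ndarray:
    wide = np.full((n_timepoints, len(marker_names)), np.nan)
    sub = markers[markers["patient_id"].astype(str) == patient_id]
    col = {m: j for j, m in enumerate(marker_names)}
    for _, row in sub.iterrows():
        t = int(row.timepoint)
        if t < n_timepoints and row.marker_name in col and pd.notna(row.value):
            wide[t, col[row.marker_name]] = float(row.value)
    return wide


def load_cohort(annotation_csv, image_dir, marker_csv, clinical_csv,
                patch_size: int = PATCH_SIZE, spacing: float = 1.0,
                n_timepoints: int = MAX_TIMEPOINTS,
                keep_volumes: bool = False) -> list[PatientRecord]:
    """Load a full cohort from disk into patient records.

    Volumes are expected as ``<image_dir>/<patient_id>_t<timepoint>.nii.gz``.
    Missing follow-ups are flagged by masks, never imputed; an annotation that
    references an absent volume is a hard error.
    """
    annotations = read_annotations(annotation_csv)
    markers = pd.read_csv(marker_csv)
    clinical = pd.read_csv(clinical_csv)
    marker_names = tuple(sorted(markers["marker_name"].dropna().unique()))

    by_patient: dict[str, list[LesionAnnotation]] = {}
    for a in annotations:
        by_patient.setdefault(a.patient_id, []).append(a)

    records = []
    for _, crow in clinical.sort_values("patient_id").iterrows():
        pid = str(crow.patient_id)
        p_anns = by_patient.get(pid)
        if not p_anns:
            raise ValueError(f"patient {pid} has no annotations (no baseline boxes)")
        volumes = {}
        for t in sorted({a.timepoint for a in p_anns}):
            path = os.path.join(image_dir, f"{pid}_t{t}.nii.gz")
            if not os.path.exists(path):
                raise FileNotFoundError(
                    f"annotation references missing image {path}")
            volumes[t] = np.asarray(nib.load(path).get_fdata(), dtype=np.float32)
        records.append(assemble_record(
            pid, p_anns, volumes,
            _markers_wide(markers, pid, marker_names, n_timepoints),
            marker_names, crow.to_dict(),
            patch_size=patch_size, spacing=spacing, n_timepoints=n_timepoints,
            keep_volumes=keep_volumes))
    return records


def write_volume(path, volume: np.ndarray, spacing: float = 1.0) -> None:
    affine = np.diag([spacing, spacing, spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """YAML-backed run configuration for the command-line workflow."""

    annotation_csv: str = "annotations.csv"
    image_dir: str = "images"
    marker_csv: str = "markers.csv"
    clinical_csv: str = "clinical.csv"
    mode: str = "train"            # train | validate
    patch_size: int = PATCH_SIZE
    spacing: float = 1.0
    seed: int = 0
    model: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("train", "validate"):
            raise ValueError("mode must be 'train' or 'validate'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)


__all__ = ["MarkerStats", "compute_marker_stats", "normalize_markers",
           "denormalize_markers", "select_target_ids", "assemble_record",
           "read_annotations", "load_cohort", "write_volume", "RunConfig",
           "ANNOTATION_COLUMNS"]
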