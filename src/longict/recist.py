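"""Comparator models: RECIST v1.1 response category and TB-delta (percent
change of the summed target-lesion area), assessed between baseline and the
second follow-up — or the first, when that is all a patient has.

Only the diameter-sum rules are implemented (CR / PR / SD / PD on the sum of
longest diameters of target lesions); nodal short-axis rules, non-target
lesions and confirmation scans are out of scope.  New-lesion appearance is an
input flag, not detected.  The primary gastric tumor is never a target
lesion, so assessments use the target-lesion tracks only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PatientRecord

CATEGORIES = ("CR", "PR", "SD", "PD")
PD_GROWTH_PCT = 20.0
PD_ABSOLUTE_MM = 5.0
PR_SHRINKAGE_PCT = -30.0
RECIST_ORDER = {"CR": 0, "PR": 1, "SD": 2, "PD": 3}


@dataclass(frozen=True)
class ResponseAssessment:
    patient_id: str
    recist: str | None
    tb_delta: float | None                  # percent
    reference_timepoint: int | None         # 1 or 2
    missing_followup: bool = False


def recist_classify(diameter_sum_base: float, diameter_sum_follow: float,
                    new_lesion: bool = False) -> str:
    """Classify response from target-lesion diameter sums (mm).

    PD: >= +20 % AND >= +5 mm absolute increase, or any new lesion.
    CR: disappearance of all target lesions.  PR: <= -30 %.  Else SD.
    """
    if diameter_sum_base <= 0:
        raise ValueError("baseline diameter sum must be positive")
    if diameter_sum_follow < 0:
        raise ValueError("negative diameter sum")
    if new_lesion:
        return "PD"
    change = 100.0 * (diameter_sum_follow - diameter_sum_base) / diameter_sum_base
    if diameter_sum_follow == 0.0:
        return "CR"
    if (change >= PD_GROWTH_PCT
            and diameter_sum_follow - diameter_sum_base >= PD_ABSOLUTE_MM):
        return "PD"
    if change <= PR_SHRINKAGE_PCT:
        return "PR"
    return "SD"


def tb_delta(areas_base, areas_follow) -> float:
    """Percent change of the summed target-lesion area (mm^2)."""
    base = float(np.sum(areas_base))
    if len(np.atleast_1d(areas_base)) == 0 or base <= 0:
        raise ValueError("baseline areas must be non-empty with positive sum")
    return 100.0 * (float(np.sum(areas_follow)) - base) / base


def assess_patient(record: PatientRecord, new_lesion: bool = False,
                   diameters: np.ndarray | None = None,
                   areas: np.ndarray | None = None) -> ResponseAssessment:
    """RECIST category and TB-delta for one patient.

    Uses the second follow-up when present, otherwise the first; with no
    follow-up at all the assessment is undefined and flagged.  Measurements
    default to the image-derived per-timepoint diameters/areas stored on the
    record's target-lesion tracks; explicit (lesion x timepoint) tables may
    be passed instead.
    """
    targets = record.target_lesions
    if targets:
        diam = np.stack([t.diameters_mm for t in targets]) if diameters is None \
            else np.asarray(diameters, dtype=float)
        area = np.stack([t.areas_mm2 for t in targets]) if areas is None \
            else np.asarray(areas, dtype=float)
    else:
        # no measurable target lesion: fall back to the primary so the
        # temporal signal is not lost entirely
        diam = np.stack([record.lesions[0].diameters_mm]) if diameters is None \
            else np.asarray(diameters, dtype=float)
        area = np.stack([record.lesions[0].areas_mm2]) if areas is None \
            else np.asarray(areas, dtype=float)
    present = np.all(np.isfinite(diam), axis=0)
    if not present[0]:
        raise ValueError(f"patient {record.patient_id} lacks baseline measurements")
    ref = next((t for t in (2, 1) if t < len(present) and present[t]), None)
    if ref is None:
        return ResponseAssessment(record.patient_id, None, None, None,
                                  missing_followup=True)
    return ResponseAssessment(
        patient_id=record.patient_id,
        recist=recist_classify(float(diam[:, 0].sum()), float(diam[:, ref].sum()),
                               new_lesion=new_lesion),
        tb_delta=tb_delta(area[:, 0], area[:, ref]),
        reference_timepoint=int(ref))


def assess_cohort(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        a = assess_patient(rec)
        rows.append(dict(patient_id=a.patient_id, recist=a.recist,
                         tb_delta=a.tb_delta,
                         reference_timepoint=a.reference_timepoint,
                         missing_followup=a.missing_followup))
    return pd.DataFrame(rows)


def recist_score(categories) -> np.ndarray:
    """Ordinal risk score for a RECIST category series (CR < PR < SD < PD)."""
    return np.array([np.nan if c is None or (isinstance(c, float) and np.isnan(c))
                     else RECIST_ORDER[c] for c in categories], dtype=float)
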