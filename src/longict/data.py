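"""Core data model: lesion annotations, per-lesion longitudinal tracks and
patient records.

Conventions fixed here for reproducibility:

* Box coordinates are 0-based pixel units, ``(x, y)`` is the top-left corner,
  extents are half-open (``x .. x+width``).
* Timepoints are indexed 0..4: 0 = baseline (BL), 1..4 = follow-ups 1F..4F.
* ``lesion_id == 0`` denotes the primary tumor; positive ids are target
  lesions.  The primary is always kept, target lesions are subject to the
  RECIST-style selection rule (diameter > 10 mm at baseline, at most five).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SITES = ("stomach", "lymph_node", "liver", "lung")
LUNG_SITES = frozenset({"lung"})
PHASES = ("arterial", "venous")
MAX_TIMEPOINTS = 5
MAX_TARGET_LESIONS = 5
MIN_TARGET_DIAMETER_MM = 10.0
POOR_OS_MONTHS = 12.0  # binary prognosis horizon: poor OS < 12 months


@dataclass(frozen=True)
class LesionAnnotation:
    """One bounding box on one lesion at one timepoint."""

    patient_id: str
    lesion_id: int
    site: str
    timepoint: int
    slice_index: int
    x: int
    y: int
    width: int
    height: int
    phase: str = "venous"

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"degenerate box for patient {self.patient_id} lesion "
                f"{self.lesion_id} timepoint {self.timepoint}: "
                f"width={self.width}, height={self.height}")
        if not 0 <= self.timepoint < MAX_TIMEPOINTS:
            raise ValueError(f"timepoint {self.timepoint} outside 0..{MAX_TIMEPOINTS - 1}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown contrast phase {self.phase!r}")

    @property
    def box(self) -> tuple[int, int, int, int]:
        return (self.x, self.y, self.width, self.height)


@dataclass
class ImagePatch:
    """Model-ready 3-channel patch for one lesion at one timepoint.

    ``array`` is (S, S, 3) float in [0, 1]; channel 1 is the annotated slice,
    channels 0/2 its lower/upper neighbours.  ``mm_per_px`` is the in-plane
    scale of the resampled square, needed to convert mask extents back to mm.
    """

    array: np.ndarray
    lesion_id: int
    timepoint: int
    site: str
    mm_per_px: float = 1.0

    def __post_init__(self):
        a = self.array
        if a.ndim != 3 or a.shape[0] != a.shape[1] or a.shape[2] != 3:
            raise ValueError(f"patch must be square with 3 channels, got {a.shape}")


@dataclass
class LesionTrack:
    """One lesion followed across timepoints (one contrast phase)."""

    lesion_id: int
    site: str
    phase: str = "venous"
    patches: list = field(default_factory=list)   # ImagePatch | None per timepoint
    diameters_mm: np.ndarray = None
    areas_mm2: np.ndarray = None
    box: tuple | None = None                      # (x, y, w, h), constant across time
    slice_index: int | None = None

    @property
    def is_primary(self) -> bool:
        return self.lesion_id == 0

    @property
    def valid(self) -> np.ndarray:
        return np.array([p is not None for p in self.patches], dtype=bool)

    @property
    def n_timepoints(self) -> int:
        return len(self.patches)


@dataclass
class PatientRecord:
    """Everything known about one patient: lesion tracks, marker series,
    clinical covariates and the censored survival outcome."""

    patient_id: str
    lesions: list                       # list[LesionTrack], primary first
    markers: np.ndarray                 # (T, M) float, NaN where missing
    marker_names: tuple
    sex: str
    her2_status: str
    therapy_line: int
    os_months: float
    event: int
    volumes: dict | None = None         # optional {timepoint: HU volume (H, W, S)}

    def __post_init__(self):
        if not self.lesions:
            raise ValueError(f"patient {self.patient_id} has no lesions")
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0 or 1")

    @property
    def n_timepoints(self) -> int:
        return self.lesions[0].n_timepoints

    @property
    def available_timepoints(self) -> np.ndarray:
        """Timepoints at which at least one lesion has a scan."""
        v = np.zeros(self.n_timepoints, dtype=bool)
        for track in self.lesions:
            v |= track.valid
        return v

    @property
    def target_lesions(self) -> list:
        return [t for t in self.lesions if not t.is_primary]
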