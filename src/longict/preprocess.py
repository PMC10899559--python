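"""ROI preprocessing: annotated lesion box -> model-ready 3-channel patch.

The pipeline mirrors standard longitudinal CT reading practice:

1. expand the annotated bounding box by a factor (default 1.5) around its
   center to include peritumoral context;
2. symmetrically pad the rectangular ROI to its minimum circumscribed square;
3. intensity-window the HU values (lung window -400/1500 for lung lesions,
   abdominal window 50/350 for everything else) to [0, 1];
4. resample to a fixed square resolution (default 224) and stack the
   annotated slice with its lower/upper neighbours into 3 channels.

Training-time augmentation is a random in-plane rotation of +-30 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from .data import ImagePatch, LesionAnnotation, LUNG_SITES

PATCH_SIZE = 224
BOX_EXPANSION = 1.5
ROTATION_MAX_DEG = 30.0


@dataclass(frozen=True)
class WindowSpec:
    """CT display window: linear map of [level-width/2, level+width/2] to [0,1]."""

    level: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")

    @property
    def lo(self) -> float:
        return self.level - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.level + self.width / 2.0


LUNG_WINDOW = WindowSpec(level=-400.0, width=1500.0)
ABDOMEN_WINDOW = WindowSpec(level=50.0, width=350.0)


def window_for_site(site: str) -> WindowSpec:
    """Lung lesions use the lung window; all other sites the abdominal one."""
    return LUNG_WINDOW if site in LUNG_SITES else ABDOMEN_WINDOW


def expand_box(box: tuple, factor: float = BOX_EXPANSION,
               image_bounds: tuple | None = None) -> tuple:
    """Scale ``box = (x, y, w, h)`` about its center, then clip to the image.

    Widths are rounded to the nearest integer; when the added margin is odd
    the extra pixel goes to the trailing side.
    """
    x, y, w, h = box
    if w <= 0 or h <= 0:
        raise ValueError(f"degenerate box {box}")
    nw, nh = int(round(w * factor)), int(round(h * factor))
    nx, ny = x - (nw - w) // 2, y - (nh - h) // 2
    if image_bounds is not None:
        bw, bh = image_bounds
        nx, ny = max(nx, 0), max(ny, 0)
        nw, nh = min(nw, bw - nx), min(nh, bh - ny)
    return (nx, ny, nw, nh)


def pad_to_square(roi: np.ndarray, pad_value: float = 0.0) -> np.ndarray:
    """Pad a 2-D ROI to its minimum circumscribed square.

    Padding is split equally between the two sides of the short axis, with
    the extra pixel on the trailing side when the total is odd.
    """
    if roi.size == 0:
        raise ValueError("empty ROI")
    h, w = roi.shape
    side = max(h, w)
    ph, pw = side - h, side - w
    return np.pad(roi, ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)),
                  constant_values=pad_value)


def apply_window(hu: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Map HU linearly onto [0, 1] over the window range, clipping outside."""
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("non-finite HU values")
    return np.clip((hu - spec.lo) / spec.width, 0.0, 1.0)


def build_patch(volume: np.ndarray, annotation: LesionAnnotation,
                spacing: float = 1.0, out_size: int = PATCH_SIZE,
                factor: float = BOX_EXPANSION) -> ImagePatch:
    """Assemble the 3-channel patch for one annotated lesion at one timepoint.

    ``volume`` is an HU array of shape (H, W, n_slices).  Channels are the
    slices below/at/above ``slice_index``; at the volume boundary the missing
    neighbour is replaced by the central slice.
    """
    h, w, n_slices = volume.shape
    s = annotation.slice_index
    if not 0 <= s < n_slices:
        raise ValueError(
            f"slice {s} outside volume with {n_slices} slices "
            f"(patient {annotation.patient_id}, lesion {annotation.lesion_id})")
    spec = window_for_site(annotation.site)
    ex, ey, ew, eh = expand_box(annotation.box, factor, image_bounds=(w, h))
    side = max(eh, ew)
    channels = []
    for ds in (-1, 0, 1):
        sl = min(max(s + ds, 0), n_slices - 1)
        roi = volume[ey:ey + eh, ex:ex + ew, sl]
        sq = pad_to_square(np.asarray(roi, dtype=float), pad_value=spec.lo)
        win = apply_window(sq, spec)
        channels.append(resize(win, (out_size, out_size), order=1,
                               mode="edge", anti_aliasing=False))
    arr = np.clip(np.stack(channels, axis=-1), 0.0, 1.0).astype(np.float32)
    return ImagePatch(array=arr, lesion_id=annotation.lesion_id,
                      timepoint=annotation.timepoint, site=annotation.site,
                      mm_per_px=side * spacing / out_size)


def augment_rotation(patch: ImagePatch, rng: np.random.Generator,
                     max_deg: float = ROTATION_MAX_DEG,
                     training: bool = True) -> ImagePatch:
    """Random in-plane rotation of the whole 3-channel stack (training only)."""
    if not training:
        raise RuntimeError("rotation augmentation is a training-time operation")
    angle = float(rng.uniform(-max_deg, max_deg))
    arr = patch.array
    fill = float(arr.min())
    rot = ndi.rotate(arr.astype(float), angle, axes=(1, 0), reshape=False,
                     order=1, mode="constant", cval=fill)
    return ImagePatch(array=np.clip(rot, 0.0, 1.0).astype(np.float32),
                      lesion_id=patch.lesion_id, timepoint=patch.timepoint,
                      site=patch.site, mm_per_px=patch.mm_per_px)


def measure_lesion(volume: np.ndarray, annotation: LesionAnnotation,
                   spacing: float = 1.0, factor: float = BOX_EXPANSION,
                   smooth_sigma: float = 1.0) -> tuple[float, float]:
    """Measure the lesion's longest in-plane diameter (mm) and area (mm^2).

    Bounding boxes are kept at their baseline size across timepoints, so size
    change has to be read from the image content: the expanded ROI at the
    annotated slice is smoothed, thresholded midway between the border-ring
    background estimate and the brightest tissue, and the largest connected
    component is measured.
    """
    h, w, n_slices = volume.shape
    ex, ey, ew, eh = expand_box(annotation.box, factor, image_bounds=(w, h))
    roi = np.asarray(volume[ey:ey + eh, ex:ex + ew, annotation.slice_index], dtype=float)
    sm = ndi.gaussian_filter(roi, smooth_sigma)
    ring = np.concatenate([sm[0, :], sm[-1, :], sm[:, 0], sm[:, -1]])
    background = float(np.median(ring))
    peak = float(np.percentile(sm, 99.5))
    if peak <= background:
        return (0.0, 0.0)
    mask = sm > (background + peak) / 2.0
    labels, n = ndi.label(mask)
    if n == 0:
        return (0.0, 0.0)
    largest = 1 + int(np.argmax(ndi.sum_labels(mask, labels, range(1, n + 1))))
    rows, cols = np.nonzero(labels == largest)
    extent = max(rows.max() - rows.min() + 1, cols.max() - cols.min() + 1)
    return (float(extent) * spacing, float(rows.size) * spacing ** 2)
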