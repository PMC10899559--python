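"""The four ROI preprocessing steps on one annotated lesion.

Box expansion (1.5x), symmetric square padding, HU windowing (lung
-400/1500, abdomen 50/350) and 3-channel stacking of adjacent slices.
"""

import numpy as np

from longict import LesionAnnotation, apply_window, build_patch, expand_box
from longict.preprocess import ABDOMEN_WINDOW, LUNG_WINDOW

box = (40, 50, 20, 24)
print("annotated box        :", box)
print("expanded 1.5x        :", expand_box(box, 1.5, image_bounds=(128, 128)))

print("\nHU -> display value")
for hu in (-1000, -400, 50, 225, 400):
    lung = apply_window(np.array([float(hu)]), LUNG_WINDOW)[0]
    abd = apply_window(np.array([float(hu)]), ABDOMEN_WINDOW)[0]
    print(f"  {hu:>6} HU   lung {lung:.3f}   abdomen {abd:.3f}")

rng = np.random.default_rng(0)
volume = rng.normal(40.0, 20.0, size=(128, 128, 5))
ann = LesionAnnotation(patient_id="P0", lesion_id=1, site="liver",
                       timepoint=0, slice_index=2, x=40, y=50,
                       width=20, height=24)
patch = build_patch(volume, ann, out_size=224)
print(f"\npatch shape {patch.array.shape}, values in "
      f"[{patch.array.min():.2f}, {patch.array.max():.2f}], "
      f"{patch.mm_per_px:.3f} mm/px")
print("The three channels are the slices below/at/above the annotation.")
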