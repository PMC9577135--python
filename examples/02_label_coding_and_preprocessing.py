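"""Color-legend label coding, class merging, and ROI preprocessing.

Decodes an RGB label raster against the class legend, merges the
background/adipose pair into a super-class, resamples a ROI to the working
resolution and standardizes it against training-pool statistics.
"""

import numpy as np

from alseg import (
    compute_stats,
    decode_label_png,
    encode_label_png,
    generate_cohort,
    merge_classes,
    premerge_legend,
    resize_to_mpp,
    standardize,
)
from alseg.legend import LabelMap
from alseg.synthetic import CohortConfig

# --- decode / encode against the color legend -----------------------------
pre = premerge_legend()  # 12 classes: Background and Adipose still separate
raster = np.tile(np.array([0, 0, 255], np.uint8), (2, 2, 1))  # Tumor is blue
labels = decode_label_png(raster, pre)
print("decoded all-blue raster ->", pre.name_of(int(labels.indices[0, 0])))

# --- merge the visually indistinguishable pair -----------------------------
idx = np.array([[pre.index_of("Background"), pre.index_of("Adipose"),
                 pre.index_of("Tumor"), pre.avoid_index]], np.int16)
merged, legend11 = merge_classes(LabelMap(idx, pre), pre,
                                 ("Background", "Adipose"), "Background/Adipose")
print(f"merged legend has {legend11.n_classes} tissue classes;",
      "pixels:", [legend11.name_of(i) if i != legend11.avoid_index else "avoid"
                  for i in merged.indices[0]])

# --- resample and standardize a ROI ----------------------------------------
cohort, _ = generate_cohort(CohortConfig(n_patients=4, n_extra_rois=0,
                                         image_size=64, mpp=1.0, seed=0))
stats = compute_stats(cohort)
s = resize_to_mpp(cohort[0], target_mpp=2.0)
z = standardize(s.image, stats)
print(f"resampled {cohort[0].labels.shape} @1um/px -> {s.labels.shape} @2um/px")
print(f"standardized image: mean {z.mean():+.3f}, std {z.std():.3f} "
      "(centered on the training pool)")
roundtrip = decode_label_png(encode_label_png(s.labels), s.labels.legend, strict=True)
print("label color round-trip exact:", bool((roundtrip.indices == s.labels.indices).all()))
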