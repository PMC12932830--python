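"""Patient-level stratified 70/15/15 splitting.

Splitting happens on patients, never images, so no patient leaks across
partitions. On a balanced 160-patient cohort with 38 images each the
split reproduces 112/24/24 patients and 4,256/912/912 images; on 790
patients it gives 553 train patients (21,014 images).
"""

import pandas as pd

from arlnet.preprocessing import SplitSpec, patient_level_split, verify_no_leakage


def manifest(n_patients: int, images_per_patient: int = 38) -> pd.DataFrame:
    rows = [{"patient_id": f"P{p:04d}", "image_id": f"P{p:04d}_I{i:03d}",
             "label": p % 2}
            for p in range(n_patients) for i in range(images_per_patient)]
    return pd.DataFrame(rows)


for n in (160, 790):
    split = patient_level_split(manifest(n), SplitSpec(seed=0))
    print(f"{n} patients -> train {len(split.train_patients)} patients "
          f"({len(split.train_idx)} images), val {len(split.val_patients)} "
          f"({len(split.val_idx)}), test {len(split.test_patients)} "
          f"({len(split.test_idx)}); leak-free={verify_no_leakage(split).ok}")
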