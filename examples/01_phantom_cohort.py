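"""Generate a small phantom CT cohort and inspect its structure.

Each patient contributes a fixed number of 128x128 grayscale slices;
cancer patients' images contain one bright elliptical nodule recorded in
a binary lesion mask. The printed counts show the patient-level class
balance and that every cancer image carries a non-empty mask.
"""

import tempfile

from arlnet.phantom import PhantomConfig, generate_cohort, write_dataset

config = PhantomConfig(n_patients=8, images_per_patient=6, image_size=128,
                       nodule_contrast=0.4, seed=0)
records = generate_cohort(config)

patients = {r.patient_id for r in records}
cancer_patients = {r.patient_id for r in records if r.label == 1}
print(f"records: {len(records)} ({len(patients)} patients x "
      f"{config.images_per_patient} images)")
print(f"cancer patients: {len(cancer_patients)} / {len(patients)}")
masked = sum(1 for r in records if r.label == 1 and r.lesion_mask.any())
print(f"cancer images with a lesion mask: {masked} / "
      f"{sum(r.label for r in records)}")

with tempfile.TemporaryDirectory() as tmp:
    manifest = write_dataset(records, tmp)
    print(f"manifest written to {manifest.name} (PNGs + lossless float archive)")
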