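"""Run the active-reinforcement pseudo-labeling loop.

Uncertain samples (high prediction entropy) are pseudo-labeled by the
Q-learning agent (reward +1 when the label matches the classifier's
prediction) and unioned into the labeled pool; the classifier retrains
each iteration. The history shows the pool growing and the validation
accuracy holding or improving; 'noise' is the pseudo-label disagreement
with the phantom ground truth (bookkeeping only).
"""

import numpy as np

from arlnet.arl import ARLConfig, arl_loop
from arlnet.models import ModelSpec, TrainConfig, build_simple_cnn, train_model
from arlnet.phantom import PhantomConfig, generate_cohort, cohort_arrays

records = generate_cohort(PhantomConfig(n_patients=20, images_per_patient=4,
                                        image_size=32, nodule_contrast=0.5,
                                        nodule_radius_range=(4, 7), seed=3))
X, y, pids = cohort_arrays(records)

# class-balanced patient-level pools: 4 labeled, 4 validation, 12 unlabeled
patients = sorted(set(pids), key=lambda p: pids.index(p))
label_of = {p: y[pids.index(p)] for p in patients}
by_class = {c: [p for p in patients if label_of[p] == c] for c in (0, 1)}
labeled_p = set(by_class[0][:2] + by_class[1][:2])
val_p = set(by_class[0][2:4] + by_class[1][2:4])
mask_lab = np.array([p in labeled_p for p in pids])
mask_val = np.array([p in val_p for p in pids])
mask_unl = ~(mask_lab | mask_val)

model = build_simple_cnn(ModelSpec("simple_cnn", input_size=32, seed=3))
train_model(model, (X[mask_lab], y[mask_lab]), None,
            TrainConfig(epochs=6, batch_size=8, learning_rate=2e-3, seed=3))

cfg = ARLConfig(batch_size=16, max_iterations=3, episodes_per_batch=10,
                retrain_epochs=2, state_mode="probability", seed=3)
retrain_cfg = TrainConfig(epochs=2, batch_size=8, learning_rate=1e-3, seed=3)
model, qtable, history = arl_loop(
    (X[mask_lab], y[mask_lab]), X[mask_unl], model, cfg,
    val=(X[mask_val], y[mask_val]),
    retrain_fn=lambda m, Xp, yp: train_model(m, (Xp, yp), None, retrain_cfg),
    true_unlabeled_labels=y[mask_unl])

frame = history.to_frame()
cols = ["iteration", "labeled_pool", "pseudo_labels", "pseudo_label_noise",
        "accuracy"]
print(frame[cols].round(3).to_string(index=False))
print(f"Q-table states learned: {len(qtable)}")
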