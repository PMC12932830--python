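# arlnet

Active-reinforcement pseudo-labeling, attention-fusion CNNs and fused
radiomic features for lung-nodule CT classification — with a built-in
synthetic phantom cohort so the entire pipeline runs end to end on a
laptop CPU, no external imaging data required.

## The problem

Training accurate lung-cancer classifiers on CT requires large
expert-labeled image sets, and annotation is the bottleneck. `arlnet`
implements a semi-supervised pipeline for binary (cancer / non-cancer)
slice classification that starts from a small labeled cohort and labels
the rest of the data itself:

1. **Uncertainty selection.** The current classifier scores a batch of
   unlabeled images; the prediction entropy
   `H(p) = -[p ln p + (1-p) ln(1-p)]` ranks them, and the top-k samples
   above an entropy threshold are selected.
2. **Q-learning pseudo-labeling.** A tabular agent assigns the labels.
   The MDP is (S, A, P, R, γ): states are discretized image feature
   vectors, actions are the two labels, the transition moves to the
   next selected image, and the reward is +1 when the chosen label
   matches the classifier's own predicted class, −1 otherwise.
   Q-values follow `Q(s,a) ← Q(s,a) + α[r + γ max_a' Q(s',a') − Q(s,a)]`
   with α = 0.1, γ = 0.95, ε-greedy exploration at ε = 0.1, batches of
   200 and up to 120 iterations.
3. **Pool union and retraining.** Pseudo-labeled samples join the
   labeled pool and the classifier retrains, iterating until the pool
   is exhausted.

Around that loop the package provides:

* **Three CNN architectures** (NumPy, CPU): a simple CNN
  (3×3 convs with 32/64/128 filters; convolutional backbone exactly
  92,672 trainable parameters), a simplified CoAtNet variant (three
  128-filter convs plus a parameter-free self-attention token-mixing
  step; 296,448 backbone parameters), and a dual-branch CNN with
  channel + spatial attention fusion. All end in global average pooling
  (128-dim), a dense head and one sigmoid unit trained with Adam on
  binary cross-entropy.
* **A 176-dim fused feature vector** per image: 25 LBP histogram bins +
  15 GLCM statistics (contrast, dissimilarity, homogeneity, energy,
  correlation × 3 directions), 3 shape and 5 intensity features, and
  the 128-dim CNN representation — standardized on the training set and
  passed through a learned per-dimension sigmoid gate before early
  fusion.
* **Leak-free evaluation**: patient-level stratified 70/15/15 splits
  (no patient crosses partitions), threshold metrics, rank-based
  ROC-AUC with stratified-bootstrap CIs, the DeLong test, paired
  t/Wilcoxon comparisons, decision-curve analysis, and three feature
  selectors (CFS, forest importance, RFE) feeding a classical bench
  (XGBoost, random forest, decision tree, Gaussian naive Bayes).
* **Explainability**: Grad-CAM heatmaps scored against lesion masks by
  IoU (top-20% binarization) and the Pointing Game.
* **A phantom generator** that emulates the target cohort's structure —
  patients × images-per-patient with balanced patient-level labels,
  textured lung-field backgrounds and one bright elliptical nodule per
  cancer image, each with an exact binary lesion mask.

## Worked example

`examples/` holds one short script per capability. For instance the
patient-level splitter (`examples/02_patient_split.py`):

```text
160 patients -> train 112 patients (4256 images), val 24 (912), test 24 (912); leak-free=True
790 patients -> train 553 patients (21014 images), val 119 (4522), test 118 (4484); leak-free=True
```

On a balanced 160-patient cohort with 38 images each, the 70/15/15
patient split yields exactly 112/24/24 patients and 4,256/912/912
images, with disjoint patient sets. Architecture pinning and training
(`examples/04_train_cnn.py`):

```text
simple CNN conv backbone parameters: 92672
simplified CoAtNet conv backbone parameters: 296448
train accuracy per epoch: [0.53, 0.42, 0.64, 0.81, 0.89, 0.97, 1.0, 0.97]
```

The two counts are the exact trainable-parameter totals of the
convolutional backbones; the trace shows the simple CNN fitting an easy
12-patient phantom cohort in a few epochs. Grad-CAM localization
(`examples/07_gradcam.py`) after brief training of the attention-fusion
CNN on 64×64 phantoms:

```text
scored images: 15
Pointing Game accuracy: 1.00
mean IoU (top-20% heatmap vs mask): 0.43
```

i.e. on every held-out cancer image the heatmap peak falls inside the
lesion mask, and the top-20% heatmap region overlaps the mask with mean
IoU 0.43. The full pipeline (generate → split → train → ARL →
features → bench → evaluation → XAI) is driven by a YAML config:

```bash
arlnet run --config run.yaml     # or: python -m arlnet.cli run ...
```

## Layout

```
src/arlnet/
  phantom.py        synthetic cohort generator (images + lesion masks)
  preprocessing.py  resize, normalize, patient-level stratified split
  nn.py             NumPy layer framework (conv, pool, dense, attention, Adam)
  models.py         the three architectures, training loop, Grad-CAM hooks
  features.py       LBP/GLCM/shape/intensity + deep features, gating, fusion
  arl.py            entropy selection, Q-table, pseudo-labeling loop
  evaluation.py     metrics, DeLong, bootstrap, DCA, selectors, bench
  xai.py            Grad-CAM, IoU, Pointing Game
  pipeline.py       YAML-configured end-to-end runner
  cli.py            thin command-line layer
docs/methods.md     model assumptions, parameter choices, limitations
examples/           one narrative script per capability
tests/              pytest suite (unit, property and end-to-end checks)
```
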