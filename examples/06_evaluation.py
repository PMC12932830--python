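"""Statistical evaluation of classifier scores.

Computes threshold metrics from the confusion counts, rank-based
ROC-AUC with a stratified-bootstrap confidence interval, the DeLong
test between two score vectors, and decision-curve net benefit (the
model's curve should sit above treat-all for thresholds beyond the
prevalence).
"""

import numpy as np

from arlnet.evaluation import (bootstrap_auc_ci, decision_curve, delong_test,
                               evaluate_probabilities)

rng = np.random.default_rng(0)
n = 200
y = np.tile([0, 1], n // 2)
good = np.clip(0.6 * y + rng.normal(0.2, 0.18, n), 0, 1)   # strong model
weak = np.clip(0.3 * y + rng.normal(0.35, 0.25, n), 0, 1)  # weaker model

report = evaluate_probabilities(y, good, B=500, seed=1)
print(f"accuracy {report.accuracy:.3f}  recall {report.recall:.3f}  "
      f"specificity {report.specificity:.3f}")
print(f"ROC-AUC {report.roc_auc:.3f} (95% CI {report.auc_ci[0]:.3f}-"
      f"{report.auc_ci[1]:.3f})  PR-AUC {report.pr_auc:.3f}  "
      f"Brier {report.brier:.3f}")

diff, z, p = delong_test(y, good, weak)
print(f"DeLong: AUC difference {diff:+.3f}, z {z:.2f}, p {p:.2e}")

curve = decision_curve(y, good, np.array([0.2, 0.5, 0.8]))
print(curve.round(3).to_string(index=False))
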