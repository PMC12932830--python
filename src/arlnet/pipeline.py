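"""Config-driven end-to-end runner.

Ties the stages together — phantom generation, patient-level splitting,
initial training, the active-reinforcement labeling loop, fused feature
extraction, feature selection and the classical bench, statistical
evaluation, and Grad-CAM localization scoring — writing every
intermediate artifact plus a machine-readable summary, reproducibly
under a single global seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arl, evaluation, features, models, phantom, preprocessing, xai

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "run"
    phantom: phantom.PhantomConfig = field(default_factory=phantom.PhantomConfig)
    split: preprocessing.SplitSpec = field(default_factory=preprocessing.SplitSpec)
    arl: arl.ARLConfig = field(default_factory=arl.ARLConfig)
    architecture: str = "simple_cnn"
    initial_epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 2e-3
    labeled_fraction: float = 0.2     # of patients initially labeled
    selectors: tuple[str, ...] = ("all", "cfs", "ff", "rfe")
    classifiers: tuple[str, ...] = ("xgb", "rf", "dt", "nb")
    k_features: int = 40
    bootstrap_B: int = 200
    seed: int = 0


_NESTED = {"phantom": phantom.PhantomConfig,
           "split": preprocessing.SplitSpec,
           "arl": arl.ARLConfig}


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _NESTED:
            cls = _NESTED[key]
            sub_known = {f.name for f in dataclasses.fields(cls)}
            sub_unknown = set(value) - sub_known
            if sub_unknown:
                raise ValueError(f"unknown {key} keys: {sorted(sub_unknown)}")
            if "nodule_radius_range" in value:
                value["nodule_radius_range"] = tuple(value["nodule_radius_range"])
            kwargs[key] = cls(**value)
        elif key in ("selectors", "classifiers"):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["phantom"]["nodule_radius_range"] = list(d["phantom"]["nodule_radius_range"])
    d["selectors"] = list(d["selectors"])
    d["classifiers"] = list(d["classifiers"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure aborts with the stage name while keeping the
    artifacts written so far.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("arlnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict[str, dict] = {}
    stage = "setup"

    def finish(name: str, t0: float, **info) -> None:
        summary[name] = {"seconds": round(time.perf_counter() - t0, 3), **info}
        logger.info("stage %s done: %s", name, info)

    try:
        # -------------------------------------------------- generate
        stage = "generate"
        t0 = time.perf_counter()
        records = phantom.generate_cohort(config.phantom)
        manifest_path = phantom.write_dataset(records, out / "data")
        X, y, pids = phantom.cohort_arrays(records)
        manifest = pd.read_csv(manifest_path)
        finish(stage, t0, n_images=len(records),
               n_patients=config.phantom.n_patients)

        # -------------------------------------------------- pools + split
        stage = "split"
        t0 = time.perf_counter()
        rng = np.random.default_rng(config.seed)
        patients = sorted(set(pids))
        patient_label = {p: int(y[pids.index(p)]) for p in patients}
        by_class: dict[int, list[str]] = {0: [], 1: []}
        for p in patients:
            by_class[patient_label[p]].append(p)
        labeled_patients: set[str] = set()
        for c, plist in by_class.items():
            n_lab = int(round(config.labeled_fraction * len(plist)))
            order = rng.permutation(len(plist))
            labeled_patients |= {plist[i] for i in order[:n_lab]}
        lab_mask = np.array([p in labeled_patients for p in pids])
        lab_manifest = manifest[lab_mask].reset_index(drop=True)
        split = preprocessing.patient_level_split(lab_manifest, config.split)
        leak = preprocessing.verify_no_leakage(split)
        if not leak.ok:
            raise preprocessing.DataIntegrityError(
                f"leakage: {leak.violating_patients}")
        split.to_json(out / "split.json")
        X_lab, y_lab = X[lab_mask], y[lab_mask]
        tr, va, te = split.train_idx, split.val_idx, split.test_idx
        finish(stage, t0, labeled_patients=len(labeled_patients),
               train_images=len(tr), val_images=len(va), test_images=len(te))

        # -------------------------------------------------- initial training
        stage = "initial_train"
        t0 = time.perf_counter()
        spec = models.ModelSpec(config.architecture,
                                input_size=config.phantom.image_size,
                                seed=config.seed)
        model = models.build_model(spec)
        init_cfg = models.TrainConfig(epochs=config.initial_epochs,
                                      batch_size=config.batch_size,
                                      learning_rate=config.learning_rate,
                                      seed=config.seed)
        hist = models.train_model(model, (X_lab[tr], y_lab[tr]),
                                  (X_lab[va], y_lab[va]), init_cfg)
        initial_val_acc = hist.val_acc[-1] if hist.val_acc else float("nan")
        finish(stage, t0, epochs=config.initial_epochs,
               val_accuracy=initial_val_acc)

        # -------------------------------------------------- ARL loop
        stage = "arl"
        t0 = time.perf_counter()
        unl_mask = ~lab_mask
        X_unl, y_unl_truth = X[unl_mask], y[unl_mask]
        retrain_cfg = models.TrainConfig(epochs=config.arl.retrain_epochs,
                                         batch_size=config.batch_size,
                                         learning_rate=config.learning_rate,
                                         seed=config.seed)

        def retrain(m, Xp, yp):
            models.train_model(m, (Xp, yp), None, retrain_cfg)

        model, qtable, history = arl.arl_loop(
            (X_lab[tr], y_lab[tr]), X_unl, model, config.arl,
            val=(X_lab[va], y_lab[va]), retrain_fn=retrain,
            true_unlabeled_labels=y_unl_truth)
        history.to_frame().to_csv(out / "arl_history.csv", index=False)
        qtable.to_json(out / "qtable.json")
        models.save_model(model, out / "model.npz")
        final_val_acc = (history.rows[-1]["accuracy"]
                         if history.rows else initial_val_acc)
        finish(stage, t0, iterations=len(history), q_states=len(qtable),
               val_accuracy=final_val_acc)

        # -------------------------------------------------- fused features
        stage = "features"
        t0 = time.perf_counter()
        pipe = features.FusedFeaturePipeline(model, seed=config.seed)
        pipe.fit(X_lab[tr], y_lab[tr])
        ids = lab_manifest["image_id"].tolist()
        frame = pipe.to_frame(X_lab, ids)
        frame.to_csv(out / "features.csv")
        finish(stage, t0, n_rows=len(frame), n_columns=frame.shape[1])

        # -------------------------------------------------- selection + bench
        stage = "bench"
        t0 = time.perf_counter()
        F = frame.to_numpy()
        bench = evaluation.run_classifier_bench(
            F[tr], y_lab[tr], F[te], y_lab[te],
            selectors=config.selectors, classifiers=config.classifiers,
            k_features=min(config.k_features, F.shape[1]), seed=config.seed)
        bench.to_csv(out / "bench.csv", index=False)
        finish(stage, t0, rows=len(bench))

        # -------------------------------------------------- evaluation
        stage = "evaluate"
        t0 = time.perf_counter()
        p_test = model.predict_proba(X_lab[te])
        report = evaluation.evaluate_probabilities(
            y_lab[te], p_test, B=config.bootstrap_B, seed=config.seed)
        with open(out / "eval.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        report.decision_curve.to_csv(out / "decision_curve.csv", index=False)
        finish(stage, t0, test_accuracy=report.accuracy,
               roc_auc=report.roc_auc)

        # -------------------------------------------------- XAI
        stage = "xai"
        t0 = time.perf_counter()
        te_recs = [r for r, m in zip(records, lab_mask) if m]
        te_recs = [te_recs[i] for i in te]
        cancer = [r for r in te_recs if r.label == 1]
        rows = []
        for r in cancer:
            h = xai.grad_cam(model, r.pixels)
            rows.append({"image_id": r.image_id,
                         "iou": xai.iou_score(xai.binarize_heatmap(h),
                                              r.lesion_mask),
                         "pointing_hit": xai.pointing_game(h, r.lesion_mask)})
        xai_frame = pd.DataFrame(rows)
        xai_frame.to_csv(out / "xai_scores.csv", index=False)
        finish(stage, t0,
               pointing_game_accuracy=float(xai_frame["pointing_hit"].mean()),
               mean_iou=float(xai_frame["iou"].mean()))
    except Exception:
        logger.exception("pipeline aborted in stage %r", stage)
        summary[stage] = {"failed": True}
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        root.removeHandler(handler)
        raise RuntimeError(f"pipeline failed in stage {stage!r}")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    root.removeHandler(handler)
    return out
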