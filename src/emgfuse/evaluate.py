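"""Accuracy metrics, confusion matrices, per-subject aggregation, and the
single-stream vs two-stream ablation harness.

Per-subject accuracy (Acc) is the fraction of correctly classified test
windows for that subject; the overall accuracy (OA) is the unweighted
mean of the per-subject accuracies — subjects, not windows, are the unit
of aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from emgfuse.ninapro_io import DEFAULT_TEST_REPS, DEFAULT_TRAIN_REPS, RecordingSession
from emgfuse.model import SingleStream, TwoStream, branch_spec, build_two_stream, two_stream_spec
from emgfuse.preprocess import FilterSpec, PairedWindows, WindowSpec, build_datasets
from emgfuse.train import TrainConfig, train_model

logger = logging.getLogger(__name__)

ABLATION_CONDITIONS = ("emg-only", "acc-only", "fused", "fused+eca", "fused-attention")


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of correctly classified segments."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("pred and truth must be nonempty vectors of equal length")
    return float((pred == truth).mean())


def overall_accuracy(per_subject: list[float]) -> float:
    """Unweighted mean of per-subject accuracies."""
    vals = np.asarray(list(per_subject), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one per-subject accuracy")
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("accuracies must lie in [0, 1]")
    return float(vals.mean())


def confusion_matrix(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> np.ndarray:
    """(i, j) = number of windows with true label i predicted j."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    for name, v in (("pred", pred), ("truth", truth)):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    return _sk_confusion(truth, pred, labels=np.arange(n_classes)).astype(np.int64)


@dataclass
class EvalReport:
    """Per-subject accuracies, overall accuracy, confusion, ablation table."""

    per_subject_acc: dict[str, float]
    overall_acc: float
    confusion: np.ndarray | None = None
    ablation_table: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [f"overall accuracy (OA): {self.overall_acc:.4f}"]
        for sid, acc in self.per_subject_acc.items():
            lines.append(f"  subject {sid}: Acc = {acc:.4f}")
        if self.ablation_table is not None:
            lines.append(self.ablation_table.to_string(index=False))
        return "\n".join(lines)


def evaluate_model(model, test: PairedWindows, n_classes: int | None = None):
    """Window accuracy and confusion matrix of a trained model on a test split.

    The confusion matrix is indexed by the model's class list (``classes_``)
    so its size is the number of trained classes regardless of the raw
    gesture ids.
    """
    classes = np.asarray(model.classes_)
    lut = {c: i for i, c in enumerate(classes)}
    truth = np.array([lut[c] for c in test.labels])
    if isinstance(model, TwoStream):
        pred = model.predict(test.emg.x, test.acc.x)
    elif isinstance(model, SingleStream):
        kind = "emg" if model.branch.spec.input_shape[0] == test.emg.x.shape[1] else "acc"
        pred = model.predict(getattr(test, kind).x)
    else:
        raise TypeError(f"unsupported model type {type(model)!r}")
    n_classes = n_classes or classes.size
    return accuracy(pred, truth), confusion_matrix(pred, truth, n_classes)


def _build_condition_model(condition: str, L: int, n_classes: int,
                           dropout: float, seed: int, preset: str):
    if condition == "emg-only":
        return SingleStream(branch_spec(preset, (12, L)), n_classes,
                            use_attention=True, dropout_rate=dropout, seed=seed)
    if condition == "acc-only":
        return SingleStream(branch_spec(preset, (36, L)), n_classes,
                            use_attention=True, dropout_rate=dropout, seed=seed)
    if condition in ("fused", "fused+eca"):
        return build_two_stream(two_stream_spec(L, n_classes, preset,
                                                use_attention=True,
                                                dropout_rate=dropout, seed=seed))
    if condition == "fused-attention":
        return build_two_stream(two_stream_spec(L, n_classes, preset,
                                                use_attention=False,
                                                dropout_rate=dropout, seed=seed))
    raise ValueError(
        f"unknown condition {condition!r}; choose from {ABLATION_CONDITIONS}"
    )


def evaluate_sessions(
    sessions: list[RecordingSession],
    config: TrainConfig,
    wspec: WindowSpec | None = None,
    fspec: FilterSpec | None = None,
    preset: str = "small",
    condition: str = "fused",
    train_reps=DEFAULT_TRAIN_REPS,
    test_reps=DEFAULT_TEST_REPS,
    include_rest: bool = False,
) -> EvalReport:
    """Preprocess -> train -> test each subject independently; average per Acc/OA.

    Returns an :class:`EvalReport` whose confusion matrix is the sum over
    subjects.
    """
    per_subject: dict[str, float] = {}
    confusion_total = None
    for session in sessions:
        ds = build_datasets(session, wspec, fspec, train_reps, test_reps, include_rest)
        n_classes = np.unique(ds.train.labels).size
        L = ds.train.emg.x.shape[2]
        model = _build_condition_model(condition, L, n_classes, config.dropout,
                                       config.seed, preset)
        model, _ = train_model(model, ds.train, config)
        acc, conf = evaluate_model(model, ds.test)
        per_subject[session.subject_id] = acc
        confusion_total = conf if confusion_total is None else confusion_total + conf
        logger.info("subject %s [%s]: Acc = %.4f", session.subject_id, condition, acc)
    return EvalReport(
        per_subject_acc=per_subject,
        overall_acc=overall_accuracy(list(per_subject.values())),
        confusion=confusion_total,
    )


def run_ablation(
    sessions: list[RecordingSession],
    conditions=("emg-only", "acc-only", "fused"),
    window_T_ms: list[float] = (200.0,),
    config: TrainConfig = TrainConfig(),
    preset: str = "small",
    S_ms: float = 50.0,
    fspec: FilterSpec | None = None,
    seeds: list[int] | None = None,
) -> EvalReport:
    """Sweep conditions x window lengths (x seeds), per-subject then averaged.

    Conditions: ``emg-only`` / ``acc-only`` (single branch + ECA + head),
    ``fused`` (the full two-stream model; ``fused+eca`` is an alias) and
    ``fused-attention`` (fusion with ECA removed).  The result's
    ``ablation_table`` has one row per (condition, T_ms, seed) with the
    overall accuracy, plus per-subject columns.
    """
    if not sessions:
        raise ValueError("need at least one session")
    unknown = set(conditions) - set(ABLATION_CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition(s) {sorted(unknown)}")
    seeds = list(seeds) if seeds is not None else [config.seed]
    fs = sessions[0].sampling_rate_hz
    rows = []
    last_report = None
    for condition in conditions:
        for T in window_T_ms:
            for seed in seeds:
                cfg = TrainConfig(**{**config.__dict__, "seed": seed})
                wspec = WindowSpec(T_ms=T, S_ms=S_ms, sampling_rate_hz=fs)
                report = evaluate_sessions(
                    sessions, cfg, wspec, fspec, preset, condition
                )
                row = {
                    "condition": condition,
                    "T_ms": T,
                    "seed": seed,
                    "overall_acc": report.overall_acc,
                }
                row.update({f"acc_{k}": v for k, v in report.per_subject_acc.items()})
                rows.append(row)
                last_report = report
    table = pd.DataFrame(rows)
    return EvalReport(
        per_subject_acc=last_report.per_subject_acc,
        overall_acc=last_report.overall_acc,
        confusion=last_report.confusion,
        ablation_table=table,
    )


def plot_confusion(confusion: np.ndarray, path: str, class_labels=None) -> str:
    """Render a confusion-matrix heatmap to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(confusion, cmap="viridis")
    ax.set_xlabel("predicted label")
    ax.set_ylabel("true label")
    if class_labels is not None:
        ax.set_xticks(range(len(class_labels)), class_labels)
        ax.set_yticks(range(len(class_labels)), class_labels)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
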