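"""Classifier evaluation: ROC curves, AUC, confusion matrices and derived
metrics, and the best-vs-random panel comparison report.

AUC is the Mann-Whitney probability that a random case outscores a random
control (ties counted half), which equals the trapezoidal area under the ROC
curve; the positive class is always the case (label 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import sklearn.metrics as skm

__all__ = [
    "RocCurve",
    "EvaluationReport",
    "compute_auc",
    "roc_curve",
    "evaluate_predictions",
    "PanelComparison",
    "compare_to_random_panels",
]


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    present = set(np.unique(labels))
    if present != {0, 1}:
        raise ValueError(
            f"need both classes (0 and 1) present, found {sorted(present)}"
        )
    return labels


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve of the scores against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    return float(skm.roc_auc_score(labels, scores))


@dataclass
class RocCurve:
    """ROC curve points (one per distinct threshold, plus endpoints)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def write_tsv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(f"# auc={self.auc:.6f}\nfpr\ttpr\n")
            for x, y in zip(self.fpr, self.tpr):
                fh.write(f"{x:.6f}\t{y:.6f}\n")


def roc_curve(scores, labels) -> RocCurve:
    """ROC curve with trapezoidal AUC; starts at (0,0), ends at (1,1)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    fpr, tpr, thresholds = skm.roc_curve(labels, scores)
    return RocCurve(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=float(np.trapezoid(tpr, fpr)),
    )


@dataclass
class EvaluationReport:
    """Confusion matrix (case = positive) and the four derived metrics.

    Metrics are stored as fractions in [0, 1]; ``to_text`` renders them as
    percentages with two decimals.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None = None

    @property
    def n_samples(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d

    def to_text(self) -> str:
        lines = [
            "predicted\\true\tcase\tcontrol",
            f"case\t{self.tp}\t{self.fp}",
            f"control\t{self.fn}\t{self.tn}",
            f"Precision\t{self.precision * 100:.2f}%",
            f"Accuracy\t{self.accuracy * 100:.2f}%",
            f"Sensitivity\t{self.sensitivity * 100:.2f}%",
            f"Specificity\t{self.specificity * 100:.2f}%",
        ]
        if self.auc is not None:
            lines.append(f"AUC\t{self.auc:.4f}")
        return "\n".join(lines) + "\n"

    def write_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def evaluate_predictions(
    predicted_labels, true_labels, scores=None
) -> EvaluationReport:
    """Confusion matrix and precision/accuracy/sensitivity/specificity.

    ``scores``, when given, additionally yields the AUC.  The case class
    (label 1) is the positive class.
    """
    pred = np.asarray(predicted_labels).astype(int)
    true = np.asarray(true_labels).astype(int)
    if pred.shape != true.shape:
        raise ValueError(
            f"length mismatch: {pred.shape[0]} predictions for "
            f"{true.shape[0]} truth labels"
        )
    _check_two_classes(true)
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    return EvaluationReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=tp / (tp + fp) if tp + fp else 0.0,
        accuracy=(tp + tn) / len(true),
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        auc=None if scores is None else compute_auc(scores, true),
    )


@dataclass
class PanelComparison:
    """Cross-validated performance of optimizer-chosen vs random panels."""

    best_panels: list[tuple[str, ...]]
    best_aucs: list[float]
    random_panels: list[tuple[str, ...]]
    random_aucs: list[float]
    best_curves: list[RocCurve] = field(default_factory=list)
    random_curves: list[RocCurve] = field(default_factory=list)

    def write_tsv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("kind\tpanel\tcv_auc\n")
            for kind, panels, aucs in (
                ("best", self.best_panels, self.best_aucs),
                ("random", self.random_panels, self.random_aucs),
            ):
                for p, a in zip(panels, aucs):
                    fh.write(f"{kind}\t{'; '.join(p)}\t{a:.4f}\n")

    def plot(self, path) -> None:
        """Write a PNG overlaying best (solid) and random (dotted) ROCs."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for curve, auc in zip(self.best_curves, self.best_aucs):
            ax.plot(curve.fpr, curve.tpr, "-", label=f"best (AUC={auc:.2f})")
        for curve, auc in zip(self.random_curves, self.random_aucs):
            ax.plot(curve.fpr, curve.tpr, ":", label=f"random (AUC={auc:.2f})")
        ax.plot([0, 1], [0, 1], color="grey", lw=0.5)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def compare_to_random_panels(
    matrix_a,
    markers,
    best_panels,
    n_random,
    spec,
    folds,
    seed,
) -> PanelComparison:
    """Score randomly drawn panels identically to the optimizer's picks.

    Random panels are drawn uniformly (without replacement within a panel)
    from the marker list, seeded.  Every panel — best and random — is scored
    with the same cross-validation fold assignment, and pooled held-out
    decision values provide a ROC curve per panel.
    """
    from .panels import cv_panel_auc, cv_pooled_scores

    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    best_panels = [tuple(sorted(p)) for p in best_panels]
    if not best_panels:
        raise ValueError("need at least one best panel")
    n = len(best_panels[0])
    if len(markers) < n:
        raise ValueError("marker list smaller than panel size")
    rng = np.random.default_rng(seed)
    markers = sorted(markers)
    random_panels = [
        tuple(sorted(rng.choice(markers, size=n, replace=False)))
        for _ in range(n_random)
    ]

    def score(panel):
        auc, _ = cv_panel_auc(matrix_a, panel, spec, folds)
        scores, ys = cv_pooled_scores(matrix_a, panel, spec, folds)
        return auc, roc_curve(scores, ys)

    best_scored = [score(p) for p in best_panels]
    random_scored = [score(p) for p in random_panels]
    return PanelComparison(
        best_panels=best_panels,
        best_aucs=[a for a, _ in best_scored],
        random_panels=random_panels,
        random_aucs=[a for a, _ in random_scored],
        best_curves=[c for _, c in best_scored],
        random_curves=[c for _, c in random_scored],
    )
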