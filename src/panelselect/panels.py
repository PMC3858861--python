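"""Exhaustive N-marker panel search scored by cross-validated SVM AUC.

Every combination of N markers drawn from the screened marker list is scored
the same way: for each cross-validation fold of the training group,
standardize features on the training folds, fit an RBF-kernel SVM, score the
held-out fold with continuous decision values, and compute the fold AUC.
The panel maximizing the aggregated (by default, mean) fold AUC is the
optimal panel; the testing group plays no part in the search.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np

from ._svm import RbfSvm
from .data import LabeledExpressionMatrix
from .metrics import compute_auc
from .splits import SplitSpec

__all__ = [
    "ClassifierSpec",
    "PanelCandidate",
    "enumerate_panels",
    "cv_panel_auc",
    "cv_pooled_scores",
    "find_optimal_panel",
    "TrainedPanelModel",
    "train_final_model",
    "predict",
]

logger = logging.getLogger(__name__)

DEFAULT_ENUMERATION_CAP = 10**8

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters of the panel classifier.

    ``gamma`` is either a positive float or ``"scale"``, meaning
    1 / (n_features * variance of the standardized training block) — with
    feature standardization on, effectively 1/N.  Together with the fold
    assignment and the data, the spec fully determines training.
    """

    kernel: str = "rbf"
    c_penalty: float = 1.0
    gamma: float | str = "scale"
    scale_features: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel != "rbf":
            raise ValueError("only the RBF kernel is supported")
        if self.c_penalty <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, str):
            if self.gamma != "scale":
                raise ValueError("gamma must be positive or 'scale'")
        elif self.gamma <= 0:
            raise ValueError("gamma must be positive or 'scale'")


@dataclass
class PanelCandidate:
    """A scored N-marker combination."""

    probe_ids: tuple[str, ...]
    validation_auc: float
    per_fold_aucs: list[float]
    rank: int


def enumerate_panels(markers, n: int, cap: int = DEFAULT_ENUMERATION_CAP):
    """Yield all C(M, N) sorted N-tuples of markers in lexicographic order."""
    markers = sorted(markers)
    if len(set(markers)) != len(markers):
        raise ValueError("marker list contains duplicates")
    if not 1 <= n <= len(markers):
        raise ValueError(f"panel size {n} not in [1, {len(markers)}]")
    total = math.comb(len(markers), n)
    if total > cap:
        raise ValueError(
            f"C({len(markers)}, {n}) = {total} combinations exceeds the cap "
            f"of {cap}; raise the cap or tighten the marker screen"
        )
    return itertools.combinations(markers, n)


# -- fold machinery --------------------------------------------------------


@dataclass
class _FoldData:
    """Per-fold standardized feature matrices for one (matrix, markers, split).

    ``x_std[f]`` is the full samples x markers matrix standardized with the
    statistics of fold f's training rows; column variances of the training
    block are cached for the gamma='scale' rule.  Degenerate features (zero
    variance in the training rows) are centered but not divided.
    """

    markers: list[str]
    y: np.ndarray
    train_idx: list[np.ndarray]
    test_idx: list[np.ndarray]
    x_std: list[np.ndarray]
    train_col_var: list[np.ndarray]
    spec: ClassifierSpec


def _build_fold_data(
    m: LabeledExpressionMatrix,
    markers,
    spec: ClassifierSpec,
    split: SplitSpec,
) -> _FoldData:
    markers = list(markers)
    rows = m.probe_indices(markers)
    a_ids = split.group_a_sample_ids
    if set(m.sample_ids) != set(a_ids):
        missing = set(a_ids) - set(m.sample_ids)
        extra = set(m.sample_ids) - set(a_ids)
        raise ValueError(
            "matrix must hold exactly the training-group samples"
            + (f"; missing {sorted(missing)}" if missing else "")
            + (f"; unexpected {sorted(extra)}" if extra else "")
        )
    col = {s: j for j, s in enumerate(m.sample_ids)}
    order = np.array([col[s] for s in a_ids], dtype=np.intp)
    X = np.ascontiguousarray(m.values[np.ix_(rows, order)].T)  # samples x M
    y = m.labels[order].astype(np.float64)
    fold_of = np.array([split.fold_assignment[s] for s in a_ids])

    train_idx, test_idx, x_std, col_vars = [], [], [], []
    for f in range(split.k):
        te = np.where(fold_of == f)[0]
        tr = np.where(fold_of != f)[0]
        if set(np.unique(y[te])) != {0.0, 1.0} or set(np.unique(y[tr])) != {
            0.0,
            1.0,
        }:
            raise ValueError(
                f"fold {f} does not contain both classes on each side; "
                "use a stratified split"
            )
        if spec.scale_features:
            mean = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            degenerate = sd == 0.0
            if np.any(degenerate):
                logger.info(
                    "fold %d: %d degenerate feature(s) passed through unscaled",
                    f,
                    int(degenerate.sum()),
                )
            scale = np.where(degenerate, 1.0, sd)
            xs = (X - mean) / scale
        else:
            xs = X.copy()
        train_idx.append(tr)
        test_idx.append(te)
        x_std.append(np.ascontiguousarray(xs))
        col_vars.append(xs[tr].var(axis=0))
    return _FoldData(
        markers=markers,
        y=y,
        train_idx=train_idx,
        test_idx=test_idx,
        x_std=x_std,
        train_col_var=col_vars,
        spec=spec,
    )


def _fast_auc(scores: np.ndarray, case: np.ndarray) -> float:
    """Mann-Whitney AUC via average ranks (ties counted half).

    Same statistic as :func:`panelselect.metrics.compute_auc`, specialized
    for the hot search loop; their equality is asserted by the test suite.
    """
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    _, inv, counts = np.unique(s, return_inverse=True, return_counts=True)
    csum = np.cumsum(counts)
    avg_rank = csum - (counts - 1) / 2.0
    ranks = np.empty(len(s))
    ranks[order] = avg_rank[inv]
    n1 = int(case.sum())
    n0 = len(case) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("need both classes present to compute an AUC")
    return float((ranks[case].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _gamma_for(spec: ClassifierSpec, col_var: np.ndarray, cols) -> float:
    if isinstance(spec.gamma, str):  # 'scale'
        v = float(np.mean(col_var[cols]))
        return 1.0 / (len(cols) * v) if v > 0 else 1.0
    return float(spec.gamma)


def _score_panel_cols(fd: _FoldData, cols: np.ndarray):
    """Per-fold AUCs plus pooled held-out (scores, labels) for one panel."""
    fold_aucs = []
    pooled_scores = []
    pooled_y = []
    for f in range(len(fd.train_idx)):
        tr, te = fd.train_idx[f], fd.test_idx[f]
        Xf = fd.x_std[f][:, cols]
        gamma = _gamma_for(fd.spec, fd.train_col_var[f], cols)
        svm = RbfSvm(c_penalty=fd.spec.c_penalty, gamma=gamma)
        svm.fit(Xf[tr], fd.y[tr])
        scores = svm.decision_function(Xf[te])
        fold_aucs.append(_fast_auc(scores, fd.y[te] == 1.0))
        pooled_scores.append(scores)
        pooled_y.append(fd.y[te])
    return fold_aucs, np.concatenate(pooled_scores), np.concatenate(pooled_y)


def _aggregate(fold_aucs, pooled_scores, pooled_y, how: str) -> float:
    if how == "mean":
        return float(np.mean(fold_aucs))
    if how == "pooled":
        return compute_auc(pooled_scores, pooled_y.astype(int))
    raise ValueError(f"unknown aggregation {how!r}")


def cv_panel_auc(
    m: LabeledExpressionMatrix,
    panel,
    spec: ClassifierSpec,
    split: SplitSpec,
    aggregation: str = "mean",
) -> tuple[float, list[float]]:
    """Cross-validated AUC of one panel on the training group.

    Returns (validation_auc, per-fold AUCs).  No held-out sample influences
    its own fold's fit: scaling statistics and the SVM are learned on the
    training folds only.
    """
    panel = tuple(sorted(panel))
    fd = _build_fold_data(m, panel, spec, split)
    cols = np.arange(len(panel))
    fold_aucs, ps, py = _score_panel_cols(fd, cols)
    return _aggregate(fold_aucs, ps, py, aggregation), fold_aucs


def cv_pooled_scores(
    m: LabeledExpressionMatrix,
    panel,
    spec: ClassifierSpec,
    split: SplitSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled held-out decision values (and labels) across all folds.

    Every training-group sample is scored exactly once, by the model of the
    fold that held it out — leakage-free in-training-group predictions.
    """
    panel = tuple(sorted(panel))
    fd = _build_fold_data(m, panel, spec, split)
    cols = np.arange(len(panel))
    _, ps, py = _score_panel_cols(fd, cols)
    return ps, py.astype(int)


def _candidate_sort_key(item):
    panel, auc, fold_aucs = item
    return (-auc, -min(fold_aucs), panel)


def find_optimal_panel(
    m: LabeledExpressionMatrix,
    markers,
    n: int,
    spec: ClassifierSpec,
    split: SplitSpec,
    top_k: int = 4,
    aggregation: str = "mean",
    cap: int = DEFAULT_ENUMERATION_CAP,
    n_workers: int = 1,
    checkpoint_path=None,
    log_every: int = 50_000,
) -> list[PanelCandidate]:
    """Score every N-marker combination and return the top panels.

    All combinations share one fold assignment and one spec, so AUC
    differences reflect panels rather than fold luck.  Ties on the
    aggregated AUC are broken by the higher minimum per-fold AUC, then by
    the lexicographically smallest panel; candidates tied with the last
    returned rank are included.  Results are independent of ``n_workers``
    and of checkpoint resumption.
    """
    markers = sorted(markers)
    panels = list(enumerate_panels(markers, n, cap=cap))
    fd = _build_fold_data(m, markers, spec, split)
    col = {p: i for i, p in enumerate(markers)}

    done: dict[tuple[str, ...], tuple[float, list[float]]] = {}
    if checkpoint_path and os.path.exists(checkpoint_path):
        done = _read_checkpoint(checkpoint_path)
        logger.info("resuming: %d panels already scored", len(done))

    todo = [p for p in panels if p not in done]
    results: dict[tuple[str, ...], tuple[float, list[float]]] = dict(done)

    def score(panel):
        cols = np.fromiter((col[p] for p in panel), dtype=np.intp)
        fold_aucs, ps, py = _score_panel_cols(fd, cols)
        return panel, _aggregate(fold_aucs, ps, py, aggregation), fold_aucs

    ckpt = open(checkpoint_path, "at", encoding="utf-8") if checkpoint_path else None
    try:
        if n_workers > 1:
            from joblib import Parallel, delayed

            chunk = max(1, len(todo) // (8 * n_workers) or 1)
            chunks = [todo[i : i + chunk] for i in range(0, len(todo), chunk)]
            for batch in Parallel(n_jobs=n_workers)(
                delayed(_score_chunk)(fd, col, c, aggregation) for c in chunks
            ):
                for panel, auc, fold_aucs in batch:
                    results[panel] = (auc, fold_aucs)
                    if ckpt:
                        _write_checkpoint_line(ckpt, panel, auc, fold_aucs)
        else:
            for i, panel in enumerate(todo):
                panel, auc, fold_aucs = score(panel)
                results[panel] = (auc, fold_aucs)
                if ckpt:
                    _write_checkpoint_line(ckpt, panel, auc, fold_aucs)
                if (i + 1) % log_every == 0:
                    logger.info("scored %d/%d combinations", i + 1, len(todo))
    finally:
        if ckpt:
            ckpt.close()

    scored = [(p, *results[p]) for p in panels]
    scored.sort(key=_candidate_sort_key)
    keep = min(top_k, len(scored))
    # include candidates tied with the last returned rank
    while keep < len(scored) and _tie_key(scored[keep]) == _tie_key(
        scored[keep - 1]
    ):
        keep += 1
    return [
        PanelCandidate(
            probe_ids=p, validation_auc=auc, per_fold_aucs=folds, rank=i + 1
        )
        for i, (p, auc, folds) in enumerate(scored[:keep])
    ]


def _tie_key(item):
    _, auc, fold_aucs = item
    return (auc, min(fold_aucs))


def _score_chunk(fd, col, panels, aggregation):
    out = []
    for panel in panels:
        cols = np.fromiter((col[p] for p in panel), dtype=np.intp)
        fold_aucs, ps, py = _score_panel_cols(fd, cols)
        out.append((panel, _aggregate(fold_aucs, ps, py, aggregation), fold_aucs))
    return out


def _write_checkpoint_line(fh, panel, auc, fold_aucs) -> None:
    fh.write(
        ";".join(panel)
        + "\t"
        + format(auc, ".17g")
        + "\t"
        + ",".join(format(a, ".17g") for a in fold_aucs)
        + "\n"
    )


def _read_checkpoint(path) -> dict:
    out = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            panel_s, auc_s, folds_s = line.split("\t")
            out[tuple(panel_s.split(";"))] = (
                float(auc_s),
                [float(x) for x in folds_s.split(",")],
            )
    return out


def write_panel_table(candidates: list[PanelCandidate], path) -> None:
    """Ranked candidates as TSV: rank, semicolon-joined panel, AUCs."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("rank\tpanel\tvalidation_auc\tper_fold_aucs\n")
        for c in candidates:
            fh.write(
                f"{c.rank}\t{'; '.join(c.probe_ids)}\t{c.validation_auc:.6f}\t"
                + ",".join(f"{a:.6f}" for a in c.per_fold_aucs)
                + "\n"
            )


# -- final model -----------------------------------------------------------


@dataclass
class TrainedPanelModel:
    """An RBF-SVM refit on the full training group for a fixed panel.

    Stores the panel, the scaling learned on the training group, and the raw
    training block, so the model serializes to text and reloads to a
    bit-identical decision function (refit from the stored block is
    deterministic).
    """

    panel: tuple[str, ...]
    spec: ClassifierSpec
    x_train_raw: np.ndarray
    y_train: np.ndarray
    mean: np.ndarray = field(init=False)
    scale: np.ndarray = field(init=False)
    gamma_value: float = field(init=False)
    _svm: RbfSvm = field(init=False, repr=False)

    def __post_init__(self) -> None:
        # fixed (C-contiguous) layout so refit-from-disk sums identically
        self.x_train_raw = np.ascontiguousarray(self.x_train_raw, dtype=np.float64)
        X = self.x_train_raw
        if self.spec.scale_features:
            self.mean = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale = np.where(sd == 0.0, 1.0, sd)
        else:
            self.mean = np.zeros(X.shape[1])
            self.scale = np.ones(X.shape[1])
        xs = (X - self.mean) / self.scale
        v = float(xs.var(axis=0).mean())
        if isinstance(self.spec.gamma, str):
            self.gamma_value = 1.0 / (xs.shape[1] * v) if v > 0 else 1.0
        else:
            self.gamma_value = float(self.spec.gamma)
        self._svm = RbfSvm(
            c_penalty=self.spec.c_penalty, gamma=self.gamma_value
        ).fit(xs, self.y_train.astype(np.float64))

    def decision_function(self, x_raw: np.ndarray) -> np.ndarray:
        xs = (np.asarray(x_raw, dtype=np.float64) - self.mean) / self.scale
        return self._svm.decision_function(xs)

    def save(self, path) -> None:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "panel": list(self.panel),
            "spec": {
                "kernel": self.spec.kernel,
                "c_penalty": self.spec.c_penalty,
                "gamma": self.spec.gamma,
                "scale_features": self.spec.scale_features,
                "seed": self.spec.seed,
            },
            "x_train_raw": [
                [format(v, ".17g") for v in row] for row in self.x_train_raw
            ],
            "y_train": [int(v) for v in self.y_train],
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(doc, fh)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "TrainedPanelModel":
        with open(path, "rt", encoding="utf-8") as fh:
            doc = json.load(fh)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format {doc.get('format_version')!r}"
            )
        spec = ClassifierSpec(**doc["spec"])
        return cls(
            panel=tuple(doc["panel"]),
            spec=spec,
            x_train_raw=np.array(
                [[float(v) for v in row] for row in doc["x_train_raw"]]
            ),
            y_train=np.array(doc["y_train"]),
        )


def train_final_model(
    m: LabeledExpressionMatrix, panel, spec: ClassifierSpec
) -> TrainedPanelModel:
    """Refit the classifier for one panel on the whole training group."""
    panel = tuple(sorted(panel))
    rows = m.probe_indices(panel)  # raises naming unknown probes
    X = m.values[rows, :].T
    if set(np.unique(m.labels)) != {0, 1}:
        raise ValueError("training group must contain both classes")
    return TrainedPanelModel(
        panel=panel, spec=spec, x_train_raw=X, y_train=np.asarray(m.labels)
    )


def predict(
    model: TrainedPanelModel, m: LabeledExpressionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Decision scores (higher = more case-like) and hard labels (score > 0)."""
    rows = m.probe_indices(model.panel)
    scores = model.decision_function(m.values[rows, :].T)
    return scores, (scores > 0).astype(int)
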