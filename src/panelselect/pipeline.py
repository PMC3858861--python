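"""End-to-end panel-discovery pipeline under a strict three-way data split.

Order of stages: (optional) log2 transform -> per-sample median
normalization -> random split into training group A and testing group B ->
per-probe centering with medians learned on A -> per-probe ANOVA + q-value
marker screen on A -> exhaustive cross-validated SVM panel search on A ->
refit of the best panel on all of A -> one-shot evaluation on B.

Group B never enters marker selection or the search: those stages receive a
view holding only group-A columns, so held-out information cannot leak by
construction.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os
import time
from dataclasses import dataclass

import yaml

from . import diffexp, metrics, panels
from .data import (
    LabeledExpressionMatrix,
    center_per_probe,
    log2_transform,
    normalize_per_sample,
    probe_medians,
)
from .splits import SplitSpec, split_groups, write_split_table

__all__ = ["RunConfig", "PipelineResult", "run_discovery", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Defaults follow the method's stated protocol: five-marker panels,
    5-fold cross validation, a strict q < 0.01 marker screen, a roughly
    half/half stratified training/testing split, and the top 4 panels
    reported.
    """

    seed: int = 0
    fraction_a: float = 0.5
    stratified: bool = True
    k_folds: int = 5
    q_threshold: float = 0.01
    max_markers: int = 100
    panel_size: int = 5
    top_k: int = 4
    c_penalty: float = 1.0
    gamma: float | str = "scale"
    scale_features: bool = True
    aggregation: str = "mean"
    input_is_log2: bool = True
    per_sample_normalization: bool = True
    per_probe_centering: bool = True
    nonpositive_policy: str = "error"
    n_random_panels: int = 4
    enumeration_cap: int = panels.DEFAULT_ENUMERATION_CAP
    workers: int = 1

    def classifier_spec(self) -> panels.ClassifierSpec:
        return panels.ClassifierSpec(
            c_penalty=self.c_penalty,
            gamma=self.gamma,
            scale_features=self.scale_features,
            seed=self.seed,
        )

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)


@dataclass
class PipelineResult:
    split: SplitSpec
    de_table: "object"
    markers: list[str]
    candidates: list[panels.PanelCandidate]
    model: panels.TrainedPanelModel | None = None
    report_train: metrics.EvaluationReport | None = None
    report_test: metrics.EvaluationReport | None = None
    comparison: metrics.PanelComparison | None = None


def _normalized(m: LabeledExpressionMatrix, config: RunConfig):
    if m.scale == "raw":
        if config.input_is_log2:
            raise ValueError("config says log2 input but matrix is raw scale")
        m = log2_transform(m, nonpositive=config.nonpositive_policy)
    if config.per_sample_normalization:
        m = normalize_per_sample(m)
    return m


def run_discovery(
    m: LabeledExpressionMatrix,
    config: RunConfig,
    checkpoint_path=None,
) -> PipelineResult:
    """Normalization, split, marker screen, and panel search (no group-B use).

    Returns a result whose evaluation fields are unset; ``run_pipeline``
    adds the refit and the group-B evaluation.  Useful on its own when the
    testing group must remain untouched (or is deliberately poisoned in a
    leakage audit).
    """
    t0 = time.monotonic()
    m = _normalized(m, config)
    split = split_groups(
        m,
        seed=config.seed,
        fraction_a=config.fraction_a,
        stratified=config.stratified,
        k=config.k_folds,
    )
    group_a = m.subset_samples(split.group_a_sample_ids)
    if config.per_probe_centering:
        group_a = center_per_probe(group_a)
    logger.info(
        "split: %d training / %d testing samples; %d probes in",
        len(split.group_a_sample_ids),
        len(split.group_b_sample_ids),
        m.n_probes,
    )

    de_table = diffexp.differential_expression(group_a)
    markers = diffexp.select_markers(
        de_table, q_threshold=config.q_threshold, max_markers=config.max_markers
    )
    logger.info("marker screen: %d probes at q < %g", len(markers), config.q_threshold)
    if len(markers) < config.panel_size:
        raise ValueError(
            f"only {len(markers)} markers passed the q < {config.q_threshold} "
            f"screen; need at least {config.panel_size} to form a panel "
            "(relax q_threshold or raise max_markers)"
        )
    spec = config.classifier_spec()
    candidates = panels.find_optimal_panel(
        group_a,
        markers,
        config.panel_size,
        spec,
        split,
        top_k=config.top_k,
        aggregation=config.aggregation,
        cap=config.enumeration_cap,
        n_workers=config.workers,
        checkpoint_path=checkpoint_path,
    )
    n_scored = math.comb(len(markers), config.panel_size)
    dt = time.monotonic() - t0
    logger.info(
        "search: %d combinations scored in %.1f s (%.0f/s); best AUC %.4f",
        n_scored,
        dt,
        n_scored / dt if dt > 0 else float("nan"),
        candidates[0].validation_auc,
    )
    return PipelineResult(
        split=split, de_table=de_table, markers=markers, candidates=candidates
    )


def run_pipeline(
    m: LabeledExpressionMatrix,
    config: RunConfig,
    outdir=None,
    checkpoint_path=None,
) -> PipelineResult:
    """Full protocol: discovery on group A, then one-shot group-B evaluation."""
    normalized = _normalized(m, config)
    result = run_discovery(m, config, checkpoint_path=checkpoint_path)
    split = result.split
    spec = config.classifier_spec()

    group_a = normalized.subset_samples(split.group_a_sample_ids)
    group_b = normalized.subset_samples(split.group_b_sample_ids)
    if config.per_probe_centering:
        ref = probe_medians(group_a)
        group_a = center_per_probe(group_a, ref)
        group_b = center_per_probe(group_b, ref)  # centered with A's medians

    best = result.candidates[0]
    result.model = panels.train_final_model(group_a, best.probe_ids, spec)

    # training-group report from pooled held-out CV predictions (leakage-free)
    cv_scores, cv_y = panels.cv_pooled_scores(group_a, best.probe_ids, spec, split)
    result.report_train = metrics.evaluate_predictions(
        (cv_scores > 0).astype(int), cv_y, scores=cv_scores
    )
    scores_b, labels_b = panels.predict(result.model, group_b)
    result.report_test = metrics.evaluate_predictions(
        labels_b, group_b.labels, scores=scores_b
    )
    logger.info(
        "evaluation: training-group CV AUC %.4f, testing-group AUC %.4f",
        result.report_train.auc,
        result.report_test.auc,
    )

    if config.n_random_panels >= 1 and len(result.markers) > config.panel_size:
        result.comparison = metrics.compare_to_random_panels(
            group_a,
            result.markers,
            [c.probe_ids for c in result.candidates[: config.top_k]],
            config.n_random_panels,
            spec,
            split,
            seed=config.seed + 1,
        )

    if outdir is not None:
        _write_artifacts(outdir, config, result)
    return result


def _write_artifacts(outdir, config: RunConfig, result: PipelineResult) -> None:
    os.makedirs(outdir, exist_ok=True)
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    write_split_table(result.split, os.path.join(outdir, "split.tsv"))
    diffexp.write_de_table(
        result.de_table,
        os.path.join(outdir, "de_table.tsv"),
        q_threshold=config.q_threshold,
    )
    with open(os.path.join(outdir, "markers.txt"), "wt", encoding="utf-8") as fh:
        fh.write("\n".join(result.markers) + "\n")
    panels.write_panel_table(
        result.candidates, os.path.join(outdir, "panels.tsv")
    )
    if result.model is not None:
        result.model.save(os.path.join(outdir, "model.json"))
    for name, report in (
        ("evaluation_train", result.report_train),
        ("evaluation_test", result.report_test),
    ):
        if report is not None:
            report.write_json(os.path.join(outdir, name + ".json"))
            with open(
                os.path.join(outdir, name + ".tsv"), "wt", encoding="utf-8"
            ) as fh:
                fh.write(report.to_text())
    if result.comparison is not None:
        result.comparison.write_tsv(os.path.join(outdir, "comparison.tsv"))
        result.comparison.plot(os.path.join(outdir, "comparison.png"))
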