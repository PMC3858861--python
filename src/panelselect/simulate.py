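"""Synthetic labeled expression matrices with planted discriminative panels.

The generator emulates the structure of a two-class peripheral-blood
microarray study: two near-balanced classes (67 cases / 63 controls by
default), thousands of null probes with Gaussian noise on the log2 scale,
and a small planted panel whose probes are shifted upward in cases by a
configurable effect size (in residual-SD units) and correlated through a
shared per-sample latent factor, the way co-regulated markers would be.
The default probe count (2,000) is the study-scale array shrunk ~16x so an
exhaustive panel search runs in minutes on one CPU.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np

from .data import LabeledExpressionMatrix, write_expression_matrix, write_labels

__all__ = ["SimulationConfig", "generate_dataset", "make_fixture_suite"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    effect_size is the case-minus-control mean shift of planted probes in
    units of residual SD; within_panel_correlation is the pairwise
    correlation among planted probes induced by a shared latent factor.
    """

    n_probes: int = 2000
    n_cases: int = 67
    n_controls: int = 63
    planted_probe_count: int = 5
    effect_size: float = 2.0
    residual_sd: float = 1.0
    within_panel_correlation: float = 0.2
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_probe_count > self.n_probes:
            raise ValueError("more planted probes than probes")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need >=2 samples per class")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if not 0 <= self.within_panel_correlation < 1:
            raise ValueError("within_panel_correlation must be in [0, 1)")
        if self.planted_probe_count < 0 or self.n_probes < 1:
            raise ValueError("invalid probe counts")


def generate_dataset(
    config: SimulationConfig,
) -> tuple[LabeledExpressionMatrix, list[str]]:
    """Draw one dataset; returns (matrix, planted probe ids).

    Null probes are N(baseline, sd^2) independent of the label.  Planted
    probes share a per-sample latent factor (weight sqrt(rho)) plus
    idiosyncratic noise (weight sqrt(1-rho)), keeping the marginal SD at
    ``residual_sd``, and cases additionally get +effect_size * sd.
    Bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    width = len(str(config.n_probes))
    probe_ids = [f"PR{i + 1:0{width}d}" for i in range(config.n_probes)]
    sample_ids = [f"S{j + 1:04d}" for j in range(n)]
    labels = np.concatenate(
        [np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)]
    )

    sd = config.residual_sd
    values = config.baseline_mean + sd * rng.standard_normal(
        (config.n_probes, n)
    )
    planted_idx = np.sort(
        rng.choice(config.n_probes, size=config.planted_probe_count, replace=False)
    )
    if config.planted_probe_count:
        rho = config.within_panel_correlation
        latent = rng.standard_normal(n)
        noise = rng.standard_normal((config.planted_probe_count, n))
        values[planted_idx, :] = (
            config.baseline_mean
            + sd * (np.sqrt(rho) * latent + np.sqrt(1 - rho) * noise)
            + config.effect_size * sd * labels
        )
    m = LabeledExpressionMatrix(
        probe_ids, sample_ids, values, labels, scale="log2"
    )
    return m, [probe_ids[i] for i in planted_idx]


def make_fixture_suite(output_dir, seed: int = 20130) -> dict[str, dict[str, str]]:
    """Write the standard trio of test fixtures; returns their paths.

    (a) ``toy``: a 4-probe x 6-sample matrix for I/O tests;
    (b) ``null``: 2,000 probes, 130 samples, no planted signal;
    (c) ``planted``: 2,000 probes, 130 samples, a 5-probe panel at effect 2.

    Each fixture gets a matrix TSV, a sidecar label TSV, and a two-column
    ground-truth manifest (probe_id, is_planted).  Regenerates byte-
    identically from the same seed.
    """
    os.makedirs(output_dir, exist_ok=True)
    out: dict[str, dict[str, str]] = {}

    toy = LabeledExpressionMatrix(
        ["P1", "P2", "P3", "P4"],
        [f"S{i}" for i in range(1, 7)],
        np.arange(24, dtype=float).reshape(4, 6) / 3.0 + 5.0,
        np.array([1, 1, 1, 0, 0, 0]),
        scale="log2",
    )
    out["toy"] = _write_fixture(output_dir, "toy", toy, [])

    null_cfg = SimulationConfig(
        planted_probe_count=0, effect_size=0.0, seed=seed
    )
    null_m, _ = generate_dataset(null_cfg)
    out["null"] = _write_fixture(output_dir, "null", null_m, [])

    planted_cfg = SimulationConfig(seed=seed + 1)
    planted_m, truth = generate_dataset(planted_cfg)
    out["planted"] = _write_fixture(output_dir, "planted", planted_m, truth)
    return out


def _write_fixture(output_dir, name, m, truth) -> dict[str, str]:
    base = os.path.join(output_dir, name)
    paths = {
        "matrix": base + "_matrix.tsv",
        "labels": base + "_labels.tsv",
        "truth": base + "_truth.tsv",
    }
    write_expression_matrix(m, paths["matrix"], labels="inline")
    write_labels(dict(zip(m.sample_ids, (int(l) for l in m.labels))), paths["labels"])
    planted = set(truth)
    with open(paths["truth"], "wt", encoding="utf-8") as fh:
        for p in m.probe_ids:
            fh.write(f"{p}\t{int(p in planted)}\n")
    return paths
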