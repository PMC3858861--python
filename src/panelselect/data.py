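"""Labeled expression matrices: container, TSV I/O, and normalization.

The container holds a probes x samples matrix of expression values on either
the raw or the log2 scale, together with a binary case/control label per
sample.  Normalization follows the standard two-step median scheme for
single-channel arrays: log2 transform, subtract the per-sample median (the
50th percentile of all values on that sample), then subtract the per-probe
median across samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LabeledExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "log2_transform",
    "normalize_per_sample",
    "center_per_probe",
    "probe_medians",
]

#: token identifying the inline label row in matrix files
LABEL_ROW = "#label"

#: default floor used when nonpositive values are clipped before log2
DEFAULT_EPSILON = 2.0**-20


@dataclass
class LabeledExpressionMatrix:
    """A probes x samples expression matrix with binary sample labels.

    Parameters
    ----------
    probe_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray, shape (n_probes, n_samples)
        Expression values; scale given by ``scale``.
    labels : ndarray of {0, 1}, shape (n_samples,)
        Case (1) / control (0) status per sample.
    scale : {"raw", "log2"}
        Whether values are raw intensities or log2-transformed.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    scale: str = "log2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        self.validate()

    def validate(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_probes, n_samples = self.values.shape
        if n_probes != len(self.probe_ids):
            raise ValueError(
                f"{len(self.probe_ids)} probe ids for {n_probes} rows"
            )
        if n_samples != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} columns"
            )
        if len(self.labels) != n_samples:
            raise ValueError(
                f"{len(self.labels)} labels for {n_samples} samples"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1, found {sorted(bad)}")

    def require_finite(self) -> None:
        """Assert no missing/non-finite values (enforced at ingestion;
        in-memory matrices may carry sentinels, e.g. in leakage audits)."""
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    # -- convenience ------------------------------------------------------

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "LabeledExpressionMatrix":
        return LabeledExpressionMatrix(
            list(self.probe_ids),
            list(self.sample_ids),
            self.values.copy(),
            self.labels.copy(),
            self.scale,
        )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def probe_indices(self, probe_ids) -> np.ndarray:
        index = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing}")
        return np.array([index[p] for p in probe_ids], dtype=np.intp)

    def subset_samples(self, sample_ids) -> "LabeledExpressionMatrix":
        """Restrict to the given samples, in the given order."""
        idx = [self.sample_index(s) for s in sample_ids]
        return LabeledExpressionMatrix(
            list(self.probe_ids),
            list(sample_ids),
            self.values[:, idx].copy(),
            self.labels[idx].copy(),
            self.scale,
        )

    def subset_probes(self, probe_ids) -> "LabeledExpressionMatrix":
        idx = self.probe_indices(probe_ids)
        return LabeledExpressionMatrix(
            list(probe_ids),
            list(self.sample_ids),
            self.values[idx, :].copy(),
            self.labels.copy(),
            self.scale,
        )


# -- I/O -------------------------------------------------------------------


def _parse_float(text: str, probe: str, sample: str):
    try:
        return float(text)
    except ValueError:
        return None


def read_expression_matrix(
    path,
    labels: str | None = "inline",
    scale: str = "log2",
    missing: str = "error",
) -> LabeledExpressionMatrix:
    """Read a tab-separated probes x samples matrix.

    The first non-metadata row holds sample ids (first field is an arbitrary
    corner label); each subsequent row is a probe.  A row whose first field
    is ``#label`` carries the 0/1 labels.  Lines starting with ``!`` (the GEO
    series-matrix metadata dialect) are skipped.

    Parameters
    ----------
    labels : "inline" or path
        Where labels come from: the ``#label`` row, or a two-column sidecar
        TSV of (sample_id, label).
    scale : {"raw", "log2"}
        Scale flag recorded on the returned matrix.
    missing : {"error", "drop"}
        Policy for empty/NA cells: hard error (default) or drop the probe row.
    """
    if missing not in ("error", "drop"):
        raise ValueError(f"unknown missing-value policy {missing!r}")
    with open(path, "rt", encoding="utf-8") as fh:
        rows = [
            line.rstrip("\n").split("\t")
            for line in fh
            if line.strip() and not line.startswith("!")
        ]
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    sample_ids = rows[0][1:]
    if not sample_ids:
        raise ValueError(f"{path}: header row has no sample ids")

    label_map: dict[str, int] = {}
    probe_ids: list[str] = []
    data: list[list[float]] = []
    n_dropped = 0
    na_tokens = {"", "na", "nan", "null", "none"}
    for row in rows[1:]:
        name, cells = row[0], row[1:]
        if name == LABEL_ROW:
            for s, c in zip(sample_ids, cells):
                label_map[s] = int(float(c))
            continue
        if len(cells) != len(sample_ids):
            raise ValueError(
                f"{path}: probe {name!r} has {len(cells)} values for "
                f"{len(sample_ids)} samples"
            )
        parsed: list[float] = []
        has_missing = False
        for j, c in enumerate(cells):
            if c.strip().lower() in na_tokens:
                if missing == "error":
                    raise ValueError(
                        f"{path}: missing value at probe {name!r}, "
                        f"sample {sample_ids[j]!r}"
                    )
                has_missing = True
                break
            v = _parse_float(c, name, sample_ids[j])
            if v is None:
                raise ValueError(
                    f"{path}: non-numeric value {c!r} at probe {name!r}, "
                    f"sample {sample_ids[j]!r}"
                )
            parsed.append(v)
        if has_missing:
            n_dropped += 1
            continue
        probe_ids.append(name)
        data.append(parsed)

    if labels == "inline":
        if not label_map:
            raise ValueError(f"{path}: no {LABEL_ROW} row and no sidecar labels")
    elif labels is not None:
        label_map = read_labels(labels)
    else:
        raise ValueError("labels must be 'inline' or a sidecar path")

    unlabeled = [s for s in sample_ids if s not in label_map]
    if unlabeled:
        raise ValueError(f"no label for sample(s): {unlabeled}")
    label_vec = np.array([label_map[s] for s in sample_ids])
    if not probe_ids:
        raise ValueError(f"{path}: matrix has no probe rows")
    m = LabeledExpressionMatrix(
        probe_ids, sample_ids, np.array(data), label_vec, scale=scale
    )
    m.require_finite()
    return m


def read_labels(path) -> dict[str, int]:
    """Read a two-column (sample_id, 0/1) sidecar TSV."""
    out: dict[str, int] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, lab = line.split("\t")[:2]
            out[sid] = int(float(lab))
    return out


def write_expression_matrix(
    m: LabeledExpressionMatrix, path, labels: str | None = "inline"
) -> None:
    """Write the matrix in the same TSV dialect ``read_expression_matrix`` reads.

    Values are written with 17 significant digits so a round trip reproduces
    them exactly.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(m.sample_ids) + "\n")
        if labels == "inline":
            fh.write(
                LABEL_ROW + "\t" + "\t".join(str(int(l)) for l in m.labels) + "\n"
            )
        for i, probe in enumerate(m.probe_ids):
            fh.write(
                probe
                + "\t"
                + "\t".join(format(v, ".17g") for v in m.values[i])
                + "\n"
            )
    if labels not in (None, "inline"):
        write_labels(dict(zip(m.sample_ids, (int(l) for l in m.labels))), labels)


def write_labels(label_map: dict[str, int], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for sid, lab in label_map.items():
            fh.write(f"{sid}\t{lab}\n")


# -- normalization ---------------------------------------------------------


def log2_transform(
    m: LabeledExpressionMatrix,
    nonpositive: str = "error",
    epsilon: float = DEFAULT_EPSILON,
) -> LabeledExpressionMatrix:
    """log2-transform a raw-scale matrix.

    ``nonpositive`` controls what happens to values <= 0: ``"error"`` (hard
    error naming the offending cell) or ``"floor"`` (clip to ``epsilon``).
    """
    if m.scale != "raw":
        raise ValueError("matrix is already on the log2 scale")
    vals = m.values
    if nonpositive == "error":
        if np.any(vals <= 0):
            i, j = np.argwhere(vals <= 0)[0]
            raise ValueError(
                f"nonpositive value {vals[i, j]} at probe {m.probe_ids[i]!r}, "
                f"sample {m.sample_ids[j]!r}; use the floor policy to clip"
            )
        out = np.log2(vals)
    elif nonpositive == "floor":
        out = np.log2(np.maximum(vals, epsilon))
    else:
        raise ValueError(f"unknown nonpositive policy {nonpositive!r}")
    return LabeledExpressionMatrix(
        m.probe_ids, m.sample_ids, out, m.labels, scale="log2"
    )


def _require_log2(m: LabeledExpressionMatrix) -> None:
    if m.scale != "log2":
        raise ValueError("operation requires a log2-scale matrix")
    if m.values.size == 0:
        raise ValueError("empty matrix")


def normalize_per_sample(m: LabeledExpressionMatrix) -> LabeledExpressionMatrix:
    """Subtract each sample's median (its 50th percentile) from its column.

    Median uses midpoint interpolation for even counts.  Idempotent.
    """
    _require_log2(m)
    med = np.median(m.values, axis=0, keepdims=True)
    return LabeledExpressionMatrix(
        m.probe_ids, m.sample_ids, m.values - med, m.labels, scale="log2"
    )


def probe_medians(m: LabeledExpressionMatrix) -> np.ndarray:
    """Per-probe medians across samples (used as centering reference)."""
    _require_log2(m)
    return np.median(m.values, axis=1)


def center_per_probe(
    m: LabeledExpressionMatrix, medians: np.ndarray | None = None
) -> LabeledExpressionMatrix:
    """Subtract the per-probe median from each row.

    ``medians`` may supply reference medians learned on another sample set
    (e.g. the training group), so held-out data can be centered without
    touching its own values.  Idempotent when ``medians`` is None.
    """
    _require_log2(m)
    med = probe_medians(m) if medians is None else np.asarray(medians, float)
    if med.shape != (m.n_probes,):
        raise ValueError("medians length does not match probe count")
    return LabeledExpressionMatrix(
        m.probe_ids, m.sample_ids, m.values - med[:, None], m.labels, scale="log2"
    )
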