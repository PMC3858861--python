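"""Reproducible training/testing splits and cross-validation fold assignment.

Samples are divided once into a training group (A) and a testing group (B);
group A is further dealt into k cross-validation folds.  Both assignments are
a pure function of (sample ids, labels, seed, fraction, k), and serialize to
a plain-text table so a split can be audited and replayed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabeledExpressionMatrix

__all__ = ["SplitSpec", "split_groups", "write_split_table", "read_split_table"]


@dataclass
class SplitSpec:
    """Assignment of samples to groups A/B and of group-A samples to folds."""

    seed: int
    k: int
    group_a_sample_ids: list[str]
    group_b_sample_ids: list[str]
    fold_assignment: dict[str, int]

    def __post_init__(self) -> None:
        a, b = set(self.group_a_sample_ids), set(self.group_b_sample_ids)
        if a & b:
            raise ValueError(f"samples in both groups: {sorted(a & b)}")
        if set(self.fold_assignment) != a:
            raise ValueError("fold assignment must cover exactly group A")
        folds = set(self.fold_assignment.values())
        if folds and (min(folds) < 0 or max(folds) >= self.k):
            raise ValueError("fold index out of range")
        if len(folds) != self.k:
            raise ValueError("every fold must be non-empty")

    def fold_members(self, fold: int) -> list[str]:
        return [s for s in self.group_a_sample_ids if self.fold_assignment[s] == fold]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _deal_folds(
    groups: list[list[str]], k: int, rng: np.random.Generator
) -> dict[str, int]:
    """Deal each id group across k folds; per-group and total fold sizes
    each differ by at most one."""
    totals = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}
    for ids in groups:
        ids = [ids[i] for i in rng.permutation(len(ids))]
        base, extra = divmod(len(ids), k)
        counts = np.full(k, base)
        # extras go to the currently smallest folds (ties by fold index)
        order = np.lexsort((np.arange(k), totals))
        counts[order[:extra]] += 1
        pos = 0
        for f in range(k):
            for s in ids[pos : pos + counts[f]]:
                assignment[s] = f
            pos += counts[f]
        totals += counts
    return assignment


def split_groups(
    m: LabeledExpressionMatrix,
    seed: int,
    fraction_a: float = 0.5,
    stratified: bool = True,
    k: int = 5,
) -> SplitSpec:
    """Randomly divide samples into training group A and testing group B,
    and assign group-A samples to k cross-validation folds.

    With ``stratified`` (default), the split and the folds preserve class
    proportions: each class is allocated round(fraction_a * n_class) training
    samples, and folds hold near-equal counts of each class.  Deterministic
    given the seed.
    """
    if not 0 < fraction_a < 1:
        raise ValueError("fraction_a must be in (0, 1)")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    labels = np.asarray(m.labels)
    ids = np.asarray(m.sample_ids, dtype=object)

    if stratified:
        class_groups = [ids[labels == c].tolist() for c in (0, 1)]
    else:
        class_groups = [list(ids)]

    group_a: list[list[str]] = []
    group_b: list[str] = []
    for members in class_groups:
        members = [members[i] for i in rng.permutation(len(members))]
        n_a = _round_half_up(fraction_a * len(members))
        group_a.append(members[:n_a])
        group_b.extend(members[n_a:])

    if stratified:
        smallest = min(len(g) for g in group_a)
        if k > smallest:
            raise ValueError(
                f"k={k} exceeds the smallest group-A class count ({smallest})"
            )
    else:
        if k > len(group_a[0]):
            raise ValueError(f"k={k} exceeds group-A size ({len(group_a[0])})")

    assignment = _deal_folds(group_a, k, rng)
    a_ids = [s for s in m.sample_ids if s in assignment]
    b_set = set(group_b)
    b_ids = [s for s in m.sample_ids if s in b_set]
    return SplitSpec(
        seed=seed,
        k=k,
        group_a_sample_ids=a_ids,
        group_b_sample_ids=b_ids,
        fold_assignment=assignment,
    )


def write_split_table(spec: SplitSpec, path) -> None:
    """Serialize as (sample_id, assignment) rows; ``A:<fold>`` or ``B``."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# seed={spec.seed}\n# k={spec.k}\n")
        for s in spec.group_a_sample_ids:
            fh.write(f"{s}\tA:{spec.fold_assignment[s]}\n")
        for s in spec.group_b_sample_ids:
            fh.write(f"{s}\tB\n")


def read_split_table(path) -> SplitSpec:
    seed = k = None
    a_ids: list[str] = []
    b_ids: list[str] = []
    folds: dict[str, int] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key == "seed":
                    seed = int(val)
                elif key == "k":
                    k = int(val)
                continue
            sid, assignment = line.split("\t")
            if assignment == "B":
                b_ids.append(sid)
            elif assignment.startswith("A:"):
                a_ids.append(sid)
                folds[sid] = int(assignment[2:])
            else:
                raise ValueError(f"bad assignment {assignment!r} for {sid!r}")
    if seed is None or k is None:
        raise ValueError(f"{path}: missing seed/k header")
    return SplitSpec(seed, k, a_ids, b_ids, folds)
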