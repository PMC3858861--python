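"""Per-probe differential expression with false-discovery-rate control.

Each probe is tested for a two-group mean difference with a one-way
fixed-effect ANOVA (for two groups the F test is exactly the squared pooled
t test).  Multiplicity is handled by a three-step procedure: raw p-value,
Benjamini-Hochberg adjusted p-value, and the Storey-Tibshirani q-value built
on an estimate of the null proportion pi0.  Markers are screened with a
strict q < threshold filter.

The underlying per-probe model is y_ij = mu + T_i + S_j + e_ij with a fixed
group effect T_i and a random sample effect S_j; with a single observation
per sample and probe the sample effect is unidentifiable from the residual,
so its variance component is reported as zero and the test reduces to the
one-way fixed-effect ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaFit",
    "fit_probe_anova",
    "bh_adjust",
    "estimate_pi0",
    "qvalues",
    "differential_expression",
    "select_markers",
    "write_de_table",
]

DEFAULT_LAMBDA_GRID = np.arange(0.0, 0.91, 0.05)


@dataclass
class AnovaFit:
    """Point estimates for one probe's group-effect model.

    ``group_effects`` are the per-group deviations from the grand mean under
    the sum-to-zero constraint; ``sample_variance_component`` is the variance
    of the random sample effect, identically zero in the one-observation-per-
    sample design and kept for API stability.
    """

    mu_hat: float
    group_effects: dict[int, float]
    residual_variance: float
    sample_variance_component: float = 0.0


def _group_views(values: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels)
    v0 = values[..., labels == 0]
    v1 = values[..., labels == 1]
    if v0.shape[-1] < 2 or v1.shape[-1] < 2:
        raise ValueError(
            f"need >=2 samples per class, got {v1.shape[-1]} cases / "
            f"{v0.shape[-1]} controls"
        )
    return v0, v1


def fit_probe_anova(values, labels) -> tuple[AnovaFit, float, float]:
    """One-way fixed-effect ANOVA of a single probe's group effect.

    Returns the fit, the F statistic of the group effect, and the p-value
    from F(1, n-2).  A probe with identical values in both groups gets
    F = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    v0, v1 = _group_views(values, labels)
    n0, n1 = v0.size, v1.size
    n = n0 + n1
    m0, m1 = v0.mean(), v1.mean()
    grand = values.mean()
    ssb = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    ssw = np.sum((v0 - m0) ** 2) + np.sum((v1 - m1) ** 2)
    resid_var = ssw / (n - 2)
    if ssw == 0.0:
        f_stat, p = (0.0, 1.0) if ssb == 0.0 else (np.inf, 0.0)
    else:
        f_stat = float(ssb / resid_var)
        p = float(stats.f.sf(f_stat, 1, n - 2))
    mu = (m0 + m1) / 2.0  # unweighted grand mean: effects sum to zero
    fit = AnovaFit(
        mu_hat=float(mu),
        group_effects={0: float(m0 - mu), 1: float(m1 - mu)},
        residual_variance=float(resid_var),
    )
    return fit, float(f_stat), float(p)


def _anova_table(values: np.ndarray, labels: np.ndarray):
    """Vectorized F and p for all probes at once."""
    v0, v1 = _group_views(values, labels)
    n0, n1 = v0.shape[1], v1.shape[1]
    n = n0 + n1
    m0, m1 = v0.mean(axis=1), v1.mean(axis=1)
    grand = values.mean(axis=1)
    ssb = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    ssw = ((v0 - m0[:, None]) ** 2).sum(axis=1) + ((v1 - m1[:, None]) ** 2).sum(
        axis=1
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ssb / (ssw / (n - 2))
    p = stats.f.sf(f_stat, 1, n - 2)
    # degenerate probes: zero within-group variance
    flat = ssw == 0.0
    null_flat = flat & (ssb == 0.0)
    f_stat = np.where(null_flat, 0.0, f_stat)
    p = np.where(null_flat, 1.0, p)
    sep_flat = flat & (ssb > 0.0)
    f_stat = np.where(sep_flat, np.inf, f_stat)
    p = np.where(sep_flat, 0.0, p)
    return f_stat, p


def _check_unit_interval(p: np.ndarray, what: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError(f"empty {what} list")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"{what} values must lie in [0, 1]")
    return p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = _check_unit_interval(p_values, "p")
    return multipletests(p, method="fdr_bh")[1]


def estimate_pi0(p_values, lambda_grid=None) -> float:
    """Estimate the null proportion pi0 from the p-value histogram.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on a grid of
    lambda values and smoothed with a least-squares cubic, evaluated at the
    largest lambda.  Falls back to 1.0 (with a warning) when fewer than 100
    p-values are supplied or the smoothed estimate leaves (0, 1].
    """
    p = _check_unit_interval(p_values, "p")
    lam = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
    if np.any(lam < 0) or np.any(lam >= 1):
        raise ValueError("lambda grid must lie in [0, 1)")
    m = p.size
    if m < 100:
        warnings.warn(
            f"only {m} p-values; pi0 estimation unreliable, using pi0=1",
            stacklevel=2,
        )
        return 1.0
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    coeffs = np.polynomial.polynomial.polyfit(lam, pi0_lam, deg=3)
    est = float(np.polynomial.polynomial.polyval(lam.max(), coeffs))
    if est <= 0.0 or not np.isfinite(est):
        warnings.warn(
            f"smoothed pi0 estimate {est:.3f} outside (0, 1]; using pi0=1",
            stacklevel=2,
        )
        return 1.0
    return min(est, 1.0)


def qvalues(p_values, pi0: float | None = None) -> np.ndarray:
    """Storey-Tibshirani q-values, in input order.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j on the ascending-sorted list,
    capped at 1.  With pi0 = 1 this is exactly the Benjamini-Hochberg
    adjustment.
    """
    p = _check_unit_interval(p_values, "p")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def differential_expression(m, pi0: float | None = None) -> pd.DataFrame:
    """Per-probe ANOVA table with BH-adjusted p and q-values.

    Returns a DataFrame with columns ``probe_id, f_statistic, p_value,
    p_adjusted_bh, q_value`` in the input probe order.
    """
    f_stat, p = _anova_table(m.values, m.labels)
    table = pd.DataFrame(
        {
            "probe_id": m.probe_ids,
            "f_statistic": f_stat,
            "p_value": p,
            "p_adjusted_bh": bh_adjust(p),
            "q_value": qvalues(p, pi0=pi0),
        }
    )
    return table


def select_markers(
    table: pd.DataFrame, q_threshold: float = 0.01, max_markers: int | None = None
) -> list[str]:
    """Probes passing the strict q < threshold screen.

    Ordered by ascending q, then ascending p, then probe_id; optionally
    truncated to the ``max_markers`` best-ranked probes.
    """
    if table.empty:
        raise ValueError("empty differential-expression table")
    ranked = table.sort_values(
        ["q_value", "p_value", "probe_id"], kind="stable"
    )
    hits = ranked.loc[ranked["q_value"] < q_threshold, "probe_id"].tolist()
    if max_markers is not None:
        hits = hits[:max_markers]
    return hits


def write_de_table(
    table: pd.DataFrame, path, q_threshold: float = 0.01
) -> None:
    """Export as TSV in deterministic (q, p, probe_id) order, with a
    selected(0/1) column reflecting the strict q < threshold filter."""
    out = table.sort_values(["q_value", "p_value", "probe_id"], kind="stable")
    out = out.assign(selected=(out["q_value"] < q_threshold).astype(int))
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
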