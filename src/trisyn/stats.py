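"""Per-animal aggregation and two-group statistics.

Per-image metric values are aggregated to one value per animal by the
median across all images from that animal (acquired from at least two
tissue sections). Group comparison uses the equal-variance (pooled)
two-sample Student t-test with df = n1 + n2 - 2 and a two-sided p-value;
normality is screened per group with the Shapiro-Wilk test. No
multiple-testing adjustment is applied by default; Benjamini-Hochberg is
available as an option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "aggregate_animal",
    "shapiro_wilk",
    "two_sample_t",
    "p_from_t",
    "summarize_groups",
    "format_comparison",
]


@dataclass
class GroupComparison:
    """Result of one two-group comparison of a per-animal metric."""

    metric: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    shapiro_w_a: float | None
    shapiro_p_a: float | None
    shapiro_w_b: float | None
    shapiro_p_b: float | None
    t: float
    df: int
    p: float
    degenerate: bool = False


def aggregate_animal(per_image_values) -> float:
    """Animal-level value: median across that animal's images.

    With an even number of images the median is the mean of the central
    pair. A single image is accepted with a warning (fewer than two tissue
    sections)."""
    values = np.asarray(list(per_image_values), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one per-image value")
    if values.size < 2:
        warnings.warn("animal has fewer than 2 images (sections)", stacklevel=2)
    return float(np.median(values))


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (Royston's approximation).

    Valid for 3 <= n <= 50 here; a constant sample is rejected because the
    statistic is undefined."""
    values = np.asarray(list(values), dtype=float)
    n = values.size
    if n < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {n}")
    if n > 50:
        warnings.warn(f"Shapiro-Wilk with n={n} > 50", stacklevel=2)
    if np.ptp(values) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(values)
    return float(w), float(p)


def p_from_t(t: float, df: int) -> float:
    """Two-sided p-value of a Student t statistic: 2 * P(T >= |t|)."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(2.0 * sps.t.sf(abs(t), df))


def two_sample_t(group_a, group_b, metric: str = "") -> GroupComparison:
    """Equal-variance two-sample Student t-test.

    t = (mean_a - mean_b) / (s_p * sqrt(1/n1 + 1/n2)) with the pooled
    standard deviation s_p and df = n1 + n2 - 2. A zero pooled variance is
    flagged degenerate (t undefined). A normality warning is emitted when
    either group fails Shapiro-Wilk at 0.05; the test is not switched.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    var_a = float(a.var(ddof=1))
    var_b = float(b.var(ddof=1))
    sem_a = math.sqrt(var_a / n1)
    sem_b = math.sqrt(var_b / n2)
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * var_a + (n2 - 1) * var_b) / df

    def _sw(x):
        try:
            return shapiro_wilk(x)
        except ValueError:
            return (None, None)

    w_a, p_a = _sw(a)
    w_b, p_b = _sw(b)
    for grp, p_norm in (("a", p_a), ("b", p_b)):
        if p_norm is not None and p_norm < 0.05:
            warnings.warn(
                f"group {grp} fails Shapiro-Wilk normality (p={p_norm:.3g}); "
                "t-test reported anyway",
                stacklevel=2,
            )
    if pooled_var == 0:
        return GroupComparison(
            metric, mean_a, mean_b, sem_a, sem_b, n1, n2,
            w_a, p_a, w_b, p_b,
            t=float("nan"), df=df, p=float("nan"), degenerate=True,
        )
    t = (mean_a - mean_b) / math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    return GroupComparison(
        metric, mean_a, mean_b, sem_a, sem_b, n1, n2,
        w_a, p_a, w_b, p_b,
        t=float(t), df=df, p=p_from_t(t, df),
    )


def summarize_groups(
    comparisons: list[GroupComparison],
    adjust: str | None = None,
) -> pd.DataFrame:
    """Tidy report table: metric, group means +/- SEM, t, df, p.

    ``adjust="bh"`` appends Benjamini-Hochberg adjusted p-values
    (off by default)."""
    if not comparisons:
        raise ValueError("need at least one comparison")
    rows = [
        {
            "metric": c.metric,
            "mean_control": c.mean_a,
            "sem_control": c.sem_a,
            "n_control": c.n_a,
            "mean_nls": c.mean_b,
            "sem_nls": c.sem_b,
            "n_nls": c.n_b,
            "shapiro_p_control": c.shapiro_p_a,
            "shapiro_p_nls": c.shapiro_p_b,
            "t": c.t,
            "df": c.df,
            "p": c.p,
            "degenerate": c.degenerate,
        }
        for c in comparisons
    ]
    table = pd.DataFrame(rows)
    if adjust == "bh":
        p = table["p"].to_numpy(dtype=float)
        order = np.argsort(p)
        m = np.isfinite(p).sum()
        adj = np.full_like(p, np.nan)
        prev = 1.0
        for rank_idx in range(len(order) - 1, -1, -1):
            i = order[rank_idx]
            if not np.isfinite(p[i]):
                continue
            val = min(prev, p[i] * m / (rank_idx + 1))
            adj[i] = val
            prev = val
        table["p_bh"] = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table


def format_comparison(c: GroupComparison, sig_figs: int = 3) -> str:
    """Plain-text line mirroring the conventional "(t(df) = x, p = y)"."""
    return f"{c.metric}: (t({c.df}) = {c.t:.3f}, p = {c.p:.{sig_figs}g})"
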