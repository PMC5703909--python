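"""Population statistics and strain-comparison reports.

Conventions: box plots summarize median, quartiles, and the 5th/95th
percentiles (whisker limits); group differences are tested with the
two-sided Mann–Whitney rank-sum test at a default significance level of
0.001; no multiple-testing correction is applied, but the number of
comparisons is reported so users can adjust.  Symmetry-coefficient (S)
comparisons are restricted to cells with exactly two foci, the only
population for which S is comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BoxplotSummary",
    "ComparisonResult",
    "boxplot_summary",
    "mann_whitney",
    "intensity_histogram",
    "compare_strains",
    "StrainReport",
    "plot_boxes",
]

DEFAULT_ALPHA = 0.001
EXACT_MAX_N = 10


@dataclass
class BoxplotSummary:
    median: float
    q25: float
    q75: float
    p5: float
    p95: float
    n: int


@dataclass
class ComparisonResult:
    U: float
    p: float  # two-sided
    n_a: int
    n_b: int
    method: str  # exact | normal_approx
    alpha: float
    significant: bool


def boxplot_summary(values) -> BoxplotSummary:
    """Five-number box-plot summary (5/25/50/75/95th percentiles).

    Percentiles use linear interpolation between order statistics
    (inclusive convention).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("boxplot_summary: empty input")
    p5, q25, med, q75, p95 = np.percentile(arr, [5, 25, 50, 75, 95], method="linear")
    return BoxplotSummary(float(med), float(q25), float(q75), float(p5), float(p95), int(arr.size))


def mann_whitney(group_a, group_b, alpha: float = DEFAULT_ALPHA) -> ComparisonResult:
    """Two-sided Mann–Whitney U test between two independent samples.

    The exact null distribution is used when both samples have at most
    10 observations and the pooled data are tie-free; otherwise the
    normal approximation with tie and continuity corrections.  U is the
    rank-sum statistic of ``group_a`` (so U(a,b) + U(b,a) = n_a * n_b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney: both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == pooled.size
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and tie_free:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "normal_approx"
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(
        U=float(res.statistic),
        p=p,
        n_a=int(a.size),
        n_b=int(b.size),
        method=method,
        alpha=alpha,
        significant=bool(p < alpha),
    )


def intensity_histogram(values, bins=50):
    """Histogram table of per-cell intensities (DNA-content emulation).

    Bins are left-closed, right-open, with the last bin closed (numpy
    convention), so counts always sum to the number of finite values;
    non-finite inputs are dropped and counted.  Returns a DataFrame with
    bin edges and counts, plus the number of dropped values.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    dropped = int((~finite).sum())
    arr = arr[finite]
    if arr.size == 0:
        raise ValueError("intensity_histogram: no finite values")
    counts, edges = np.histogram(arr, bins=bins)
    df = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    return df, dropped


@dataclass
class StrainReport:
    """Per-group summaries and pairwise tests against a reference group."""

    metric: str
    reference: str
    summaries: dict  # group -> BoxplotSummary (or None for empty groups)
    tests: pd.DataFrame  # columns: group, U, p, n_ref, n_group, method, significant
    n_comparisons: int
    empty_groups: tuple = ()


def compare_strains(
    table: pd.DataFrame,
    group: str,
    metric: str,
    reference: str,
    alpha: float = DEFAULT_ALPHA,
) -> StrainReport:
    """Compare every group against a reference on one per-cell metric.

    ``metric`` is a column of ``table`` (e.g. S, D_min,
    nucleoid_fraction, pcc); rows with missing values are dropped, and
    S is additionally restricted to 2-focus cells when an ``n_foci``
    column is present.  Each non-reference group gets a two-sided
    Mann–Whitney test against the reference; groups empty after
    filtering are reported but excluded from testing.  Output is
    invariant to input row order.
    """
    if metric not in table.columns:
        raise ValueError(f"metric column {metric!r} not in table")
    if group not in table.columns:
        raise ValueError(f"grouping column {group!r} not in table")
    df = table.copy()
    if metric == "S" and "n_foci" in df.columns:
        df = df[df["n_foci"] == 2]
    df = df[np.isfinite(pd.to_numeric(df[metric], errors="coerce"))]
    groups = sorted(map(str, table[group].astype(str).unique()))
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not found")
    if len(groups) < 2:
        raise ValueError("compare_strains needs at least two groups")
    values = {g: df.loc[df[group].astype(str) == g, metric].to_numpy(float) for g in groups}
    empty = tuple(g for g in groups if values[g].size == 0)
    summaries = {g: (boxplot_summary(values[g]) if values[g].size else None) for g in groups}
    rows = []
    for g in groups:
        if g == reference or g in empty or reference in empty:
            continue
        res = mann_whitney(values[reference], values[g], alpha=alpha)
        rows.append(
            {
                "group": g,
                "U": res.U,
                "p": res.p,
                "n_ref": res.n_a,
                "n_group": res.n_b,
                "method": res.method,
                "significant": res.significant,
            }
        )
    tests = pd.DataFrame(
        rows, columns=["group", "U", "p", "n_ref", "n_group", "method", "significant"]
    )
    return StrainReport(
        metric=metric,
        reference=reference,
        summaries=summaries,
        tests=tests,
        n_comparisons=len(rows),
        empty_groups=empty,
    )


def plot_boxes(report: StrainReport, path=None):
    """Box plot of the report's groups with 5-95 percentile whiskers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = [g for g, s in report.summaries.items() if s is not None]
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    boxes = []
    for g in groups:
        s = report.summaries[g]
        boxes.append(
            {
                "med": s.median,
                "q1": s.q25,
                "q3": s.q75,
                "whislo": s.p5,
                "whishi": s.p95,
                "label": f"{g}\n(n={s.n})",
                "fliers": [],
            }
        )
    ax.bxp(boxes, showfliers=False)
    ax.set_ylabel(report.metric)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
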