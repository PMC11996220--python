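"""Cohort characterisation: group summaries and significance tests.

Mirrors the standard clinical Table-1 workflow for a three-group
(CN/MCI/AD) cohort: chi-square contingency tests for categorical
proportions, one-way ANOVA for near-normal continuous features —
recomputable from printed means/SDs/sizes alone — and Kruskal-Wallis for
the rest.  No continuity correction is applied in the chi-square test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CLASS_ORDER, CohortDataset

__all__ = [
    "chi_square_from_counts",
    "anova_from_summary",
    "kruskal_wallis_raw",
    "summarize_cohort",
    "format_p",
]


def chi_square_from_counts(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table, no continuity
    correction; df = (r-1)(c-1).  Zero marginals are rejected."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total in contingency table")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def anova_from_summary(means, sds, ns) -> tuple[float, int, int, float]:
    """One-way ANOVA reconstructed from per-group mean, SD and size.

    Between-group SS uses the size-weighted grand mean; within-group SS is
    sum((n_i - 1) * sd_i^2).  Exactly equivalent to raw-data one-way ANOVA
    whenever raw data with those moments exist.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    if (sds <= 0).any():
        raise ValueError("every group needs SD > 0")
    grand = float((means * ns).sum() / ns.sum())
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1 = len(means) - 1
    df2 = int(ns.sum()) - len(means)
    if ssb == 0.0:
        return 0.0, df1, df2, 1.0
    f = (ssb / df1) / (ssw / df2)
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


def kruskal_wallis_raw(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (df = groups-1).

    Groups constant across the board give H = 0, p = 1.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def format_p(p: float, threshold: float = 0.001) -> str:
    """3-significant-figure p-value with a ``<0.001`` floor."""
    if p < threshold:
        return f"<{threshold:g}"
    return f"{p:.3g}"


def summarize_cohort(
    dataset: CohortDataset, feature_tests: dict[str, str]
) -> pd.DataFrame:
    """Per-feature group summaries with the mapped significance test.

    ``feature_tests`` maps a clinical column to ``anova``, ``chi_square``
    or ``kruskal_wallis``.  Continuous features are summarised as mean +-
    SD per group (3 dp); categorical as per-group counts of each category.
    """
    labels = dataset.labels
    present = [c for c in CLASS_ORDER if (labels == c).any()]
    if len(present) < 2:
        raise ValueError("cohort summaries need at least two diagnostic groups")
    rows = []
    for feature, test in feature_tests.items():
        if feature not in dataset.clinical.columns:
            raise KeyError(f"unknown clinical feature {feature!r}")
        col = dataset.clinical[feature]
        groups = {c: col[labels == c].dropna() for c in present}
        if test == "anova":
            f, df1, df2, p = anova_from_summary(
                [g.mean() for g in groups.values()],
                [g.std(ddof=1) for g in groups.values()],
                [len(g) for g in groups.values()],
            )
            stat = f
        elif test == "kruskal_wallis":
            stat, p = kruskal_wallis_raw(*groups.values())
        elif test == "chi_square":
            cats = sorted(col.dropna().unique(), key=str)
            table = np.array(
                [[int((groups[c] == cat).sum()) for c in present] for cat in cats]
            )
            stat, _, p = chi_square_from_counts(table)
        else:
            raise ValueError(f"unknown test {test!r} for feature {feature!r}")
        row = {"feature": feature, "test": test, "statistic": stat,
               "p": p, "p_formatted": format_p(p)}
        for c in present:
            g = groups[c]
            row[f"n_{c}"] = len(g)
            if test == "chi_square":
                row[f"summary_{c}"] = "; ".join(
                    f"{cat}:{int((g == cat).sum())}" for cat in sorted(col.dropna().unique(), key=str)
                )
            else:
                row[f"summary_{c}"] = f"{g.mean():.3f} ± {g.std(ddof=1):.3f}"
        rows.append(row)
    return pd.DataFrame(rows)
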