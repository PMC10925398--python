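"""Two-group differential abundance, FDR control, threshold filters,
fraction-comparison statistics, and supervised clustering."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .containers import AbundanceMatrix


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Sorted ascending, ``q_(i) = min_{j>=i}(p_(j) * m / j)`` capped at 1 and
    mapped back to the input order.  Missing p-values pass through and do not
    count toward the family size ``m``.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    out[mask] = q
    return out


def student_ttest_table(
    matrix: AbundanceMatrix,
    groups: dict,
    group_labels: tuple = ("Control", "AD"),
    min_per_group: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein two-sided pooled-variance Student t-test on log2 values.

    ``groups`` maps sample id -> group label; ``log2fc`` is mean(group2) -
    mean(group1).  Proteins with fewer than ``min_per_group`` observed values
    in either group are excluded from testing (missing p/q, not counted in
    the BH family).  ``direction`` is up/down by log2fc sign at p < alpha,
    else unchanged.
    """
    if matrix.scale != "log2":
        raise ValueError("student_ttest_table expects a log2 matrix")
    g1_label, g2_label = group_labels
    g1 = [s for s, g in groups.items() if g == g1_label]
    g2 = [s for s, g in groups.items() if g == g2_label]
    if not g1 or not g2:
        missing = g1_label if not g1 else g2_label
        raise ValueError(f"group {missing!r} has no samples")
    unknown = [s for s in g1 + g2 if s not in matrix.sample_ids]
    if unknown:
        raise ValueError(f"unknown sample(s): {unknown[:5]}")

    x1 = matrix.data[g1].to_numpy()
    x2 = matrix.data[g2].to_numpy()
    n1 = (~np.isnan(x1)).sum(axis=1)
    n2 = (~np.isnan(x2)).sum(axis=1)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(x1, axis=1)
        m2 = np.nanmean(x2, axis=1)
        v1 = np.nanvar(x1, axis=1, ddof=1)
        v2 = np.nanvar(x2, axis=1, ddof=1)
    log2fc = m2 - m1
    df = n1 + n2 - 2
    tested = (n1 >= min_per_group) & (n2 >= min_per_group) & (df > 0)

    with np.errstate(all="ignore"):
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t = log2fc / se
    # zero pooled variance: identical groups give t=0/p=1, separated ones p=0
    degenerate = tested & (sp2 == 0)
    t[degenerate & (log2fc == 0)] = 0.0
    t[degenerate & (log2fc != 0)] = np.sign(log2fc[degenerate & (log2fc != 0)]) * np.inf
    p = np.full(len(t), np.nan)
    p[tested] = 2.0 * stats.t.sf(np.abs(t[tested]), df[tested])
    q = bh_adjust(p)

    direction = np.where(
        np.isnan(p) | (p >= alpha), "unchanged", np.where(log2fc > 0, "up", "down")
    )
    table = pd.DataFrame(
        {
            "n_group1": n1,
            "n_group2": n2,
            "log2fc": log2fc,
            "t_stat": np.where(tested, t, np.nan),
            "p_value": p,
            "q_value": q,
            "direction": direction,
        },
        index=matrix.protein_ids.rename("protein_id"),
    )
    return table


def threshold_filter(
    table: pd.DataFrame,
    p_max: float,
    fc_min_fold: float | None = None,
    use_q: bool = False,
) -> tuple[list, list]:
    """Partition a differential table into (up, down) protein lists.

    Strict inequalities throughout: significance requires p (or q) < p_max,
    and, when a fold threshold is given, |fold change| > fc_min_fold on the
    linear scale (i.e. |log2fc| > log2(fc_min_fold)).
    """
    if fc_min_fold is not None and fc_min_fold <= 1:
        raise ValueError("fc_min_fold must be > 1")
    stat = table["q_value"] if use_q else table["p_value"]
    sig = stat.notna() & (stat < p_max)
    lfc = table["log2fc"]
    bound = 0.0 if fc_min_fold is None else np.log2(fc_min_fold)
    up = list(table.index[sig & (lfc > bound)])
    down = list(table.index[sig & (lfc < -bound)])
    return up, down


def anova_tukey(values, groups) -> pd.DataFrame:
    """One-way ANOVA with Tukey HSD post-hoc pairwise adjusted p-values.

    Returns a table with one row per group pair: mean difference and the
    studentized-range adjusted p.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [values[groups == lev] for lev in levels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    if all(np.var(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group")
    f_stat, f_p = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            rows.append(
                {
                    "group1": levels[i],
                    "group2": levels[j],
                    "mean_diff": float(np.mean(arrays[j]) - np.mean(arrays[i])),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["f_stat"] = float(f_stat)
    out.attrs["f_p"] = float(f_p)
    return out


def supervised_clustering(matrix: AbundanceMatrix, protein_subset) -> tuple[list, np.ndarray]:
    """Hierarchically cluster samples on a protein subset.

    Euclidean distance, complete linkage, on complete data for the subset.
    Returns the dendrogram leaf order (sample ids) and the merge heights.
    """
    protein_subset = list(protein_subset)
    if not protein_subset:
        raise ValueError("protein subset is empty")
    missing = [p for p in protein_subset if p not in matrix.protein_ids]
    if missing:
        raise ValueError(f"unknown protein(s): {missing[:5]}")
    sub = matrix.data.loc[protein_subset]
    if sub.isna().to_numpy().any():
        raise ValueError("subset contains missing values; impute or drop first")
    samples = list(matrix.sample_ids)
    if len(samples) == 1:
        return samples, np.empty(0)
    X = sub.to_numpy().T  # samples x proteins
    Z = linkage(X, method="complete", metric="euclidean")
    order = [samples[i] for i in leaves_list(Z)]
    return order, Z[:, 2]
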