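"""Two-set meta-analysis, sample inclusion, Z-transform and trait correlation.

The two independently processed sample sets are combined with Fisher's
combined-probability method over the per-set Student p-values and the mean of
the per-set log2 fold-changes; proteins quantified in only one set keep that
set's statistics.  Protein abundances are then row Z-transformed across the
pooled, inclusion-filtered samples and correlated (Pearson) against the AD
biomarker traits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TRAIT_COLUMNS, AbundanceMatrix, SampleSheet, TraitTable


def sample_inclusion_filter(
    sheet: SampleSheet,
    traits: TraitTable,
    ratio_thresh: float = 0.226,
    moca_ad_max: float = 24.0,
    moca_ctl_min: float = 26.0,
    exempt=(),
) -> SampleSheet:
    """Drop samples that fail the CSF-biomarker / cognition criteria.

    AD samples are retained iff tTau/Abeta ratio > ``ratio_thresh`` and MoCA
    < ``moca_ad_max``; Controls iff ratio <= ``ratio_thresh`` and MoCA >
    ``moca_ctl_min``.  ``exempt`` samples (e.g. cases overlapping both sets)
    and GIS channels are always retained.
    """
    exempt = set(exempt)
    keep = []
    for sid, row in sheet.data.iterrows():
        if sid in exempt or row["is_gis"] or pd.isna(row["diagnosis"]):
            keep.append(sid)
            continue
        if row["diagnosis"] not in ("AD", "Control"):
            keep.append(sid)
            continue
        if sid not in traits.sample_ids:
            raise ValueError(f"no trait measurements for sample {sid!r}")
        ratio = traits.data.loc[sid, "tTau_Abeta_ratio"]
        moca = traits.data.loc[sid, "MoCA"]
        if pd.isna(ratio) or pd.isna(moca):
            raise ValueError(f"missing inclusion trait for sample {sid!r}")
        if row["diagnosis"] == "AD":
            if ratio > ratio_thresh and moca < moca_ad_max:
                keep.append(sid)
        else:
            if ratio <= ratio_thresh and moca > moca_ctl_min:
                keep.append(sid)
    return sheet.subset(keep)


def fisher_combine(p_values, clamp: bool = False) -> float:
    """Fisher's combined probability over 1..k p-values.

    ``X = -2 * sum(ln p_i)`` referred to a chi-square with 2k degrees of
    freedom; a single p-value is returned unchanged.  Exact zeros are an
    error unless ``clamp`` is set, in which case they are clamped to the
    smallest positive float (useful when upstream tests underflow).
    """
    p = np.asarray([v for v in np.atleast_1d(p_values)], dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if clamp:
        p = np.clip(p, np.nextafter(0, 1), 1.0)
    if np.any(np.isnan(p)) or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 1:
        return float(p[0])
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * p.size))


def meta_table(diff_set1: pd.DataFrame, diff_set2: pd.DataFrame) -> pd.DataFrame:
    """Combine two per-set differential tables over the union of proteins.

    ``mean_log2fc`` averages the per-set log2FC over the sets where the
    protein was measured; ``meta_p`` is the Fisher combination over the sets
    where it was tested.  Proteins present in one set keep that set's values
    (``n_sets`` records how many contributed).
    """
    proteins = diff_set1.index.union(diff_set2.index, sort=False)
    lfc = pd.concat(
        [diff_set1["log2fc"].reindex(proteins), diff_set2["log2fc"].reindex(proteins)], axis=1
    )
    pvals = pd.concat(
        [diff_set1["p_value"].reindex(proteins), diff_set2["p_value"].reindex(proteins)], axis=1
    )
    mean_lfc = lfc.mean(axis=1, skipna=True)
    n_sets = pvals.notna().sum(axis=1)
    meta_p = np.full(len(proteins), np.nan)
    pv = pvals.to_numpy()
    for i in range(len(proteins)):
        row = pv[i][~np.isnan(pv[i])]
        if row.size:
            meta_p[i] = fisher_combine(row, clamp=True)
    return pd.DataFrame(
        {"mean_log2fc": mean_lfc, "meta_p": meta_p, "n_sets": n_sets},
        index=proteins.rename("protein_id"),
    )


def zscore_rows(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Standardize each protein row over its observed samples (sd with n-1)."""
    if matrix.scale != "log2":
        raise ValueError("zscore_rows expects a log2 matrix")
    data = matrix.data
    n_obs = data.notna().sum(axis=1)
    if (n_obs < 2).any():
        bad = data.index[n_obs < 2][0]
        raise ValueError(f"protein {bad!r} has fewer than 2 observed values")
    mean = data.mean(axis=1, skipna=True)
    sd = data.std(axis=1, ddof=1, skipna=True)
    if (sd == 0).any():
        bad = data.index[sd == 0][0]
        raise ValueError(f"protein {bad!r} has zero variance")
    return AbundanceMatrix(data.sub(mean, axis=0).div(sd, axis=0), "zscore")


def pearson_cor_p(x, y, min_n: int = 3):
    """Pearson r over pairwise-complete pairs with a two-sided Student p.

    ``p`` comes from ``t = r * sqrt(n-2) / sqrt(1-r^2)`` with n-2 degrees of
    freedom.  Returns ``(r, p, n)``; r and p are nan when fewer than
    ``min_n`` complete pairs exist or either side is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < min_n:
        return np.nan, np.nan, n
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(xs, ys)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p, n


def trait_correlation_table(zmatrix: AbundanceMatrix, traits: TraitTable) -> pd.DataFrame:
    """Protein x trait Pearson correlations of Z-scores vs biomarker values.

    Columns are a (trait, statistic) MultiIndex with statistics ``r``, ``p``
    and ``n`` per trait.
    """
    if zmatrix.scale != "zscore":
        raise ValueError("trait_correlation_table expects a z-scored matrix")
    shared = [s for s in zmatrix.sample_ids if s in traits.sample_ids]
    Z = zmatrix.data[shared].to_numpy()
    T = traits.data.loc[shared, list(TRAIT_COLUMNS)].to_numpy()
    out = {}
    for j, trait in enumerate(TRAIT_COLUMNS):
        r_col = np.full(Z.shape[0], np.nan)
        p_col = np.full(Z.shape[0], np.nan)
        n_col = np.zeros(Z.shape[0], dtype=int)
        y = T[:, j]
        for i in range(Z.shape[0]):
            r_col[i], p_col[i], n_col[i] = pearson_cor_p(Z[i], y)
        out[(trait, "r")] = r_col
        out[(trait, "p")] = p_col
        out[(trait, "n")] = n_col
    frame = pd.DataFrame(out, index=zmatrix.protein_ids.rename("protein_id"))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["trait", "stat"])
    return frame


def select_multitrait_proteins(
    correlations: pd.DataFrame, min_significant: int = 3, alpha: float = 0.05
) -> list:
    """Proteins whose correlations reach p < alpha in >= min_significant traits."""
    traits = correlations.columns.get_level_values("trait").unique()
    if min_significant > len(traits):
        raise ValueError("min_significant exceeds the number of traits")
    pmat = correlations.loc[:, (slice(None), "p")]
    n_sig = ((pmat < alpha) & pmat.notna()).sum(axis=1)
    return list(correlations.index[n_sig >= min_significant])
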