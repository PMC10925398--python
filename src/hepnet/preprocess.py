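"""Normalization, filtering, imputation and variance correction.

The TMT chain is: channel-sum scaling -> 50% missingness filter -> TAMPOR
(tunable two-way median polish of log-ratios against an internal-standard
denominator) -> non-parametric bootstrap regression of nuisance covariates.
The LFQ chain instead uses the 2-of-3 detection filter and downshifted
Gaussian imputation.  All downstream statistics operate on log2 abundance;
the TMT chain never imputes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, SampleSheet

logger = logging.getLogger("hepnet.preprocess")

_IMPUTE_STAGE = 11
_BOOT_STAGE = 12


def channel_sum_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each sample so observed column sums match the largest column sum.

    Each observed value becomes ``v_ij * max_k(S_k) / S_j`` where ``S_j`` is
    the sum of observed intensities in sample ``j``; missing entries stay
    missing.  On complete matrices all column sums are equal afterwards.
    """
    if matrix.scale not in ("raw", "normalized"):
        raise ValueError("channel_sum_normalize expects a raw-scale matrix")
    sums = matrix.data.sum(axis=0, skipna=True)
    empty = sums.index[(matrix.data.notna().sum(axis=0) == 0)]
    if len(empty):
        raise ValueError(f"sample {empty[0]!r} has no observed values")
    scaled = matrix.data * (sums.max() / sums)
    return AbundanceMatrix(scaled, "normalized")


def filter_missingness(matrix: AbundanceMatrix, max_missing_frac: float = 0.5) -> AbundanceMatrix:
    """Drop proteins whose missing fraction strictly exceeds the threshold.

    A protein missing in exactly half the samples is retained under the
    default (removal requires *more than* 50% missing).
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = matrix.data.isna().mean(axis=1)
    keep = frac <= max_missing_frac
    logger.info("filter_missingness: retained %d of %d proteins", int(keep.sum()), len(keep))
    return AbundanceMatrix(matrix.data.loc[keep].copy(), matrix.scale)


def detect_in_k_of_n(matrix: AbundanceMatrix, groups: dict, k: int) -> dict:
    """Per group, the set of proteins observed in at least ``k`` member samples."""
    unknown = [s for s in groups if s not in matrix.sample_ids]
    if unknown:
        raise ValueError(f"unknown sample(s) in groups: {unknown[:5]}")
    out: dict[str, set] = {}
    by_group: dict[str, list] = {}
    for sample, group in groups.items():
        by_group.setdefault(group, []).append(sample)
    for group, samples in by_group.items():
        if k > len(samples):
            raise ValueError(f"k={k} exceeds size of group {group!r} ({len(samples)})")
        counts = matrix.data[samples].notna().sum(axis=1)
        out[group] = set(matrix.protein_ids[counts >= k])
    return out


def impute_downshifted(
    matrix: AbundanceMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
) -> AbundanceMatrix:
    """Left-censored Gaussian imputation per sample column.

    Missing cells in column ``j`` draw from ``N(m_j - downshift * s_j,
    (width * s_j)^2)`` where ``m_j``/``s_j`` are the observed mean and sd of
    that column — the standard downshifted-distribution treatment of
    below-detection-limit intensities.
    """
    if matrix.scale != "log2":
        raise ValueError("impute_downshifted expects a log2 matrix")
    rng = np.random.default_rng([_IMPUTE_STAGE, int(seed)])
    data = matrix.data.copy()
    for col in data.columns:
        vals = data[col]
        observed = vals.dropna()
        if len(observed) < 2:
            raise ValueError(f"sample {col!r} has fewer than 2 observed values")
        n_missing = int(vals.isna().sum())
        if n_missing == 0:
            continue
        m, s = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(m - downshift * s, width * s, size=n_missing)
        data.loc[vals.isna(), col] = draws
    return AbundanceMatrix(data, "log2")


@dataclass
class TamporOptions:
    """Options for the tunable median-polish batch correction.

    ``denominator`` picks the per-batch reference used to form log-ratios:
    the pooled internal-standard channels (``gis``) or all samples of the
    batch (``all_samples``) — this is the "tunable" part.
    """

    denominator: str = "gis"
    max_iter: int = 250
    tol: float = 1e-8
    output_scale: str = "log2"

    def __post_init__(self) -> None:
        if self.denominator not in ("gis", "all_samples"):
            raise ValueError("denominator must be 'gis' or 'all_samples'")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.output_scale not in ("log2", "abundance"):
            raise ValueError("output_scale must be 'log2' or 'abundance'")


def median_polish(residuals: np.ndarray, max_iter: int, tol: float) -> tuple[np.ndarray, bool]:
    """Two-way median polish: alternately remove row then column medians.

    Missing cells are ignored by the medians and stay missing.  Returns the
    polished residuals and whether the largest absolute adjustment fell below
    ``tol`` within ``max_iter`` sweeps.
    """
    res = residuals.copy()
    for _ in range(max_iter):
        with np.errstate(all="ignore"):
            row_med = np.nanmedian(res, axis=1)
        row_med = np.where(np.isnan(row_med), 0.0, row_med)
        res -= row_med[:, None]
        with np.errstate(all="ignore"):
            col_med = np.nanmedian(res, axis=0)
        col_med = np.where(np.isnan(col_med), 0.0, col_med)
        res -= col_med[None, :]
        delta = max(np.max(np.abs(row_med)), np.max(np.abs(col_med)))
        if delta < tol:
            return res, True
    return res, False


def tampor(matrix: AbundanceMatrix, sheet: SampleSheet, opts: TamporOptions | None = None) -> AbundanceMatrix:
    """Tunable median polish of ratios: remove batch and loading effects.

    Per protein and batch, a denominator ``d_ib`` is the median over the
    batch's denominator samples; the log2 ratios ``R_ij = log2(A_ij /
    d_ib(j))`` are then two-way median polished, and the per-protein log2
    median abundance over all samples is added back so values stay on an
    interpretable abundance scale.  All medians are taken on the log2 scale
    (geometric interpolation for even counts), which makes the correction
    exactly idempotent.
    """
    opts = opts or TamporOptions()
    if matrix.scale not in ("raw", "normalized"):
        raise ValueError("tampor expects positive raw/normalized abundances")
    sheet.check_matches(matrix)
    sub = sheet.data.loc[matrix.sample_ids]
    vals = matrix.values
    ratios = np.full_like(vals, np.nan)
    log2_vals = np.log2(vals)

    for batch in dict.fromkeys(sub["batch_label"]):
        in_batch = (sub["batch_label"] == batch).to_numpy()
        if opts.denominator == "gis":
            denom_cols = in_batch & sub["is_gis"].to_numpy()
            if not denom_cols.any():
                raise ValueError(f"batch {batch!r} has no GIS denominator samples")
        else:
            denom_cols = in_batch
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d_log2 = np.nanmedian(log2_vals[:, denom_cols], axis=1)
        ratios[:, in_batch] = log2_vals[:, in_batch] - d_log2[:, None]

    polished, converged = median_polish(ratios, opts.max_iter, opts.tol)
    if not converged:
        logger.warning("tampor: median polish did not converge within %d iterations", opts.max_iter)

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        anchor = np.nanmedian(log2_vals, axis=1)
    out = polished + anchor[:, None]
    frame = pd.DataFrame(out, index=matrix.protein_ids, columns=matrix.sample_ids)
    if opts.output_scale == "abundance":
        return AbundanceMatrix(np.exp2(frame), "normalized")
    return AbundanceMatrix(frame, "log2")


def _design_matrix(sub: pd.DataFrame, terms) -> tuple[np.ndarray, list, list]:
    """Intercept + one-hot (drop-first) categoricals + numeric covariates.

    Returns the matrix, the column names, and the indices of columns
    belonging to each requested term.
    """
    cols = [np.ones(len(sub))]
    names = ["intercept"]
    spans: list[tuple[str, list]] = []
    for term in terms:
        series = sub[term]
        if series.dtype.kind in "fiu":
            idx = [len(names)]
            cols.append(series.to_numpy(dtype=float))
            names.append(term)
        else:
            levels = list(dict.fromkeys(series.dropna()))
            if len(levels) < 2:
                raise ValueError(f"categorical covariate {term!r} has fewer than 2 levels")
            idx = []
            for level in levels[1:]:
                idx.append(len(names))
                cols.append((series == level).to_numpy(dtype=float))
                names.append(f"{term}[{level}]")
        spans.append((term, idx))
    return np.column_stack(cols), names, spans


def bootstrap_covariate_regress(
    matrix: AbundanceMatrix,
    sheet: SampleSheet,
    covariates,
    protect=("diagnosis",),
    n_boot: int = 100,
    seed: int = 0,
) -> AbundanceMatrix:
    """Remove covariate effects by bootstrap-averaged OLS, per protein.

    Each protein's log2 abundance is regressed on the protected terms plus
    the covariates over its complete cases; coefficients are averaged over
    ``n_boot`` batch-stratified bootstrap resamples of the samples
    (rank-deficient resamples are skipped and redrawn).  The corrected value
    subtracts only the covariate contributions, centred at the covariate
    means, so protected (e.g. diagnosis) effects are untouched.
    """
    if matrix.scale != "log2":
        raise ValueError("bootstrap_covariate_regress expects a log2 matrix")
    covariates = list(covariates)
    protect = list(protect)
    overlap = set(covariates) & set(protect)
    if overlap:
        raise ValueError(f"terms cannot be both protected and covariates: {sorted(overlap)}")
    sheet.check_matches(matrix)
    sub = sheet.data.loc[matrix.sample_ids].copy()
    # GIS channels have no diagnosis; they are excluded from the fit and left untouched
    usable = np.ones(len(sub), dtype=bool)
    for term in protect + covariates:
        if term not in sub.columns:
            raise ValueError(f"term {term!r} not found in sample sheet")
        usable &= sub[term].notna().to_numpy()

    X_all, names, spans = _design_matrix(sub[usable], protect + covariates)
    cov_idx = [i for term, idx in spans if term in covariates for i in idx]
    n_params = X_all.shape[1]
    usable_pos = np.flatnonzero(usable)
    batches = sub["batch_label"].to_numpy()[usable_pos]

    rng = np.random.default_rng([_BOOT_STAGE, int(seed)])
    # pre-draw a pool of batch-stratified resamples shared across proteins;
    # n_boot=0 degenerates to a single plain-OLS fit on the full sample
    plain_ols = n_boot == 0
    n_boot = max(n_boot, 1)
    pool_size = n_boot * 2
    resamples = np.empty((pool_size, len(usable_pos)), dtype=int)
    for r in range(pool_size):
        if plain_ols:
            resamples[r] = np.arange(len(usable_pos))
            continue
        draw = []
        for batch in dict.fromkeys(batches):
            members = np.flatnonzero(batches == batch)
            draw.append(rng.choice(members, size=len(members), replace=True))
        resamples[r] = np.concatenate(draw)

    Y = matrix.values
    corrected = Y.copy()
    x_means = X_all.mean(axis=0)
    n_uncorrected = 0
    for i in range(Y.shape[0]):
        y = Y[i, usable_pos]
        obs = ~np.isnan(y)
        if obs.sum() < n_params:
            n_uncorrected += 1
            continue
        coefs = np.zeros(n_params)
        n_ok = 0
        for r in range(pool_size):
            rows = resamples[r][obs[resamples[r]]]
            Xb = X_all[rows]
            beta, _, rank, _ = np.linalg.lstsq(Xb, y[rows], rcond=None)
            if rank < n_params:
                continue  # rank-deficient resample: skip, the pool holds spares
            coefs += beta
            n_ok += 1
            if n_ok == n_boot:
                break
        if n_ok == 0:
            n_uncorrected += 1
            continue
        coefs /= n_ok
        adjustment = (X_all[:, cov_idx] - x_means[cov_idx]) @ coefs[cov_idx]
        corrected[i, usable_pos] = np.where(np.isnan(y), np.nan, y - adjustment)
    if n_uncorrected:
        logger.warning(
            "bootstrap_covariate_regress: %d protein(s) left uncorrected (too few complete cases)",
            n_uncorrected,
        )
    frame = pd.DataFrame(corrected, index=matrix.protein_ids, columns=matrix.sample_ids)
    return AbundanceMatrix(frame, "log2")
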