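"""Projection of a proteome onto a reference co-expression network.

Implements the biweight midcorrelation (bicor), module eigenproteins (first
principal component of the standardized member proteins), kME-based module
(re)assignment with a grey fallback, module-trait correlation, and the
one-tailed hypergeometric (Fisher exact) overrepresentation machinery used
for module-overlap and cell-type enrichment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GREY, AbundanceMatrix, NetworkReference, gene_symbols
from .differential import bh_adjust

logger = logging.getLogger("hepnet.netmap")


def _biweight_transform(v: np.ndarray) -> np.ndarray:
    """Median/MAD-based biweight transform of one vector.

    ``u = (v - median) / (9 * MAD)``; weights ``(1 - u^2)^2`` inside |u|<1,
    zero outside.  Falls back to plain mean-centering when MAD is zero (or
    every weight vanishes), which reduces bicor to Pearson for that vector.
    """
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return v - np.mean(v)
    u = (v - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    if not np.any(w > 0):
        logger.warning("bicor: all biweight weights vanished; falling back to Pearson centering")
        return v - np.mean(v)
    return (v - med) * w


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors over pairwise-complete pairs.

    Robust to outliers: observations far from the median (beyond 9 MADs) get
    zero weight.  Returns nan with fewer than 3 complete pairs or when a
    transformed vector has zero norm.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return np.nan
    xt = _biweight_transform(x[ok])
    yt = _biweight_transform(y[ok])
    nx = np.sqrt((xt**2).sum())
    ny = np.sqrt((yt**2).sum())
    if nx == 0 or ny == 0:
        return np.nan
    return float(np.clip((xt * yt).sum() / (nx * ny), -1.0, 1.0))


def bicor_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """bicor between every row of X and every row of Y (same column space).

    Fully vectorized when both matrices are complete; rows containing
    missing values drop to pairwise-complete scalar evaluation.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    out = np.full((X.shape[0], Y.shape[0]), np.nan)
    x_complete = ~np.isnan(X).any(axis=1)
    y_complete = ~np.isnan(Y).any(axis=1)
    if y_complete.all():
        Yt = np.vstack([_biweight_transform(row) for row in Y])
        norms_y = np.sqrt((Yt**2).sum(axis=1))
        Xc = X[x_complete]
        if Xc.size:
            Xt = np.vstack([_biweight_transform(row) for row in Xc])
            norms_x = np.sqrt((Xt**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                out[x_complete] = (Xt @ Yt.T) / np.outer(norms_x, norms_y)
        for i in np.flatnonzero(~x_complete):
            for j in range(Y.shape[0]):
                out[i, j] = bicor(X[i], Y[j])
    else:
        for i in range(X.shape[0]):
            for j in range(Y.shape[0]):
                out[i, j] = bicor(X[i], Y[j])
    return np.clip(out, -1.0, 1.0)


def module_eigenprotein(matrix: AbundanceMatrix, member_ids) -> pd.Series:
    """First principal component of a module's standardized member proteins.

    Missing member values are filled with that protein's row mean before the
    decomposition.  The returned sample-length vector is standardized (mean
    0, sd 1 with n-1) and signed so it correlates positively with the mean
    standardized member profile.
    """
    member_ids = [m for m in member_ids if m in matrix.protein_ids]
    sub = matrix.data.loc[member_ids]
    usable = sub.index[(sub.notna().sum(axis=1) >= 2) & (sub.std(axis=1, ddof=1) > 0)]
    if len(usable) < 2:
        raise ValueError("need at least 2 usable member proteins")
    sub = sub.loc[usable]
    filled = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
    standardized = filled.sub(filled.mean(axis=1), axis=0).div(filled.std(axis=1, ddof=1), axis=0)
    X = standardized.to_numpy()
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    pc = vt[0]
    pc = (pc - pc.mean()) / pc.std(ddof=1)
    reference = X.mean(axis=0)
    if np.corrcoef(pc, reference)[0, 1] < 0:
        pc = -pc
    return pd.Series(pc, index=matrix.sample_ids)


def recompute_eigenproteins(matrix: AbundanceMatrix, ref: NetworkReference, min_members: int = 2) -> pd.DataFrame:
    """Eigenproteins of the reference modules on a query matrix.

    Membership is matched by gene symbol, so a network built on one tissue
    can be projected onto a proteome measured on different samples.  Modules
    with too few matched members are dropped (logged).
    """
    membership = ref.membership_by_symbol()
    symbols = matrix.symbols
    eig = {}
    for module in ref.module_ids:
        module_syms = set(membership.index[membership == module])
        members = matrix.protein_ids[symbols.isin(module_syms)]
        if len(members) < min_members:
            logger.info("module %s: only %d member(s) in query matrix; skipped", module, len(members))
            continue
        try:
            eig[module] = module_eigenprotein(matrix, members)
        except ValueError:
            logger.info("module %s: eigenprotein not computable on query matrix; skipped", module)
    if not eig:
        raise ValueError("no reference module has enough members in the query matrix")
    return pd.DataFrame(eig).T


def assign_to_modules(
    matrix: AbundanceMatrix,
    ref: NetworkReference,
    kme_min: float = 0.30,
    mode: str = "shared",
) -> pd.DataFrame:
    """Assign each protein to the module whose eigenprotein it tracks best.

    kME is the bicor of a protein's profile against each module eigenprotein.
    The protein goes to the module with the highest positive kME when that
    value is >= ``kme_min`` (inclusive), otherwise to grey.  Ties break to
    the lowest module index.  ``mode='shared'`` correlates against the
    reference eigenproteins on the shared sample space; ``mode='recompute'``
    rebuilds eigenproteins from reference membership on the query matrix
    (for projecting across tissues).
    """
    if mode not in ("shared", "recompute"):
        raise ValueError("mode must be 'shared' or 'recompute'")
    if mode == "recompute":
        eig = recompute_eigenproteins(matrix, ref)
        data = matrix.data
    else:
        shared = [s for s in matrix.sample_ids if s in ref.sample_ids]
        if len(shared) < 3:
            raise ValueError("query matrix and reference eigenproteins share fewer than 3 samples")
        eig = ref.eigenproteins[shared]
        data = matrix.data[shared]

    kme = bicor_matrix(data.to_numpy(), eig.to_numpy())
    modules = list(eig.index)
    best_idx = np.nanargmax(np.where(np.isnan(kme), -np.inf, kme), axis=1)
    best = kme[np.arange(len(kme)), best_idx]
    assigned = np.array(
        [modules[j] if (not np.isnan(b)) and b >= kme_min else GREY for j, b in zip(best_idx, best)],
        dtype=object,
    )
    table = pd.DataFrame(
        {"assigned_module": assigned, "kme_best": best},
        index=matrix.protein_ids.rename("protein_id"),
    )
    kme_cols = pd.DataFrame(kme, index=table.index, columns=[f"kme_{m}" for m in modules])
    return pd.concat([table, kme_cols], axis=1)


def module_trait_bicor(eigenproteins: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """bicor of each module eigenprotein against each trait, with Student p.

    Returns a module x (trait, stat) table; constant traits or too few
    complete pairs yield nan.
    """
    shared = [s for s in eigenproteins.columns if s in traits.index]
    E = eigenproteins[shared].to_numpy()
    out = {}
    for trait in traits.columns:
        y = traits.loc[shared, trait].to_numpy(dtype=float)
        r_col = np.full(E.shape[0], np.nan)
        p_col = np.full(E.shape[0], np.nan)
        for i in range(E.shape[0]):
            ok = ~(np.isnan(E[i]) | np.isnan(y))
            n = int(ok.sum())
            r = bicor(E[i], y)
            if np.isnan(r) or n < 3:
                continue
            r_col[i] = r
            if abs(r) == 1.0:
                p_col[i] = 0.0
            else:
                t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
                p_col[i] = 2.0 * stats.t.sf(abs(t), n - 2)
        out[(trait, "r")] = r_col
        out[(trait, "p")] = p_col
    frame = pd.DataFrame(out, index=eigenproteins.index.rename("module_id"))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["trait", "stat"])
    return frame


def fisher_exact_one_tailed(k, K, n, N):
    """One-tailed overrepresentation p and hypergeometric Z for an overlap.

    ``p = P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)`` (overlap of a
    size-``n`` foreground with a size-``K`` set in a size-``N`` background);
    ``z = (k - mu) / sigma`` with the hypergeometric moments, 0 when sigma
    vanishes.  Accepts scalars or broadcastable arrays.
    """
    k = np.asarray(k, dtype=int)
    K = np.asarray(K, dtype=int)
    n = np.asarray(n, dtype=int)
    N = np.asarray(N, dtype=int)
    if np.any((k < 0) | (K < 0) | (n < 0) | (N < 0)) or np.any((K > N) | (n > N)):
        raise ValueError("inconsistent hypergeometric margins")
    if np.any(k > np.minimum(K, n)):
        raise ValueError("overlap k exceeds min(K, n)")
    p = stats.hypergeom.sf(k - 1, N, K, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = n * K / N
        var = n * K * (N - K) * (N - n) / (N**2 * np.maximum(N - 1, 1))
        z = np.where(var > 0, (k - mu) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    if p.ndim == 0:
        return float(p), float(z)
    return p, z


def _enrichment_rows(foreground: set, sets: dict, background: set) -> pd.DataFrame:
    """Shared overrepresentation table builder (no BH)."""
    N = len(background)
    n = len(foreground)
    rows = []
    for set_id, members in sets.items():
        in_bg = set(members) & background
        K = len(in_bg)
        if K == 0:
            continue
        k = len(in_bg & foreground)
        p, z = fisher_exact_one_tailed(k, K, n, N)
        rows.append(
            {
                "set_id": set_id,
                "overlap_k": k,
                "set_size_K": K,
                "foreground_n": n,
                "background_N": N,
                "expected_mu": n * K / N,
                "z_score": z,
                "p_one_tailed": p,
            }
        )
    return pd.DataFrame(rows).set_index("set_id") if rows else pd.DataFrame(
        columns=["overlap_k", "set_size_K", "foreground_n", "background_N", "expected_mu", "z_score", "p_one_tailed"]
    )


def module_overlap_fet(
    fg_up,
    fg_down,
    ref: NetworkReference,
    background,
) -> pd.DataFrame:
    """Overrepresentation of up-/down-regulated proteins in network modules.

    Foregrounds and background are gene symbols; module member lists are
    intersected with the background and BH correction runs across modules
    within each direction.
    """
    background = {s.upper() for s in background}
    membership = ref.membership_by_symbol()
    module_sets = {
        m: set(membership.index[membership == m]) for m in ref.module_ids
    }
    frames = []
    for direction, fg in (("up", fg_up), ("down", fg_down)):
        fg = {s.upper() for s in fg}
        outside = fg - background
        if outside:
            raise ValueError(f"foreground symbols missing from background: {sorted(outside)[:5]}")
        table = _enrichment_rows(fg, module_sets, background)
        table["q_bh"] = bh_adjust(table["p_one_tailed"].to_numpy()) if len(table) else []
        table["direction"] = direction
        frames.append(table)
    out = pd.concat(frames)
    out.index.name = "set_id"
    return out


def celltype_fet(ref: NetworkReference, markers: dict, background) -> pd.DataFrame:
    """Cell-type enrichment of each module against marker gene lists.

    One-tailed FET per (module, cell type) on case-insensitive symbol
    overlap; BH correction across all module x cell-type cells.
    """
    background = {s.upper() for s in background}
    if not background:
        raise ValueError("background is empty")
    for celltype, genes in markers.items():
        if not genes:
            raise ValueError(f"marker list for {celltype!r} is empty")
    membership = ref.membership_by_symbol()
    rows = []
    N = len(background)
    for module in ref.module_ids:
        module_syms = set(membership.index[membership == module]) & background
        if not module_syms:
            continue
        for celltype, genes in markers.items():
            marker_syms = {g.upper() for g in genes} & background
            K = len(marker_syms)
            if K == 0:
                continue
            k = len(module_syms & marker_syms)
            p, z = fisher_exact_one_tailed(k, K, len(module_syms), N)
            rows.append(
                {
                    "module_id": module,
                    "celltype": celltype,
                    "overlap_k": k,
                    "set_size_K": K,
                    "foreground_n": len(module_syms),
                    "background_N": N,
                    "expected_mu": len(module_syms) * K / N,
                    "z_score": z,
                    "p_one_tailed": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_bh"] = bh_adjust(out["p_one_tailed"].to_numpy())
    return out
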