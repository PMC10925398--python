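"""bicor, eigenproteins, kME module assignment and overrepresentation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hepnet import (
    AbundanceMatrix,
    NetworkReference,
    assign_to_modules,
    bicor,
    celltype_fet,
    fisher_exact_one_tailed,
    module_eigenprotein,
    module_overlap_fet,
    module_trait_bicor,
)


# ----------------------------------------------------------------------- bicor
def test_bicor_self_correlation(rng):
    x = rng.normal(size=50)
    assert bicor(x, x) == pytest.approx(1.0)
    assert bicor(x, -x) == pytest.approx(-1.0)


def test_bicor_close_to_pearson_on_clean_data(rng):
    x = rng.normal(size=500)
    y = 0.5 * x + np.sqrt(0.75) * rng.normal(size=500)
    pearson = np.corrcoef(x, y)[0, 1]
    assert abs(bicor(x, y) - pearson) < 0.05


def test_bicor_outlier_robustness(rng):
    x = rng.normal(size=200)
    y = 0.6 * x + 0.8 * rng.normal(size=200)
    clean = bicor(x, y)
    x_out = np.append(x, 100.0)
    y_out = np.append(y, -100.0)
    robust = bicor(x_out, y_out)
    pearson_shift = abs(np.corrcoef(x_out, y_out)[0, 1] - np.corrcoef(x, y)[0, 1])
    assert abs(robust - clean) < 0.05
    assert pearson_shift > 0.2


def test_bicor_edge_cases(rng):
    assert np.isnan(bicor([1.0, 2.0], [3.0, 4.0]))  # too few pairs
    # zero MAD (heavily tied vector) falls back to Pearson-style centering
    x = np.array([1.0, 1.0, 1.0, 1.0, 5.0])
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert np.isfinite(bicor(x, y))
    # pairwise-complete handling
    xm = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
    assert np.isfinite(bicor(xm, y))


# --------------------------------------------------------------- eigenprotein
def test_eigenprotein_rank_one_module():
    profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
    rows = np.vstack([profile, profile, profile])
    m = AbundanceMatrix(
        pd.DataFrame(rows, index=["A|A", "B|B", "C|C"], columns=[f"s{j}" for j in range(6)]),
        "log2",
    )
    e = module_eigenprotein(m, ["A|A", "B|B", "C|C"])
    standardized = (profile - profile.mean()) / profile.std(ddof=1)
    assert np.allclose(e.to_numpy(), standardized, atol=1e-9)


def test_eigenprotein_recovers_latent(brain_net):
    matrix, ref, _, truth = brain_net
    for module in ["M1", "M5"]:
        members = truth.true_membership.index[truth.true_membership == module]
        e = module_eigenprotein(matrix, members)
        r = np.corrcoef(e, truth.latents.loc[module])[0, 1]
        assert abs(r) > 0.9


def test_eigenprotein_sign_convention(brain_net):
    matrix, ref, _, truth = brain_net
    members = list(truth.true_membership.index[truth.true_membership == "M2"])
    e = module_eigenprotein(matrix, members)
    flipped = AbundanceMatrix(-matrix.data.loc[members], "log2")
    e_flip = module_eigenprotein(flipped, members)
    # members correlate positively with their eigenprotein in both orientations
    std = lambda df: df.sub(df.mean(axis=1), axis=0).div(df.std(axis=1, ddof=1), axis=0)
    assert std(matrix.data.loc[members]).mul(e, axis=1).mean(axis=1).mean() > 0
    assert std(flipped.data).mul(e_flip, axis=1).mean(axis=1).mean() > 0
    with pytest.raises(ValueError, match="at least 2"):
        module_eigenprotein(matrix, [members[0]])


# ------------------------------------------------------------------ assignment
def test_assignment_recovers_planted_network(brain_net):
    matrix, ref, _, truth = brain_net
    table = assign_to_modules(matrix, ref, kme_min=0.30, mode="shared")
    members = truth.true_membership != "grey"
    correct = (
        table.loc[members.index[members], "assigned_module"].to_numpy()
        == truth.true_membership[members].to_numpy()
    )
    assert correct.mean() >= 0.9
    grey = truth.true_membership == "grey"
    grey_ok = (table.loc[grey.index[grey], "assigned_module"] == "grey").mean()
    assert grey_ok >= 0.8


def test_assignment_threshold_inclusive_and_grey_fallback(brain_net):
    matrix, ref, _, _ = brain_net
    # a protein identical to an eigenprotein is assigned there with kME 1
    clone = AbundanceMatrix(
        pd.DataFrame(
            [ref.eigenproteins.loc["M3"].to_numpy()], index=["X|X"], columns=ref.sample_ids
        ),
        "log2",
    )
    table = assign_to_modules(clone, ref, kme_min=1.0, mode="shared")
    assert table.loc["X|X", "assigned_module"] == "M3"  # >= threshold is inclusive
    assert table.loc["X|X", "kme_best"] == pytest.approx(1.0)
    # raising the threshold above the achievable kME sends proteins to grey
    strict = assign_to_modules(matrix, ref, kme_min=0.9999, mode="shared")
    frac_grey = (strict["assigned_module"] == "grey").mean()
    assert frac_grey > 0.99


def test_assignment_affine_invariance(brain_net):
    matrix, ref, _, _ = brain_net
    sub = AbundanceMatrix(matrix.data.iloc[:30], "log2")
    base = assign_to_modules(sub, ref, mode="shared")
    rescaled = AbundanceMatrix(sub.data.mul(3.7).add(12.0), "log2")
    moved = assign_to_modules(rescaled, ref, mode="shared")
    assert (base["assigned_module"] == moved["assigned_module"]).all()
    assert np.allclose(base["kme_best"], moved["kme_best"], atol=1e-12)


def test_assignment_recompute_mode_cross_samples(brain_net):
    matrix, ref, _, truth = brain_net
    # rename samples: no shared sample space with the reference
    renamed = AbundanceMatrix(
        matrix.data.rename(columns=lambda s: "Q" + s), "log2"
    )
    table = assign_to_modules(renamed, ref, mode="recompute")
    members = truth.true_membership != "grey"
    correct = (
        table.loc[members.index[members], "assigned_module"].to_numpy()
        == truth.true_membership[members].to_numpy()
    )
    assert correct.mean() >= 0.9
    with pytest.raises(ValueError, match="fewer than 3 samples"):
        assign_to_modules(renamed, ref, mode="shared")


# ------------------------------------------------------------------------ FET
def test_fet_hand_derived_example():
    p, z = fisher_exact_one_tailed(3, 4, 4, 8)
    assert p == pytest.approx(17 / 70, rel=1e-12)
    assert z == pytest.approx((3 - 2) / math.sqrt(256 / 448), rel=1e-10)


def test_fet_boundary_cases():
    p, z = fisher_exact_one_tailed(0, 5, 5, 20)
    assert p == pytest.approx(1.0)
    p, z = fisher_exact_one_tailed(4, 4, 4, 4)  # all margins equal
    assert p == pytest.approx(1.0)
    assert z == 0.0
    with pytest.raises(ValueError, match="margins|exceeds"):
        fisher_exact_one_tailed(5, 4, 4, 8)


def test_fet_matches_enumeration_small():
    """Exhaustive check against hand enumeration for small backgrounds."""
    for N in (6, 11, 17):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    p, _ = fisher_exact_one_tailed(k, K, n, N)
                    total = math.comb(N, n)
                    tail = sum(
                        math.comb(K, j) * math.comb(N - K, n - j)
                        for j in range(k, min(K, n) + 1)
                    )
                    assert p == pytest.approx(tail / total, rel=1e-10)


# ------------------------------------------------------- module / cell-type FET
def test_module_overlap_maximal_for_own_members(brain_net):
    _, ref, _, _ = brain_net
    background = {s for s in ref.membership_by_symbol().index}
    fg_up = set(ref.module_symbols("M4"))
    out = module_overlap_fet(fg_up, set(), ref, background)
    up = out[out["direction"] == "up"]
    assert up["p_one_tailed"].idxmin() == "M4"
    assert up.loc["M4", "overlap_k"] == len(fg_up)
    # disjoint module has k=0, p=1
    assert up.loc["M5", "overlap_k"] == 0
    assert up.loc["M5", "p_one_tailed"] == pytest.approx(1.0)


def test_module_overlap_foreground_subset_enforced(brain_net):
    _, ref, _, _ = brain_net
    with pytest.raises(ValueError, match="missing from background"):
        module_overlap_fet({"NOT_A_GENE"}, set(), ref, set(ref.module_symbols("M1")))


def test_celltype_fet_planted_module_and_case_insensitive(brain_net):
    _, ref, _, _ = brain_net
    background = set(ref.membership_by_symbol().index)
    markers = {
        "astro": [s.lower() for s in list(ref.module_symbols("M2"))[:10]],
        "micro": ["ZZZZ1", "ZZZZ2", "ZZZZ3"],
    }
    out = celltype_fet(ref, markers, background | {"ZZZZ1", "ZZZZ2", "ZZZZ3"})
    astro = out[out["celltype"] == "astro"].set_index("module_id")
    assert astro["q_bh"].idxmin() == "M2"
    micro = out[out["celltype"] == "micro"]
    assert (micro["overlap_k"] == 0).all()
    assert np.allclose(micro["p_one_tailed"], 1.0)
    with pytest.raises(ValueError, match="empty"):
        celltype_fet(ref, {"astro": []}, background)


def test_module_trait_bicor_recovers_planted_trait(brain_net):
    _, ref, traits, _ = brain_net
    out = module_trait_bicor(ref.eigenproteins, traits)
    assert out.shape == (len(ref.module_ids), 2 * traits.shape[1])
    assert out.loc["M1", ("CERAD", "r")] > 0.5
    assert out.loc["M1", ("CERAD", "p")] < 1e-4
    others = out.drop(index="M1")
    assert others[("CERAD", "r")].abs().median() < 0.25
    constant = traits.assign(CERAD=1.0)
    flagged = module_trait_bicor(ref.eigenproteins, constant)
    assert flagged[("CERAD", "r")].isna().all()


def test_eigenprotein_beats_random_subsets(brain_net):
    """A planted module's eigenprotein explains more member variance than a
    random protein subset of the same size explains of its own."""
    matrix, ref, _, truth = brain_net
    members = list(truth.true_membership.index[truth.true_membership == "M1"])

    def explained(ids):
        sub = matrix.data.loc[ids]
        std = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
        s = np.linalg.svd(std.to_numpy(), compute_uv=False)
        return s[0] ** 2 / (s**2).sum()

    target = explained(members)
    rng = np.random.default_rng(0)
    wins = 0
    for _ in range(100):
        random_ids = rng.choice(matrix.protein_ids, size=len(members), replace=False)
        if target > explained(random_ids):
            wins += 1
    assert wins >= 99
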