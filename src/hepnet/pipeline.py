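"""Stage orchestration: each stage reads its inputs from, and writes its
outputs to, a run directory, so the CLI subcommands compose and a full run is
reproducible byte-for-byte from (config, seed).
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import io as hio
from . import meta as hmeta
from . import netmap as hnet
from .config import config_hash
from .containers import AbundanceMatrix, gene_symbols
from .differential import student_ttest_table, supervised_clustering, threshold_filter
from .enrichment import go_fet
from .preprocess import (
    TamporOptions,
    bootstrap_covariate_regress,
    channel_sum_normalize,
    filter_missingness,
    tampor,
)
from .simulate import (
    simulate_celltype_markers,
    simulate_gene_sets,
    simulate_lfq_fractions,
    simulate_reference_brain,
    simulate_tmt_plasma,
)

logger = logging.getLogger("hepnet.pipeline")

_EFFECT_PICK_STAGE = 9


def _path(out_dir, stage, name):
    hio.ensure_dir(os.path.join(out_dir, stage))
    return os.path.join(out_dir, stage, name)


def _update_manifest(out_dir, cfg, seed, stage, counts):
    path = os.path.join(out_dir, "manifest.json")
    manifest = {"seed": seed, "config_hash": config_hash(cfg), "stages": {}}
    if os.path.exists(path):
        with open(path) as fh:
            manifest = json.load(fh)
    manifest["seed"] = seed
    manifest["config_hash"] = config_hash(cfg)
    manifest.setdefault("stages", {})[stage] = counts
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("stage %s: %s", stage, counts)


def run_simulate(cfg, seed, out_dir) -> dict:
    """Generate the synthetic plasma study, reference brain and LFQ fixture."""
    tmt = cfg["simulate"]["tmt"]
    brain_cfg = cfg["simulate"]["brain"]

    # planted effects: the whole matrisome-like brain module (up), the rest random
    ppm = brain_cfg["proteins_per_module"]
    n_eff = tmt["n_effect_proteins"]
    n_prot = tmt["n_proteins"]
    rng = np.random.default_rng([_EFFECT_PICK_STAGE, int(seed)])
    matrisome = list(range(min(ppm, n_eff, n_prot)))
    pool = np.setdiff1d(np.arange(n_prot), matrisome)
    extra = np.sort(rng.choice(pool, size=n_eff - len(matrisome), replace=False))
    signs_extra = np.ones(len(extra))
    signs_extra[: len(extra) // 2] = -1.0
    effect_indices = np.concatenate([matrisome, extra]).astype(int)
    effect_signs = np.concatenate([np.ones(len(matrisome)), rng.permutation(signs_extra)])

    raw, sheet, traits, truth = simulate_tmt_plasma(
        n_sets=len(tmt["set_labels"]),
        batches_per_set=tmt["batches_per_set"],
        channels_per_batch=tmt["channels_per_batch"],
        n_proteins=n_prot,
        n_effect_proteins=n_eff,
        delta_log2=tmt["delta_log2"],
        sigma_batch=tmt["sigma_batch"],
        sigma_channel=tmt["sigma_channel"],
        sigma_noise=tmt["sigma_noise"],
        missing_steepness=tmt["missing_steepness"],
        seed=seed,
        missing_rate=tmt["missing_rate"],
        ad_fraction=tmt["ad_fraction"],
        set_labels=tmt["set_labels"],
        effect_indices=effect_indices,
        effect_signs=effect_signs,
    )
    hio.write_abundance_matrix(raw, _path(out_dir, "sim", "plasma_raw.tsv"))
    hio.write_sample_sheet(sheet, _path(out_dir, "sim", "sample_sheet.tsv"))
    hio.write_trait_table(traits, _path(out_dir, "sim", "traits.tsv"))
    effects = truth.effect_sizes[truth.effect_sizes != 0]
    hio.write_table(effects.rename("delta_log2").to_frame(), _path(out_dir, "sim", "truth_effects.tsv"))

    brain, ref, brain_traits, brain_truth = simulate_reference_brain(
        n_modules=brain_cfg["n_modules"],
        proteins_per_module=ppm,
        n_samples=brain_cfg["n_samples"],
        kme_target=brain_cfg["kme_target"],
        n_grey=brain_cfg["n_grey"],
        seed=seed,
    )
    hio.write_abundance_matrix(brain, _path(out_dir, "sim", "brain_log2.tsv"))
    hio.write_network_reference(
        ref,
        _path(out_dir, "sim", "brain_membership.tsv"),
        _path(out_dir, "sim", "brain_eigenproteins.tsv"),
    )
    hio.write_table(brain_traits.rename_axis("sample_id"), _path(out_dir, "sim", "brain_traits.tsv"))

    lfq_cfg = cfg["simulate"]["lfq"]
    lfq, _ = simulate_lfq_fractions(
        n_proteins=lfq_cfg["n_proteins"],
        n_hbp=lfq_cfg["n_hbp"],
        n_abundant=lfq_cfg["n_abundant"],
        enrich_fold=lfq_cfg["enrich_fold"],
        deplete_fold=lfq_cfg["deplete_fold"],
        seed=seed,
    )
    hio.write_abundance_matrix(lfq, _path(out_dir, "sim", "lfq_raw.tsv"))

    gs_cfg = cfg["simulate"]["gene_sets"]
    up_symbols = gene_symbols(effects.index[effects > 0])
    gmt = simulate_gene_sets(
        raw.symbols, up_symbols, gs_cfg["n_random_sets"], gs_cfg["set_size"], seed
    )
    hio.write_gmt(gmt, _path(out_dir, "sim", "gene_sets.gmt"))

    ct_cfg = cfg["simulate"]["celltypes"]
    markers = simulate_celltype_markers(
        ref, ct_cfg["n_celltypes"], ct_cfg["markers_per_type"], seed
    )
    hio.write_marker_lists(markers, _path(out_dir, "sim", "celltype_markers.tsv"))

    counts = {
        "plasma_proteins": int(raw.data.shape[0]),
        "plasma_samples": int(raw.data.shape[1]),
        "planted_effects": int(len(effects)),
        "brain_proteins": int(brain.data.shape[0]),
        "brain_modules": len(ref.module_ids),
    }
    _update_manifest(out_dir, cfg, seed, "simulate", counts)
    return counts


def _set_labels(cfg):
    return list(cfg["simulate"]["tmt"]["set_labels"])


def preprocess_set(raw: AbundanceMatrix, sheet, cfg, seed, set_label) -> AbundanceMatrix:
    """The full TMT variance-correction chain for one sample set."""
    prep = cfg["preprocess"]
    sub_sheet = sheet.subset(sheet.data.index[sheet.data["set_label"] == set_label])
    sub = AbundanceMatrix(raw.data[list(sub_sheet.sample_ids)].copy(), raw.scale)
    normalized = channel_sum_normalize(sub)
    filtered = filter_missingness(normalized, prep["max_missing_frac"])
    t_cfg = prep["tampor"]
    corrected = tampor(
        filtered,
        sub_sheet,
        TamporOptions(
            denominator=t_cfg["denominator"],
            max_iter=t_cfg["max_iter"],
            tol=t_cfg["tol"],
            output_scale="log2",
        ),
    )
    r_cfg = prep["regression"]
    return bootstrap_covariate_regress(
        corrected,
        sub_sheet,
        covariates=r_cfg["covariates"],
        protect=r_cfg["protect"],
        n_boot=r_cfg["n_boot"],
        seed=seed,
    )


def run_preprocess(cfg, seed, out_dir) -> dict:
    raw = hio.read_abundance_matrix(_path(out_dir, "sim", "plasma_raw.tsv"), "raw")
    sheet = hio.read_sample_sheet(_path(out_dir, "sim", "sample_sheet.tsv"))
    counts = {}
    for set_label in _set_labels(cfg):
        corrected = preprocess_set(raw, sheet, cfg, seed, set_label)
        hio.write_abundance_matrix(corrected, _path(out_dir, "prep", f"corrected_{set_label}.tsv"))
        counts[set_label] = {
            "proteins": int(corrected.data.shape[0]),
            "samples": int(corrected.data.shape[1]),
        }
    _update_manifest(out_dir, cfg, seed, "preprocess", counts)
    return counts


def _diagnosis_groups(sheet, sample_ids):
    sub = sheet.data.loc[[s for s in sample_ids if s in sheet.data.index]]
    sub = sub[~sub["is_gis"] & sub["diagnosis"].isin(["Control", "AD"])]
    return {sid: diag for sid, diag in sub["diagnosis"].items()}


def run_diff(cfg, seed, out_dir) -> dict:
    sheet = hio.read_sample_sheet(_path(out_dir, "sim", "sample_sheet.tsv"))
    alpha = cfg["differential"]["alpha"]
    counts = {}
    for set_label in _set_labels(cfg):
        corrected = hio.read_abundance_matrix(
            _path(out_dir, "prep", f"corrected_{set_label}.tsv"), "log2"
        )
        groups = _diagnosis_groups(sheet, corrected.sample_ids)
        table = student_ttest_table(
            corrected, groups, min_per_group=cfg["differential"]["min_per_group"], alpha=alpha
        )
        hio.write_table(table, _path(out_dir, "diff", f"diff_{set_label}.tsv"))
        up, down = threshold_filter(table, p_max=alpha)
        for name, ids in (("up", up), ("down", down)):
            with open(_path(out_dir, "diff", f"{set_label}_{name}.txt"), "w") as fh:
                fh.write("\n".join(ids) + ("\n" if ids else ""))
        # supervised clustering of samples on the most significant proteins
        q_max = cfg["differential"]["cluster_q_max"]
        keep = list(groups)
        sub = AbundanceMatrix(corrected.data[keep], "log2")
        complete = sub.data.notna().all(axis=1)
        top = table.index[(table["q_value"] < q_max) & complete]
        n_clustered = 0
        if len(top) >= 1 and len(keep) >= 2:
            order, heights = supervised_clustering(sub, top)
            cluster = pd.DataFrame(
                {
                    "sample_id": order,
                    "diagnosis": [groups[s] for s in order],
                    "merge_height": list(heights) + [np.nan] * (len(order) - len(heights)),
                }
            )
            hio.write_table(cluster, _path(out_dir, "diff", f"{set_label}_clustering.tsv"), index=False)
            n_clustered = len(top)
        counts[set_label] = {
            "tested": int(table["p_value"].notna().sum()),
            "up": len(up),
            "down": len(down),
            "clustered_proteins": n_clustered,
        }
    _update_manifest(out_dir, cfg, seed, "diff", counts)
    return counts


def run_meta(cfg, seed, out_dir) -> dict:
    sheet = hio.read_sample_sheet(_path(out_dir, "sim", "sample_sheet.tsv"))
    traits = hio.read_trait_table(_path(out_dir, "sim", "traits.tsv"))
    inc = cfg["inclusion"]
    included = hmeta.sample_inclusion_filter(
        sheet,
        traits,
        ratio_thresh=inc["ratio_thresh"],
        moca_ad_max=inc["moca_ad_max"],
        moca_ctl_min=inc["moca_ctl_min"],
        exempt=inc["exempt"],
    )
    hio.write_sample_sheet(included, _path(out_dir, "meta", "included_samples.tsv"))

    per_set = []
    for set_label in _set_labels(cfg):
        corrected = hio.read_abundance_matrix(
            _path(out_dir, "prep", f"corrected_{set_label}.tsv"), "log2"
        )
        keep = [s for s in corrected.sample_ids if s in included.sample_ids]
        sub = AbundanceMatrix(corrected.data[keep], "log2")
        groups = _diagnosis_groups(included, keep)
        per_set.append(
            student_ttest_table(sub, groups, min_per_group=cfg["differential"]["min_per_group"])
        )
    table = hmeta.meta_table(per_set[0], per_set[1])
    hio.write_table(table, _path(out_dir, "meta", "meta.tsv"))
    counts = {
        "included_samples": int((~included.data["is_gis"]).sum()),
        "proteins": int(len(table)),
        "meta_up": int(((table["meta_p"] < 0.05) & (table["mean_log2fc"] > 0)).sum()),
        "meta_down": int(((table["meta_p"] < 0.05) & (table["mean_log2fc"] < 0)).sum()),
    }
    _update_manifest(out_dir, cfg, seed, "meta", counts)
    return counts


def _pooled_corrected(cfg, out_dir, included) -> AbundanceMatrix:
    frames = []
    for set_label in _set_labels(cfg):
        corrected = hio.read_abundance_matrix(
            _path(out_dir, "prep", f"corrected_{set_label}.tsv"), "log2"
        )
        keep = [
            s
            for s in corrected.sample_ids
            if s in included.sample_ids and not included.data.loc[s, "is_gis"]
        ]
        frames.append(corrected.data[keep])
    pooled = pd.concat(frames, axis=1)
    return AbundanceMatrix(pooled, "log2")


def run_traits(cfg, seed, out_dir) -> dict:
    traits = hio.read_trait_table(_path(out_dir, "sim", "traits.tsv"))
    included = hio.read_sample_sheet(_path(out_dir, "meta", "included_samples.tsv"))
    pooled = _pooled_corrected(cfg, out_dir, included)
    # z-scoring needs >= 2 observed values and non-degenerate variance per row
    obs = pooled.data.notna().sum(axis=1)
    sd = pooled.data.std(axis=1, ddof=1)
    usable = (obs >= 2) & (sd > 0)
    z = hmeta.zscore_rows(AbundanceMatrix(pooled.data.loc[usable], "log2"))
    hio.write_abundance_matrix(z, _path(out_dir, "traits", "zscores.tsv"))
    correlations = hmeta.trait_correlation_table(z, traits)
    flat = correlations.copy()
    flat.columns = [f"{trait}.{stat}" for trait, stat in correlations.columns]
    hio.write_table(flat, _path(out_dir, "traits", "trait_correlations.tsv"))
    t_cfg = cfg["traits"]
    selected = hmeta.select_multitrait_proteins(
        correlations, min_significant=t_cfg["min_significant"], alpha=t_cfg["alpha"]
    )
    with open(_path(out_dir, "traits", "multitrait_proteins.txt"), "w") as fh:
        fh.write("\n".join(selected) + ("\n" if selected else ""))
    counts = {"zscored_proteins": int(len(z.data)), "multitrait_proteins": len(selected)}
    _update_manifest(out_dir, cfg, seed, "traits", counts)
    return counts


def run_netmap(cfg, seed, out_dir) -> dict:
    ref = hio.read_network_reference(
        _path(out_dir, "sim", "brain_membership.tsv"),
        _path(out_dir, "sim", "brain_eigenproteins.tsv"),
    )
    brain = hio.read_abundance_matrix(_path(out_dir, "sim", "brain_log2.tsv"), "log2")
    brain_traits = pd.read_csv(
        _path(out_dir, "sim", "brain_traits.tsv"), sep="\t", index_col=0, na_values=["", "NA"]
    )
    kme_min = cfg["netmap"]["kme_min"]

    # re-assignment of the brain proteome to its own network
    brain_assign = hnet.assign_to_modules(brain, ref, kme_min=kme_min, mode="shared")
    hio.write_table(brain_assign, _path(out_dir, "netmap", "brain_assignments.tsv"))

    # projection of the plasma proteome onto the brain network (across tissues)
    included = hio.read_sample_sheet(_path(out_dir, "meta", "included_samples.tsv"))
    pooled = _pooled_corrected(cfg, out_dir, included)
    plasma_assign = hnet.assign_to_modules(pooled, ref, kme_min=kme_min, mode=cfg["netmap"]["mode"])
    hio.write_table(plasma_assign, _path(out_dir, "netmap", "plasma_assignments.tsv"))

    mt = hnet.module_trait_bicor(ref.eigenproteins, brain_traits)
    flat = mt.copy()
    flat.columns = [f"{trait}.{stat}" for trait, stat in mt.columns]
    hio.write_table(flat, _path(out_dir, "netmap", "module_trait_bicor.tsv"))

    # overrepresentation of differentially abundant plasma proteins in modules
    meta_tbl = pd.read_csv(
        _path(out_dir, "meta", "meta.tsv"), sep="\t", index_col=0, na_values=["", "NA"]
    )
    de_alpha = cfg["netmap"]["de_alpha"]
    background = set(gene_symbols(ref.membership.index))
    sig = meta_tbl["meta_p"] < de_alpha
    up = set(gene_symbols(meta_tbl.index[sig & (meta_tbl["mean_log2fc"] > 0)])) & background
    down = set(gene_symbols(meta_tbl.index[sig & (meta_tbl["mean_log2fc"] < 0)])) & background
    overlap = hnet.module_overlap_fet(up, down, ref, background)
    hio.write_table(overlap, _path(out_dir, "netmap", "module_overlap.tsv"))

    markers = hio.read_marker_lists(_path(out_dir, "sim", "celltype_markers.tsv"))
    ct = hnet.celltype_fet(ref, markers, background)
    hio.write_table(ct, _path(out_dir, "netmap", "celltype_enrichment.tsv"), index=False)

    correct = (
        brain_assign["assigned_module"].to_numpy()
        == ref.membership.reindex(brain_assign.index).to_numpy()
    )
    counts = {
        "brain_correctly_assigned": int(correct.sum()),
        "plasma_assigned_nongrey": int((plasma_assign["assigned_module"] != "grey").sum()),
        "modules_overlap_sig": int((overlap["q_bh"] < 0.05).sum()),
    }
    _update_manifest(out_dir, cfg, seed, "netmap", counts)
    return counts


def run_enrich(cfg, seed, out_dir) -> dict:
    gmt = hio.read_gmt(_path(out_dir, "sim", "gene_sets.gmt"))
    meta_tbl = pd.read_csv(
        _path(out_dir, "meta", "meta.tsv"), sep="\t", index_col=0, na_values=["", "NA"]
    )
    background = sorted(set(gene_symbols(meta_tbl.index)))
    e_cfg = cfg["enrichment"]
    counts = {}
    for direction, mask in (
        ("up", (meta_tbl["meta_p"] < 0.05) & (meta_tbl["mean_log2fc"] > 0)),
        ("down", (meta_tbl["meta_p"] < 0.05) & (meta_tbl["mean_log2fc"] < 0)),
    ):
        fg = sorted(set(gene_symbols(meta_tbl.index[mask])))
        table = go_fet(
            fg,
            background,
            gmt,
            min_genes=e_cfg["min_genes"],
            z_min=e_cfg["z_min"],
            q_max=e_cfg["q_max"],
            min_size_on=e_cfg["min_size_on"],
        )
        hio.write_table(table, _path(out_dir, "enrich", f"go_{direction}.tsv"))
        counts[direction] = {"tested_sets": int(len(table)), "passing": int(table["passes_filter"].sum()) if len(table) else 0}
    _update_manifest(out_dir, cfg, seed, "enrich", counts)
    return counts


STAGES = (
    ("simulate", run_simulate),
    ("preprocess", run_preprocess),
    ("diff", run_diff),
    ("meta", run_meta),
    ("traits", run_traits),
    ("netmap", run_netmap),
    ("enrich", run_enrich),
)


def run_all(cfg, seed, out_dir) -> dict:
    results = {}
    for name, stage in STAGES:
        results[name] = stage(cfg, seed, out_dir)
    return results
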