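"""Synthetic study generators with known ground truth.

Three generators mirror the data the pipeline consumes:

* ``simulate_tmt_plasma`` — a multi-batch, multi-set TMT plasma study with one
  pooled global-internal-standard (GIS) channel per batch, multiplicative
  batch and channel-loading effects, planted AD vs Control log2 effects on a
  subset of proteins, abundance-dependent missingness, and biomarker traits
  driven by a latent disease severity.
* ``simulate_reference_brain`` — a modular co-expression "brain" dataset with
  known module membership, latent eigenproteins and module-driven
  clinicopathological traits, used as the projection target.
* ``simulate_lfq_fractions`` — heparin-fractionation triplicates (input,
  flow-through, heparin-enriched) with planted enrichment/depletion folds.

All randomness flows from a single integer seed; each generator derives its
own stream via a fixed stage offset so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GREY, AbundanceMatrix, GeneSetCollection, NetworkReference, SampleSheet, TraitTable

# fixed stage offsets for deriving per-stage generator streams
_STAGE_TMT = 1
_STAGE_BRAIN = 2
_STAGE_LFQ = 3
_STAGE_GENESETS = 4
_STAGE_CELLTYPES = 5


def _rng(seed: int, stage: int) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is required")
    return np.random.default_rng([int(stage), int(seed)])


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator.

    ``effect_sizes`` holds the true AD - Control log2 difference per protein
    (0 off the planted list); ``batch_effects`` the per-(set:batch, protein)
    log2 offsets; ``channel_loadings`` per-sample log2 loadings;
    ``severity`` the latent disease severity per sample; ``true_membership``
    and ``true_kme`` the planted network structure; ``latents`` the module
    latent profiles the eigenproteins should recover.
    """

    effect_sizes: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    batch_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    channel_loadings: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    true_membership: pd.Series = field(default_factory=lambda: pd.Series(dtype="string"))
    true_kme: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    severity: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    latents: pd.DataFrame = field(default_factory=pd.DataFrame)


def _as_per_set(value, n_sets: int, name: str) -> list:
    if np.isscalar(value):
        return [int(value)] * n_sets
    value = [int(v) for v in value]
    if len(value) != n_sets:
        raise ValueError(f"{name} must be a scalar or have length n_sets={n_sets}")
    return value


def protein_id(i: int, prefix: str = "P") -> str:
    """Deterministic protein id; gene symbols are shared across generators."""
    return f"{prefix}{i:05d}|GENE{i:05d}"


def simulate_tmt_plasma(
    n_sets: int,
    batches_per_set,
    channels_per_batch,
    n_proteins: int,
    n_effect_proteins: int,
    delta_log2: float,
    sigma_batch: float,
    sigma_channel: float,
    sigma_noise: float,
    missing_steepness: float,
    seed: int,
    *,
    missing_rate: float = 0.15,
    ad_fraction: float = 0.5,
    set_labels=None,
    effect_indices=None,
    effect_signs=None,
    base_mean: float = 10.0,
    base_sd: float = 3.0,
):
    """Simulate a raw TMT plasma study.

    Observed raw abundance is ``2 ** (base_i + delta_i * I(AD) + gamma_{set,b,i}
    + lambda_j + eps_ij)`` with ``eps ~ N(0, sigma_noise)``.  GIS channels are
    the noiseless per-batch readout of a fixed virtual pool (no diagnosis
    effect, no measurement noise beyond the batch/channel terms), which makes
    internal-standard-based batch correction exactly testable.  Missingness
    hits non-GIS channels with probability that falls logistically with the
    within-sample abundance rank (steepness 0 = missing completely at random).

    Planted effects carry random balanced signs of magnitude ``delta_log2``
    unless explicit ``effect_indices``/``effect_signs`` are given.

    Returns ``(raw AbundanceMatrix, SampleSheet, TraitTable, SyntheticTruth)``.
    """
    for name, val in [("sigma_batch", sigma_batch), ("sigma_channel", sigma_channel), ("sigma_noise", sigma_noise)]:
        if val < 0:
            raise ValueError(f"{name} must be non-negative")
    if n_effect_proteins > n_proteins:
        raise ValueError("n_effect_proteins cannot exceed n_proteins")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = _rng(seed, _STAGE_TMT)

    batches_per_set = _as_per_set(batches_per_set, n_sets, "batches_per_set")
    channels = _as_per_set(channels_per_batch, n_sets, "channels_per_batch")
    if min(channels) < 3:
        raise ValueError("channels_per_batch must be >= 3 (one GIS + two groups)")
    if set_labels is None:
        set_labels = [f"Set{s + 1}" for s in range(n_sets)]

    proteins = pd.Index([protein_id(i) for i in range(n_proteins)])
    base = rng.normal(base_mean, base_sd, size=n_proteins)

    # planted effects: balanced random signs unless caller pins them
    delta = np.zeros(n_proteins)
    if effect_indices is None:
        effect_indices = np.sort(rng.choice(n_proteins, size=n_effect_proteins, replace=False))
    else:
        effect_indices = np.asarray(list(effect_indices), dtype=int)
        if len(effect_indices) != n_effect_proteins:
            raise ValueError("effect_indices length must equal n_effect_proteins")
    if effect_signs is None:
        signs = np.ones(len(effect_indices))
        signs[: len(signs) // 2] = -1.0
        signs = rng.permutation(signs)
    else:
        signs = np.asarray(list(effect_signs), dtype=float)
    delta[effect_indices] = signs * delta_log2

    sheet_rows = []
    columns: list[str] = []
    col_log2: list[np.ndarray] = []
    gamma_cols: dict[str, np.ndarray] = {}
    lam_all: dict[str, float] = {}
    sev_all: dict[str, float] = {}

    for s, set_label in enumerate(set_labels):
        n_batches = batches_per_set[s]
        # per-protein batch offsets, centred to zero mean across the set's batches
        gamma = rng.normal(0.0, sigma_batch, size=(n_batches, n_proteins)) if sigma_batch > 0 else np.zeros((n_batches, n_proteins))
        if n_batches > 1:
            gamma -= gamma.mean(axis=0, keepdims=True)
        else:
            gamma[:] = 0.0
        for b in range(n_batches):
            batch_label = f"{set_label}.b{b + 1}"
            gamma_cols[batch_label] = gamma[b]
            for c in range(channels[s]):
                is_gis = c == 0
                sid = f"{set_label}.b{b + 1}.{'GIS' if is_gis else f'c{c:02d}'}"
                lam = rng.normal(0.0, sigma_channel) if sigma_channel > 0 else 0.0
                lam_all[sid] = lam
                if is_gis:
                    diagnosis = None
                    values = base + gamma[b] + lam
                else:
                    is_ad = rng.random() < ad_fraction
                    diagnosis = "AD" if is_ad else "Control"
                    sev = rng.normal(0.0, 1.0) + (1.0 if is_ad else 0.0)
                    sev_all[sid] = sev
                    eps = rng.normal(0.0, sigma_noise, size=n_proteins) if sigma_noise > 0 else 0.0
                    values = base + delta * (1.0 if is_ad else 0.0) + gamma[b] + lam + eps
                sheet_rows.append(
                    {
                        "sample_id": sid,
                        "set_label": set_label,
                        "batch_label": batch_label,
                        "channel_label": f"ch{c + 1:02d}",
                        "is_gis": is_gis,
                        "diagnosis": diagnosis,
                        "age": float(np.round(rng.normal(70.0, 8.0), 1)),
                        "sex": "F" if rng.random() < 0.5 else "M",
                    }
                )
                columns.append(sid)
                col_log2.append(values)

    log2 = np.column_stack(col_log2)
    sheet = SampleSheet(pd.DataFrame(sheet_rows))

    # abundance-rank-dependent missingness on non-GIS channels only
    if missing_rate > 0:
        gis_mask = sheet.data["is_gis"].reindex(columns).to_numpy()
        for j in range(log2.shape[1]):
            if gis_mask[j]:
                continue
            ranks = (np.argsort(np.argsort(log2[:, j])) + 0.5) / n_proteins
            with np.errstate(over="ignore"):
                p_miss = 2.0 * missing_rate / (1.0 + np.exp(missing_steepness * (ranks - 0.5)))
            p_miss = np.clip(p_miss, 0.0, 1.0)
            drop = rng.random(n_proteins) < p_miss
            log2[drop, j] = np.nan

    raw = AbundanceMatrix(pd.DataFrame(np.exp2(log2), index=proteins, columns=columns), "raw")

    traits = _plasma_traits(sev_all, rng)
    truth = SyntheticTruth(
        effect_sizes=pd.Series(delta, index=proteins),
        batch_effects=pd.DataFrame(gamma_cols, index=proteins),
        channel_loadings=pd.Series(lam_all),
        severity=pd.Series(sev_all),
    )
    return raw, sheet, traits, truth


def _plasma_traits(severity: dict, rng: np.random.Generator) -> TraitTable:
    """Biomarker traits as monotone functions of latent severity.

    Intercepts/slopes are calibrated so that the published tTau/Abeta ratio
    threshold (0.226) separates the simulated groups the way the clinical
    assays do: controls sit near 0.15, AD near 0.37.
    """
    sids = list(severity)
    sev = np.array([severity[s] for s in sids])
    n = len(sids)
    moca = np.clip(28.0 - 6.0 * sev + rng.normal(0, 1.5, n), 0.0, 30.0)
    abeta = np.maximum(1200.0 - 300.0 * sev + rng.normal(0, 100.0, n), 100.0)
    ttau = np.maximum(180.0 + 150.0 * sev + rng.normal(0, 40.0, n), 20.0)
    ptau = np.maximum(18.0 + 15.0 * sev + rng.normal(0, 4.0, n), 1.0)
    plasma_ptau = np.maximum(2.0 + 1.2 * sev + rng.normal(0, 0.4, n), 0.05)
    df = pd.DataFrame(
        {
            "MoCA": moca,
            "CSF_Abeta42": abeta,
            "CSF_tTau": ttau,
            "CSF_pTau181": ptau,
            "tTau_Abeta_ratio": ttau / abeta,
            "plasma_pTau181": plasma_ptau,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    return TraitTable(df)


def simulate_reference_brain(
    n_modules: int,
    proteins_per_module: int,
    n_samples: int,
    kme_target: float,
    n_grey: int,
    seed: int,
    *,
    matrisome_module: str = "M1",
):
    """Simulate a modular reference proteome and its network.

    Per module a standardized latent profile ``e_m`` is drawn; each member row
    is ``kme_target * e_m + sqrt(1 - kme_target^2) * noise`` (plus a
    per-protein baseline), so member-eigenprotein correlation targets
    ``kme_target``.  Grey proteins are pure noise.  Clinicopathological traits
    (CERAD- , Braak- and MMSE-like) are linear functions of the designated
    matrisome-like module's latent plus noise.

    Returns ``(log2 AbundanceMatrix, NetworkReference, brain-trait DataFrame,
    SyntheticTruth)``.
    """
    if not 0.0 < kme_target < 1.0:
        raise ValueError("kme_target must be in (0, 1)")
    rng = _rng(seed, _STAGE_BRAIN)
    samples = pd.Index([f"BRN{j:03d}" for j in range(n_samples)])
    module_ids = [f"M{m + 1}" for m in range(n_modules)]
    if matrisome_module not in module_ids:
        raise ValueError(f"matrisome_module {matrisome_module!r} not among module ids")

    latents = rng.normal(size=(n_modules, n_samples))
    latents = (latents - latents.mean(axis=1, keepdims=True)) / latents.std(axis=1, ddof=1, keepdims=True)

    n_total = n_modules * proteins_per_module + n_grey
    proteins = pd.Index([protein_id(i, prefix="B") for i in range(n_total)])
    base = rng.normal(10.0, 1.0, size=n_total)
    rows = np.empty((n_total, n_samples))
    membership = []
    kme_true = np.zeros(n_total)
    idx = 0
    for m, mid in enumerate(module_ids):
        for _ in range(proteins_per_module):
            noise = rng.normal(size=n_samples)
            rows[idx] = base[idx] + kme_target * latents[m] + np.sqrt(1.0 - kme_target**2) * noise
            membership.append(mid)
            kme_true[idx] = kme_target
            idx += 1
    for _ in range(n_grey):
        rows[idx] = base[idx] + rng.normal(size=n_samples)
        membership.append(GREY)
        idx += 1

    matrix = AbundanceMatrix(pd.DataFrame(rows, index=proteins, columns=samples), "log2")
    eig = pd.DataFrame(latents, index=module_ids, columns=samples)
    ref = NetworkReference(
        pd.Series(membership, index=proteins),
        eig,
        module_labels={matrisome_module: "matrisome-like"},
    )

    e = eig.loc[matrisome_module].to_numpy()
    brain_traits = pd.DataFrame(
        {
            "CERAD": np.clip(1.5 + 0.9 * e + rng.normal(0, 0.4, n_samples), 0.0, 3.0),
            "Braak": np.clip(3.0 + 1.8 * e + rng.normal(0, 0.8, n_samples), 0.0, 6.0),
            "MMSE": np.clip(20.0 - 6.0 * e + rng.normal(0, 2.0, n_samples), 0.0, 30.0),
        },
        index=samples,
    )
    truth = SyntheticTruth(
        true_membership=pd.Series(membership, index=proteins, dtype="string"),
        true_kme=pd.Series(kme_true, index=proteins),
        latents=eig.copy(),
    )
    return matrix, ref, brain_traits, truth


def simulate_lfq_fractions(
    n_proteins: int,
    n_hbp: int,
    n_abundant: int,
    enrich_fold: float,
    deplete_fold: float,
    seed: int,
    *,
    sigma_noise: float = 0.15,
    missing_low_frac: float = 0.15,
):
    """Simulate heparin-fractionation triplicates (DP input, FT, HP-enriched).

    Designated heparin-binding-like proteins are multiplied by
    ``enrich_fold`` and designated high-abundance proteins divided by
    ``deplete_fold`` in the HP columns.  A fraction of low-abundance proteins
    is set missing in DP/FT only (fraction-unique detections).  Zeros are
    never emitted.
    """
    if enrich_fold <= 1 or deplete_fold <= 1:
        raise ValueError("enrich_fold and deplete_fold must be > 1")
    if n_hbp + n_abundant > n_proteins:
        raise ValueError("n_hbp + n_abundant cannot exceed n_proteins")
    rng = _rng(seed, _STAGE_LFQ)
    proteins = pd.Index([protein_id(i, prefix="L") for i in range(n_proteins)])
    columns = [f"{frac}{r}" for frac in ("DP", "FT", "HP") for r in (1, 2, 3)]

    base = rng.normal(8.0, 3.0, size=n_proteins)
    roles = np.array(["bulk"] * n_proteins, dtype=object)
    abundant_idx = rng.choice(n_proteins, size=n_abundant, replace=False)
    base[abundant_idx] += 8.0  # high-abundance proteins dominate the input
    roles[abundant_idx] = "abundant"
    remaining = np.setdiff1d(np.arange(n_proteins), abundant_idx)
    hbp_idx = rng.choice(remaining, size=n_hbp, replace=False)
    roles[hbp_idx] = "hbp"

    shift = np.zeros(n_proteins)
    shift[hbp_idx] = np.log2(enrich_fold)
    shift[abundant_idx] = -np.log2(deplete_fold)

    log2 = np.empty((n_proteins, 9))
    for j, col in enumerate(columns):
        eps = rng.normal(0.0, sigma_noise, size=n_proteins) if sigma_noise > 0 else 0.0
        log2[:, j] = base + (shift if col.startswith("HP") else 0.0) + eps

    # fraction-unique detections: low-abundance proteins absent from DP/FT
    low = np.argsort(base)[: max(1, n_proteins // 3)]
    drop = low[rng.random(len(low)) < missing_low_frac]
    log2[np.ix_(drop, [j for j, c in enumerate(columns) if not c.startswith("HP")])] = np.nan

    matrix = AbundanceMatrix(pd.DataFrame(np.exp2(log2), index=proteins, columns=columns), "raw")
    truth = SyntheticTruth(
        effect_sizes=pd.Series(shift, index=proteins),
        true_membership=pd.Series(roles, index=proteins, dtype="string"),
    )
    return matrix, truth


def simulate_gene_sets(
    universe_symbols,
    planted_symbols,
    n_random_sets: int = 20,
    set_size: int = 40,
    seed: int = 0,
) -> GeneSetCollection:
    """A GMT-style collection: one set holding the planted-effect symbols plus
    random sets drawn from the symbol universe."""
    rng = _rng(seed, _STAGE_GENESETS)
    universe = list(dict.fromkeys(s.upper() for s in universe_symbols))
    planted = [s.upper() for s in planted_symbols]
    collection = GeneSetCollection()
    if planted:
        collection.add("PLANTED_EFFECT", "planted differential-abundance proteins", planted)
    for k in range(n_random_sets):
        members = rng.choice(universe, size=min(set_size, len(universe)), replace=False)
        collection.add(f"RANDOM_{k + 1:02d}", "random background set", list(members))
    return collection


def simulate_celltype_markers(
    ref: NetworkReference,
    n_celltypes: int = 5,
    markers_per_type: int = 50,
    seed: int = 0,
    *,
    module_fraction: float = 0.8,
) -> dict:
    """Cell-type marker lists seeded from reference modules.

    Each cell type draws ``module_fraction`` of its markers from one module's
    member symbols and the rest from the whole reference, so the planted
    module is the type's strongest enrichment.
    """
    rng = _rng(seed, _STAGE_CELLTYPES)
    names = ["astrocyte", "microglia", "neuron", "oligodendrocyte", "endothelia"]
    all_symbols = np.array(sorted(set(ref.membership_by_symbol().index)))
    markers = {}
    for t in range(n_celltypes):
        name = names[t] if t < len(names) else f"celltype{t + 1}"
        module = ref.module_ids[t % len(ref.module_ids)]
        members = np.array(sorted(set(ref.module_symbols(module))))
        n_mod = min(int(round(module_fraction * markers_per_type)), len(members))
        picked = list(rng.choice(members, size=n_mod, replace=False))
        pool = np.setdiff1d(all_symbols, picked)
        n_rand = min(markers_per_type - n_mod, len(pool))
        picked += list(rng.choice(pool, size=n_rand, replace=False))
        markers[name] = picked
    return markers
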