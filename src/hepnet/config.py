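"""Declarative pipeline configuration.

A single nested key/value mapping drives every stage; ``DEFAULTS`` carries the
study conditions and the published thresholds (50% missingness, kME 0.30,
tTau/Abeta ratio 0.226, MoCA 24/26, Z 1.96, 5 minimum genes).  A YAML file
passed on the command line is deep-merged over the defaults, so a run only
states what it changes.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

DEFAULTS: dict = {
    "simulate": {
        "tmt": {
            # Two independent sample sets: a 3-batch discovery set and a
            # 5-batch replication set, one GIS channel per batch.
            "set_labels": ["Set1", "Set2"],
            "batches_per_set": [3, 5],
            "channels_per_batch": [13, 18],
            "n_proteins": 2000,
            "n_effect_proteins": 200,
            "delta_log2": 1.0,
            "sigma_batch": 0.5,
            "sigma_channel": 0.1,
            "sigma_noise": 0.2,
            "missing_rate": 0.2,
            "missing_steepness": 8.0,
            "ad_fraction": 0.5,
        },
        "brain": {
            "n_modules": 40,
            "proteins_per_module": 25,
            "n_samples": 100,
            "kme_target": 0.6,
            "n_grey": 200,
        },
        "lfq": {
            "n_proteins": 800,
            "n_hbp": 60,
            "n_abundant": 20,
            "enrich_fold": 4.0,
            "deplete_fold": 4.0,
        },
        "gene_sets": {"n_random_sets": 20, "set_size": 40},
        "celltypes": {"n_celltypes": 5, "markers_per_type": 50},
    },
    "preprocess": {
        "max_missing_frac": 0.5,
        "tampor": {
            "denominator": "gis",
            "max_iter": 250,
            "tol": 1e-8,
            "output_scale": "log2",
        },
        "regression": {
            "covariates": ["batch_label"],
            "protect": ["diagnosis"],
            "n_boot": 100,
        },
    },
    "differential": {"alpha": 0.05, "min_per_group": 2, "cluster_q_max": 0.0005},
    "inclusion": {
        "ratio_thresh": 0.226,
        "moca_ad_max": 24.0,
        "moca_ctl_min": 26.0,
        "exempt": [],
    },
    "traits": {"min_significant": 3, "alpha": 0.05},
    "netmap": {"kme_min": 0.30, "mode": "recompute", "de_alpha": 0.05},
    "enrichment": {"min_genes": 5, "z_min": 1.96, "q_max": 0.05, "min_size_on": "overlap"},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def load_config(path=None) -> dict:
    """Defaults, optionally deep-merged with a YAML file."""
    if path is None:
        return default_config()
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _deep_merge(DEFAULTS, override)


def config_hash(config: dict) -> str:
    """Stable sha256 of a config mapping (order-independent)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
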