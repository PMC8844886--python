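"""Run configuration: defaults, YAML round-trip, canonical hashing."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config", "dump_config", "config_hash", "merge_config"]

# Every knob the pipeline exposes, with its default. Stage sections mirror
# the module boundaries; ``simulate`` scales are desk-scale so a full run
# stays interactive.
_DEFAULTS = {
    "seed": 0,
    "stages": ["simulate", "quantify-images", "count-umis", "test-enrichment",
               "estimate-particles"],
    "simulate": {
        "fish": {
            "shape": [16, 160, 192],
            "voxel_size": [0.25, 0.2, 0.2],
            "n_puncta": 60,
            "frac_inside": 0.5,
            "tube_radius_um": 1.5,
            "tube_intensity": 200.0,
            "psf_sigma_um": 0.2,
            "background_mean": 100.0,
            "background_sd": 20.0,
            "snr": 5.0,
        },
        "reads": {
            "n_wells": 8,
            "n_genes": 30,
            "mean_molecules": 40,
            "barcode_sub_rate": 0.002,
            "umi_sub_rate": 0.002,
            "mean_duplication": 3.0,
            "umi_length": 8,
        },
        "counts": {
            "n_genes": 300,
            "n_per_cell": 4,
            "baseline_mean": 100.0,
            "dispersion": 0.1,
            "fraction_effect_log2": 1.0,
            "n_interaction_genes": 30,
            "interaction_log2fc": 2.0,
        },
        "qpcr": {"noise_sd_cq": 0.2},
    },
    "quantify_images": {
        "diameter_range": [0.5, 1.0],
        "n_scales": 3,
        "k_sd": 2.0,
        "null_quantile": 0.999,
    },
    "count_umis": {
        "barcode_length": 8,
        "umi_length": 8,
        "collapse_method": "components",
    },
    "test_enrichment": {
        "full_terms": ["genotype", "fraction", "genotype:fraction"],
        "reduced_terms": ["genotype", "fraction"],
        "min_total_count": 5,
        "fdr": 0.05,
    },
    "estimate_particles": {
        "umi": {"total_umis": 1.0, "sorted_particles": 50.0, "efficiency": 0.01},
        "mass": {
            "total_rna_yield_g": 1.0e-9,
            "sorted_particles": 1.0e8,
            "pct_mrna": 0.01,
            "mean_mrna_length_nt": 2000.0,
        },
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def merge_config(base: dict, override: dict) -> dict:
    """Deep-merge ``override`` into a copy of ``base``."""
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = merge_config(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None) -> dict:
    """Defaults, overridden by a YAML file when given."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = merge_config(cfg, user)
    return cfg


def dump_config(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """SHA-256 over the canonical (sorted-key JSON) form of the config."""
    blob = json.dumps(cfg, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(dump_config(cfg))
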