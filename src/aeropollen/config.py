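"""Declarative run configuration with strict schema checking."""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range values."""


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "outdir": "runs/demo",
    "reference": {
        "n_families": 4,
        "n_genera_per_family": 3,
        "n_species_per_genus": 4,
        "seq_length": 300,
        "extra_global_families": 1,
        "extra_global_species_per_genus": 1,
        "offtarget_clades": ["fungi", "bryophytes", "green_algae"],
        "n_offtarget_species_per_clade": 2,
    },
    "design": {
        "sites": ["West", "SouthEast"],
        "seasons": ["spring", "fall"],
        "n_samples_per_cell": 3,
        "n_replicates": 3,
        "n_pool_species": 20,
        "depth_mean": 5000,
        "error_rate": 0.001,
        "leakage_rate": 0.001,
        "n_contaminants": 2,
        "contaminant_mean_reads": 4.0,
        "microscope_grains": 1000,
        "pollen_m3_scale": 5.0,
        "dirichlet_base_alpha": 0.4,
        "sample_concentration": 60.0,
        "replicate_concentration": 400.0,
        "n_extraction_blanks": 2,
        "n_pcr_negatives": 2,
        "n_positive_controls": 2,
        "family_level_morphotypes": ["Family01"],
    },
    "markers": {
        "trnL-like": {"bias_sd": 0.8, "seq_length": 120},
        "nrITS2-like": {"bias_sd": 0.2, "seq_length": 300},
    },
    "process": {
        "alpha": 2.0,
        "min_abundance": 10,
        "detect_chimeras": False,
        "max_primer_mismatch_frac": 0.2,
    },
    "filter": {
        "min_reads_per_repeat": 10,
        "min_repeat_depth": 3000,
        "min_replicates_present": 2,
        "excluded_clades": ["fungi", "bryophytes", "green_algae"],
        "leakage_denominator": "otu_total",
    },
    "analysis": {
        "combined_min_frac": 0.05,
        "n_target_morphotypes": 3,
        "n_permutations": 999,
        "nmds_starts": 20,
        "nmds_max_iter": 300,
    },
}

_RANGES = {
    ("process", "alpha"): (0.0, 10.0),
    ("process", "min_abundance"): (1, 10**9),
    ("process", "max_primer_mismatch_frac"): (0.0, 0.5),
    ("design", "error_rate"): (0.0, 0.05),
    ("design", "leakage_rate"): (0.0, 1.0),
    ("filter", "min_reads_per_repeat"): (0, 10**9),
    ("filter", "min_repeat_depth"): (0, 10**9),
    ("filter", "min_replicates_present"): (1, 100),
    ("analysis", "combined_min_frac"): (0.0, 1.0),
    ("analysis", "n_permutations"): (1, 10**7),
    ("analysis", "nmds_starts"): (1, 10**4),
}


def _check_keys(user: dict, defaults: dict, path: str = "") -> None:
    for key, value in user.items():
        where = f"{path}{key}"
        if key not in defaults:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict) and path != "markers.":
            if not isinstance(value, dict):
                raise ConfigError(f"{where} must be a mapping")
            if key == "markers":
                for marker, sub in value.items():
                    if not isinstance(sub, dict):
                        raise ConfigError(f"markers.{marker} must be a mapping")
                    for k in sub:
                        if k not in ("bias_sd", "seq_length"):
                            raise ConfigError(
                                f"unknown config key: markers.{marker}.{k}"
                            )
            else:
                _check_keys(value, defaults[key], where + ".")


def _merge(defaults: dict, user: dict) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            if key == "markers":
                out[key] = copy.deepcopy(value)  # markers replace wholesale
            else:
                out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def validate_config(cfg: dict) -> dict:
    """Check keys against the schema and thresholds against ranges."""
    _check_keys(cfg, DEFAULT_CONFIG)
    merged = _merge(DEFAULT_CONFIG, cfg)
    for (section, key), (lo, hi) in _RANGES.items():
        value = merged[section][key]
        if not lo <= value <= hi:
            raise ConfigError(
                f"{section}.{key} = {value!r} outside allowed range [{lo}, {hi}]"
            )
    for marker, sub in merged["markers"].items():
        from aeropollen.amplicon import MARKERS

        if marker not in MARKERS:
            raise ConfigError(f"unknown marker {marker!r}")
        if sub.get("bias_sd", 0.0) < 0:
            raise ConfigError(f"markers.{marker}.bias_sd must be >= 0")
    return merged


def load_config(path: str | Path | None) -> dict:
    """Load YAML config merged over defaults; ``None`` gives defaults."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config root must be a mapping")
    return validate_config(user)
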