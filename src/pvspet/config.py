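"""YAML pipeline configuration with strict key validation."""

from __future__ import annotations

import yaml

__all__ = ["load_config", "validate_config", "DEFAULTS"]

DEFAULTS = {
    "output": None,
    "seed": 0,
    "phantom": {
        "shape": [48, 48, 48],
        "spacing": [1.0, 1.0, 1.0],
        "n_wm_tubes": 12,
        "n_bg_tubes": 4,
        "tube_radius_vox": 1.0,
        "tube_length_vox": 6.0,
        "n_subjects": 10,
    },
    "analysis": {
        "fwhm_mm": 4.0,
        "theta3_min": 0.006,
        "theta3_max": 0.6,
        "n_basis": 64,
        "patlak_t_start": 0.5,
        "vascular_correction": True,
        "pvs_bp_increment": 0.15,
        "vascular_fraction": 0.05,
        "pet_noise_sd": 0.0,
        "dce_noise_sd": 0.0,
        "r1_relaxivity": 3.5,
        "dynamic_flip_deg": 12.0,
        "effect_rho": 0.5,
        "layer_effect_sd": 0.3,
    },
}


def _merge_validate(user, defaults, path=""):
    if not isinstance(user, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    merged = {}
    for key, default in defaults.items():
        sub = f"{path}.{key}" if path else key
        if isinstance(default, dict):
            merged[key] = _merge_validate(user.get(key, {}), default, sub)
        else:
            merged[key] = user.get(key, default)
    for key in user:
        if key not in defaults:
            sub = f"{path}.{key}" if path else key
            raise ValueError(f"invalid config key: {sub!r}")
    return merged


def validate_config(raw: dict) -> dict:
    """Merge a user config over the defaults; reject unknown keys and
    require the output directory."""
    cfg = _merge_validate(raw or {}, DEFAULTS)
    if not cfg["output"]:
        raise ValueError("config is missing the required 'output' key")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)
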