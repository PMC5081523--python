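"""Declarative run configuration: nested key/value YAML with validation.

Every CLI run resolves its configuration against the defaults below,
validates it against the schema (unknown keys and wrong types are errors)
and logs the resolved values together with the RNG seed, so any run can be
reproduced from its log alone.
"""

from __future__ import annotations

import copy
import logging

import yaml

from .errors import FormatError

log = logging.getLogger("chromosteer")

DEFAULTS: dict = {
    "genome": {
        "n_chrom": 2,
        "length_bp": 10_000_000,
        "resolution": 100_000,
        "bead_bp": 3030,
        "nucleus_radius_nm": 4800.0,
    },
    "synthetic": {
        "mu_scale": 100.0,
        "mu_exponent": 1.0,
        "theta": 2.0,
        "pi": 0.4,
        "n_planted": 200,
        "fold": 50.0,
        "min_sep_bp": 200_000,
    },
    "calling": {
        "alpha": 0.01,
        "min_delta": 1,
        "pool_min_n": 50,
        "pool_min_nonzero": 10,
    },
    "builder": {
        "n_loop": 101,
        "petals_per_turn": 12,
        "pitch_per_turn": 2.0,
        "placement_trials": 10_000,
        "compress_tau": 1200.0,
    },
    "dynamics": {
        "dt": 0.012,
        "gamma": 0.5,
        "kappa": 5.0,
        "temperature": 1.0,
        "relax_tau": 120_000.0,
        "steer_tau": 6000.0,
        "extra_steer_tau": 600.0,
        "recondense_tau": 300.0,
        "k_max": 0.1,
        "recondense_k": 1.0,
        "time_scale": 1.0,  # desk-scale multiplier on all durations
    },
    "analysis": {
        "n_shells": 15,
        "cutoffs_nm": [120.0, 240.0, 480.0],
        "d_cap_nm": 750.0,
        "d_fill_nm": 1000.0,
        "mds_alpha": 1.0,
        "n_random_partitions": 1000,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise FormatError(f"unknown config key: {where}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise FormatError(f"config key {where} must be a mapping")
            out[key] = _merge(base[key], val, where)
        else:
            if val is not None and base[key] is not None:
                want = type(base[key])
                if want in (float,) and isinstance(val, int):
                    val = float(val)
                elif want is list and isinstance(val, list):
                    pass
                elif not isinstance(val, want):
                    raise FormatError(
                        f"config key {where}: expected {want.__name__}, "
                        f"got {type(val).__name__}")
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Resolve a config file (optional) + overrides against the defaults."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise FormatError(f"{path}: top level must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def log_resolved(cfg: dict, seed: int) -> None:
    log.info("resolved config:\n%s", yaml.safe_dump(cfg, sort_keys=True))
    log.info("rng seed: %d", seed)
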