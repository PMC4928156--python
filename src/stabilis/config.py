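"""Package-wide configuration with per-module sections.

Every analysis threshold is surfaced here with its documented default:
the 0.2 RSA accessibility cut, the |1| kcal/mol perturbation threshold,
the 5 Å heavy-atom contact cutoff, the 70 % structural-coverage and
3.0 Å resolution dataset filters, and the minimum of 5 disease variants
per protein for interactome binning.  A YAML file with the same section
layout overrides defaults key by key.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import InputError

DEFAULTS: dict = {
    "structure": {
        "probe_radius": 1.4,        # Å, solvent probe
        "n_points": 960,            # Shrake-Rupley sampling points per atom
        "rsa_accessible": 0.2,      # RSA >= threshold -> accessible
    },
    "features": {
        "contact_cutoff": 5.0,      # Å, min heavy-atom distance for a contact
        "exclude_window": 0,        # sequence neighbours to exclude from contacts
    },
    "regression": {
        "C_grid": [1.0, 10.0, 100.0],
        "epsilon_grid": [0.01, 0.1, 0.5],
        "gamma_factors": [0.5, 1.0, 2.0],
        "lopo_max_proteins": 40,    # <= this many proteins -> leave-one-protein-out
        "n_folds": 10,
    },
    "analysis": {
        "perturb_threshold": 1.0,   # kcal/mol on |ddG|
        "min_coverage": 0.70,
        "max_resolution": 3.0,      # Å, strict upper bound
        "abs_ddg_bins": [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0],
        "signed_ddg_bins": [-5.0, -4.5, -4.0, -3.5, -3.0, -2.5, -2.0, -1.5,
                            -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0,
                            3.5, 4.0, 4.5, 5.0],
    },
    "interactome": {
        "min_variants": 5,
        "fraction_bins": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
    },
}


def load_config(path: str | Path | None = None) -> dict:
    """Return the default configuration, optionally overridden from YAML."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is None:
        return cfg
    try:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise InputError(f"cannot read config file {path}: {exc}") from exc
    if not isinstance(user, dict):
        raise InputError(f"config file {path} must contain a mapping")
    for section, values in user.items():
        if section not in cfg:
            raise InputError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise InputError(f"config section {section!r} must be a mapping")
        cfg[section].update(values)
    return cfg
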