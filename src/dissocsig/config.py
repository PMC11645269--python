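"""Run-configuration schema and validation for the pipeline driver.

A run config is a YAML document:

.. code-block:: yaml

    seed: 7
    out_dir: runs/demo
    stages:
      simulate: {n_genes: 1200, cells_per_sample: 250}
      qc: {min_genes_per_cell: 50, min_umis: 100, max_umis: 1.0e9, max_mito_fraction: 0.25}
      normalize: {scale: 10000.0}
      pseudobulk: {classes: [myeloid]}
      de: {comparisons: [[DNC-NONE, ENZ-NONE]], padj_max: 0.05, abs_log2fc_min: 0.58}
      consensus: {direction: up}
      score: {n_bins: 25, ctrl_per_gene: 100}
      calibrate: {n_lists: 1000, tail: 0.025}
      enrich: {cell_class: myeloid}
      correlate: {covariates: [PMI, age]}

Stages execute in the fixed dependency order above; any suffix of the chain
may be omitted. Alternatively ``inputs: {counts_dir: ..., annotations: ...}``
replaces the simulate stage. Unknown keys anywhere are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError

STAGE_ORDER = (
    "simulate",
    "qc",
    "normalize",
    "pseudobulk",
    "de",
    "consensus",
    "score",
    "calibrate",
    "enrich",
    "correlate",
)

# stage -> {param: (type tuple, required)}
_NUM = (int, float)
STAGE_SCHEMA: dict[str, dict[str, tuple[tuple, bool]]] = {
    "simulate": {
        "n_genes": ((int,), False),
        "class_proportions": ((dict,), False),
        "groups": ((list,), False),
        "samples_per_group": ((int,), False),
        "cells_per_sample": ((int,), False),
        "base_mean_log_mu": (_NUM, False),
        "base_mean_log_sd": (_NUM, False),
        "dispersion": (_NUM, False),
        "libsize_factor_sd": (_NUM, False),
        "program_size": ((int,), False),
        "program_log2_effect": (_NUM + (list,), False),
        "program_symbols": ((list,), False),
        "activated_fraction": ((dict,), False),
        "mito_fraction_of_genes": (_NUM, False),
        "mito_mean_scale": (_NUM, False),
        "species": ((str,), False),
    },
    "qc": {
        "min_genes_per_cell": ((int,), True),
        "min_umis": ((int,), True),
        "max_umis": (_NUM, True),
        "max_mito_fraction": (_NUM, True),
        "mito_prefixes": ((list,), False),
    },
    "normalize": {"scale": (_NUM, False)},
    "pseudobulk": {"classes": ((list,), False)},
    "de": {
        "comparisons": ((list,), True),
        "padj_max": (_NUM, False),
        "abs_log2fc_min": (_NUM, False),
    },
    "consensus": {"direction": ((str,), False)},
    "score": {
        "n_bins": ((int,), False),
        "ctrl_per_gene": ((int,), False),
        "signature": ((str,), False),  # path; defaults to the consensus stage output
        "species": ((str,), False),
        "target_species": ((str,), False),
    },
    "calibrate": {
        "n_lists": ((int,), False),
        "tail": (_NUM, False),
        "list_length": ((int,), False),
        "n_bins": ((int,), False),
        "ctrl_per_gene": ((int,), False),
        "n_mads": (_NUM, False),
        "mad_scale": (_NUM, False),
        "downsample": ((bool,), False),
    },
    "enrich": {"cell_class": ((str,), False)},
    "correlate": {"covariates": ((list,), True)},
}

_STAGE_DEPENDS: dict[str, tuple[str, ...]] = {
    "qc": ("simulate|inputs",),
    "normalize": ("qc",),
    "pseudobulk": ("qc",),
    "de": ("pseudobulk",),
    "consensus": ("de",),
    "score": ("normalize",),
    "calibrate": ("normalize",),
    "enrich": ("score", "calibrate"),
    "correlate": ("enrich",),
}


def load_config(path: str | Path) -> dict[str, Any]:
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse config: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def validate_config(cfg: dict[str, Any], base_dir: str | Path = ".") -> list[str]:
    """Schema / range / path / cross-stage consistency check; no computation.

    Returns a human-readable report (one line per check); raises
    :class:`ConfigError` on the first violation.
    """
    report: list[str] = []
    allowed_top = {"seed", "out_dir", "stages", "inputs"}
    for key in cfg:
        if key not in allowed_top:
            raise ConfigError(f"unknown config key {key!r}")
    if not isinstance(cfg.get("seed"), int):
        raise ConfigError("config requires an integer 'seed'")
    if not isinstance(cfg.get("out_dir"), str):
        raise ConfigError("config requires a string 'out_dir'")
    stages = cfg.get("stages")
    if not isinstance(stages, dict) or not stages:
        raise ConfigError("config requires a non-empty 'stages' mapping")
    report.append(f"seed: {cfg['seed']}")

    for name, params in stages.items():
        if name not in STAGE_SCHEMA:
            raise ConfigError(f"unknown stage {name!r}")
        if params is None:
            params = {}
        if not isinstance(params, dict):
            raise ConfigError(f"stage {name!r}: parameters must be a mapping")
        schema = STAGE_SCHEMA[name]
        for key, value in params.items():
            if key not in schema:
                raise ConfigError(f"stage {name!r}: unknown key {key!r}")
            types, _ = schema[key]
            if value is not None and not isinstance(value, types):
                raise ConfigError(
                    f"stage {name!r}: key {key!r} has type {type(value).__name__}, "
                    f"expected one of {[t.__name__ for t in types]}"
                )
        for key, (_, required) in schema.items():
            if required and key not in params:
                raise ConfigError(f"stage {name!r}: missing required key {key!r}")
        report.append(f"stage {name}: ok")

    # range checks
    cal = stages.get("calibrate") or {}
    tail = cal.get("tail", 0.025)
    if not 0.0 < tail < 1.0:
        raise ConfigError(f"stage 'calibrate': tail {tail} outside (0, 1)")
    qc = stages.get("qc") or {}
    if "max_mito_fraction" in qc and not 0.0 <= qc["max_mito_fraction"] <= 1.0:
        raise ConfigError("stage 'qc': max_mito_fraction outside [0, 1]")

    # inputs / dependency consistency
    inputs = cfg.get("inputs")
    have = set(stages)
    if "simulate" not in stages:
        if not isinstance(inputs, dict):
            raise ConfigError(
                "without a 'simulate' stage the config needs 'inputs' with "
                "'counts_dir' and 'annotations'"
            )
        for key in ("counts_dir", "annotations"):
            p = inputs.get(key)
            if not isinstance(p, str):
                raise ConfigError(f"inputs: missing path {key!r}")
            full = Path(base_dir) / p
            if not full.exists():
                raise ConfigError(
                    f"inputs: path {p!r} (needed by stage 'qc') does not exist"
                )
            report.append(f"input {key}: {p}")
        have.add("inputs")
    sig = (stages.get("score") or {}).get("signature")
    if sig is not None:
        if not (Path(base_dir) / sig).exists():
            raise ConfigError(
                f"stage 'score': signature path {sig!r} does not exist"
            )
    elif "score" in stages and "consensus" not in stages:
        raise ConfigError(
            "stage 'score' needs either a 'signature' path or a 'consensus' stage"
        )
    for stage, deps in _STAGE_DEPENDS.items():
        if stage not in stages:
            continue
        for dep in deps:
            options = dep.split("|")
            if not any(o in have for o in options):
                raise ConfigError(
                    f"stage {stage!r} requires stage(s) {' or '.join(options)}"
                )
    report.append("valid")
    return report
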