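"""JSON run configuration: versioned schema, strict validation, manifests.

Unknown keys are errors, not warnings — a silently ignored option is a
reproducibility hazard. Every CLI run echoes the fully defaulted
configuration (including the shipped motion-classifier thresholds, which
are placeholders pending retraining on labelled components) into a manifest
so the run can be repeated bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional

from .correction import SCALING_METHODS, WorkflowOptions
from .regressors import RegressorSpec

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


_WORKFLOW_KEYS = {f.name for f in dataclasses.fields(WorkflowOptions)} - {"regressors"}
_REGRESSOR_KEYS = {f.name for f in dataclasses.fields(RegressorSpec)}
_QC_KEYS = {
    "dice_min",
    "corr_max",
    "variability_dice_min",
    "effect_max",
    "min_n",
    "min_retained",
    "top_fraction",
    "smooth_fwhm",
    "modified_z_threshold",
}

_UNIT_INTERVAL_KEYS = {"dice_min", "corr_max", "variability_dice_min", "effect_max",
                       "min_retained", "top_fraction"}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def validate_config(raw: dict) -> dict:
    """Validate and normalise a raw config dict; returns the cleaned dict."""
    if not isinstance(raw, dict):
        raise ConfigError("config must be a JSON object")
    _check_keys(raw, {"schema_version", "workflow", "regressors", "qc"}, "config root")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version} (expected {SCHEMA_VERSION})")
    wf = dict(raw.get("workflow", {}))
    _check_keys(wf, _WORKFLOW_KEYS, "workflow")
    if "scaling" in wf and wf["scaling"] not in SCALING_METHODS:
        raise ConfigError(f"workflow.scaling must be one of {SCALING_METHODS}")
    if "detrend_order" in wf and wf["detrend_order"] not in (1, 2):
        raise ConfigError("workflow.detrend_order must be 1 or 2")
    reg = dict(raw.get("regressors", {}))
    _check_keys(reg, _REGRESSOR_KEYS, "regressors")
    qc = dict(raw.get("qc", {}))
    _check_keys(qc, _QC_KEYS, "qc")
    for key in _UNIT_INTERVAL_KEYS & set(qc):
        val = qc[key]
        if not isinstance(val, (int, float)) or not 0 <= val <= 1:
            raise ConfigError(f"qc.{key} must lie in [0, 1], got {val!r}")
    if "min_n" in qc and (not isinstance(qc["min_n"], int) or qc["min_n"] < 2):
        raise ConfigError("qc.min_n must be an integer >= 2")
    return {"schema_version": SCHEMA_VERSION, "workflow": wf, "regressors": reg, "qc": qc}


def load_config(path: Optional[str]) -> dict:
    if path is None:
        return validate_config({})
    raw = json.loads(Path(path).read_text())
    return validate_config(raw)


def workflow_options_from_config(cfg: dict, seed: Optional[int] = None) -> WorkflowOptions:
    wf = dict(cfg.get("workflow", {}))
    reg = cfg.get("regressors", {})
    opt = WorkflowOptions(**wf)
    if reg:
        opt.regressors = RegressorSpec(**reg)
    if seed is not None:
        opt.seed = seed
    return opt


def echo_options(opt: WorkflowOptions) -> dict:
    out = dataclasses.asdict(opt)
    return out


def write_manifest(out_dir: Path, command: str, inputs: dict, cfg: dict,
                   seed: Optional[int]) -> Path:
    from . import __version__

    manifest = {
        "command": command,
        "package": "boldqc",
        "version": __version__,
        "seed": seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": cfg,
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
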