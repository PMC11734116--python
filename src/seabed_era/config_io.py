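"""Configuration loading/validation and deterministic serialization.

The on-disk model definition is a single JSON document with sections
``variables``, ``cpts``, ``scenarios``, ``groups``, ``bins`` and ``metadata``.
Loading validates the schema and rejects unknown keys with path-specific
messages; a patch document (same shape, sparse) can be merged over the default
to override any prior, weight, beta pair, escape fraction or scenario.
Outputs are written as UTF-8 CSV with '.' decimals, LF line endings and
6-decimal probabilities, accompanied by a small run manifest for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelConfig

SCHEMA_VERSION = 1

_TOP_KEYS = {"variables", "cpts", "scenarios", "groups", "bins", "metadata",
             "schema_version"}
_VARIABLE_KEYS = {"name", "states", "role", "tier", "confidence", "nominal"}
_GROUP_KEYS = {"key", "name", "habit", "escape_fraction", "depth_sensitive",
               "substrate_affinity"}
_CPT_KEYS_BY_TYPE = {
    "table": {"type", "parents", "table"},
    "ordinal_response": {"type", "parents", "offset", "coeffs", "scale"},
    "beta_elicitation": {"type", "best", "worst", "influences", "bins"},
    "direct_removal": {"type", "group", "intensity_fracs", "depth_multipliers"},
    "combined_immediate": {"type", "parents", "grid_m"},
    "recovery": {"type", "parents", "recovery"},
}


class ConfigError(ValueError):
    """Schema violation with a path into the offending document."""


def config_to_dict(config: ModelConfig) -> dict:
    d = dataclasses.asdict(config)
    d["schema_version"] = SCHEMA_VERSION
    return d


def config_from_dict(doc: dict) -> ModelConfig:
    _validate_schema(doc)
    return ModelConfig(
        variables=doc["variables"],
        cpts=doc["cpts"],
        scenarios=doc.get("scenarios", {}),
        groups=doc.get("groups", []),
        bins=doc.get("bins", [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]),
        metadata=doc.get("metadata", {}),
    )


def _reject_unknown(mapping: dict, allowed: set, path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")


def _validate_schema(doc: dict) -> None:
    if not isinstance(doc, dict):
        raise ConfigError("top level: expected a JSON object")
    _reject_unknown(doc, _TOP_KEYS, "top level")
    if "variables" not in doc:
        raise ConfigError("top level: missing required section 'variables'")
    if "cpts" not in doc:
        raise ConfigError("top level: missing required section 'cpts'")
    for i, v in enumerate(doc["variables"]):
        path = f"variables[{i}]"
        if not isinstance(v, dict):
            raise ConfigError(f"{path}: expected an object")
        _reject_unknown(v, _VARIABLE_KEYS, path)
        for req in ("name", "states", "role", "tier"):
            if req not in v:
                raise ConfigError(f"{path}: missing {req!r}")
    if not isinstance(doc["cpts"], dict):
        raise ConfigError("cpts: expected an object keyed by variable name")
    for name, spec in doc["cpts"].items():
        path = f"cpts.{name}"
        if not isinstance(spec, dict) or "type" not in spec:
            raise ConfigError(f"{path}: expected an object with a 'type'")
        allowed = _CPT_KEYS_BY_TYPE.get(spec["type"])
        if allowed is None:
            raise ConfigError(f"{path}: unknown CPT type {spec['type']!r}")
        _reject_unknown(spec, allowed, path)
    for i, g in enumerate(doc.get("groups", [])):
        _reject_unknown(g, _GROUP_KEYS, f"groups[{i}]")
    scenarios = doc.get("scenarios", {})
    if not isinstance(scenarios, dict):
        raise ConfigError("scenarios: expected an object keyed by scenario name")
    for name, assignment in scenarios.items():
        if not isinstance(assignment, dict):
            raise ConfigError(f"scenarios.{name}: expected variable -> state object")


def save_config(config: ModelConfig, path) -> None:
    Path(path).write_text(dumps_config(config), encoding="utf-8")


def dumps_config(config: ModelConfig) -> str:
    return json.dumps(config_to_dict(config), indent=2, sort_keys=True) + "\n"


def load_config(path) -> ModelConfig:
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ConfigError(f"{path}: not valid JSON (line {e.lineno}): {e.msg}") from e
    return config_from_dict(doc)


def merge_patch(base: dict, patch: dict) -> dict:
    """Recursive merge of a sparse override document over a config dict.

    Mappings merge key-wise; everything else (lists, scalars) is replaced.
    """
    out = dict(base)
    for key, value in patch.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = merge_patch(out[key], value)
        else:
            out[key] = value
    return out


def load_config_with_patch(path, patch_path) -> ModelConfig:
    base = json.loads(Path(path).read_text(encoding="utf-8"))
    patch = json.loads(Path(patch_path).read_text(encoding="utf-8"))
    return config_from_dict(merge_patch(base, patch))


# ---------------------------------------------------------------------------
# output serialization


def evidence_hash(evidence: dict[str, str]) -> str:
    payload = json.dumps(sorted(evidence.items()))
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def posterior_frame(
    posterior: dict[str, np.ndarray],
    states: dict[str, tuple[str, ...]],
    evidence: dict[str, str],
) -> pd.DataFrame:
    """Posterior export table: variable, state, probability, evidence_hash."""
    h = evidence_hash(evidence)
    rows = []
    for name in sorted(posterior):
        for state, p in zip(states[name], posterior[name]):
            rows.append(dict(
                variable=name, state=state, probability=round(float(p), 6),
                evidence_hash=h,
            ))
    return pd.DataFrame(rows)


def write_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def write_manifest(
    path,
    command: str,
    config: ModelConfig,
    seeds: dict[str, int] | None,
    outputs: list[str],
) -> None:
    """Run manifest written alongside outputs (provenance record)."""
    from . import __version__

    digest = hashlib.sha256(dumps_config(config).encode()).hexdigest()
    manifest = dict(
        command=command,
        config_sha256=digest,
        seeds=seeds or {},
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        outputs=[str(o) for o in outputs],
    )
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
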