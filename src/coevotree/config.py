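"""Validated run configuration shared by the CLI subcommands.

A single versioned JSON document collects every tunable of the pipeline;
CLI flags override file values.  Unknown keys are rejected so that typos do
not silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

__all__ = ["RunConfig", "load_config", "config_hash"]

_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    # preprocessing
    max_col_gap_frac: float = 0.5
    max_seq_gap_frac: float = 0.5
    min_seqs: int = 50
    min_cols: int = 50
    max_cols: int = 400
    # pair statistics
    lambda_single: float = 0.5
    apc: bool = True
    # tree model
    lambda_min: float = 1e-12
    alpha: float = 1.0
    # contacts
    contact_threshold: float = 8.0
    min_coverage: float = 0.8
    # prior
    d_switch: int = 4
    prior_D: int = 14
    prior_gamma: float = 1.0
    entropy_bin_width: float = 0.25
    # chains
    z_threshold: float = 4.0
    n_perm: int = 100
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.max_col_gap_frac <= 1.0):
            raise ValueError("max_col_gap_frac out of range")
        if not (0.0 <= self.max_seq_gap_frac <= 1.0):
            raise ValueError("max_seq_gap_frac out of range")
        if self.min_cols > self.max_cols:
            raise ValueError("min_cols exceeds max_cols")
        if self.lambda_single <= 0:
            raise ValueError("lambda_single must be positive")
        if not (0.0 < self.lambda_min < 1.0):
            raise ValueError("lambda_min must be in (0, 1)")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.contact_threshold <= 0:
            raise ValueError("contact_threshold must be positive")
        if not (0.0 <= self.min_coverage <= 1.0):
            raise ValueError("min_coverage out of range")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.pop("schema_version", _SCHEMA_VERSION)
    if version != _SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {version!r}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)


def config_hash(cfg: RunConfig) -> str:
    doc = dataclasses.asdict(cfg)
    doc["schema_version"] = _SCHEMA_VERSION
    canonical = json.dumps(doc, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
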