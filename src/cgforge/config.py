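"""Declarative run configuration: YAML in, validated knobs out.

Unknown keys are rejected so typos fail loudly; every run can log the
resolved configuration and its hash, making deterministic stages
re-runnable bit-exactly.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "load_config"]

VERSION = "1"

_KNOWN = {
    "seed": int,
    "units": dict,
    "mapping": dict,
    "priors": dict,
    "model": dict,
    "training": dict,
    "simulation": dict,
    "analysis": dict,
    "mutation": dict,
    "paths": dict,
}

_KNOWN_SUBKEYS = {
    "units": {"length", "energy"},
    "mapping": {"sequence", "pdb"},
    "priors": {"exclusion", "repulsion_p"},
    "model": {"embedding_dim", "n_interactions", "cutoff", "n_rbf", "seed"},
    "training": {"n_epochs", "batch_size", "learning_rate", "grad_clip",
                 "validation_fraction", "patience", "exclude_tags",
                 "decoy_stride", "decoy_sigma"},
    "simulation": {"temperature", "friction", "timestep", "n_steps",
                   "save_interval", "ladder", "exchange_interval"},
    "analysis": {"tica_lag", "fes_bins", "q_beta", "q_lambda", "q_cutoff"},
    "mutation": {"n_resamples", "batch_size", "folded_q_min",
                 "unfolded_q_max"},
    "paths": None,           # free-form
}


@dataclass
class RunConfig:
    """Resolved configuration document covering every module's knobs."""

    values: dict = field(default_factory=dict)
    version: str = VERSION

    def __post_init__(self):
        for key, sub in self.values.items():
            if key not in _KNOWN:
                raise ValueError(f"unknown config key {key!r}")
            allowed = _KNOWN_SUBKEYS.get(key)
            if allowed is not None and isinstance(sub, dict):
                for k in sub:
                    if k not in allowed:
                        raise ValueError(f"unknown config key {key}.{k}")

    @property
    def hash(self) -> str:
        blob = json.dumps({"version": self.version, "values": self.values},
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def section(self, name: str) -> dict:
        return dict(self.values.get(name, {}))

    def get(self, dotted: str, default=None):
        sec, _, key = dotted.partition(".")
        if not key:
            return self.values.get(sec, default)
        return self.values.get(sec, {}).get(key, default)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return RunConfig(doc)
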