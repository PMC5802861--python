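"""Configuration files, seed derivation, and run manifests.

All randomness in CLI runs flows from explicit integer seeds recorded in
a per-run manifest; per-cell sweep seeds derive from a master seed and
the cell coordinates through a counter-based scheme (SeedSequence over
the hashed key), so any cell can be reproduced in isolation.
"""

from __future__ import annotations

import datetime
import json
import zlib
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .training import TrainingConfig

__all__ = ["derive_seed", "load_config", "RunManifest", "write_manifest"]


def derive_seed(master_seed: int, *key) -> int:
    """Deterministic 31-bit seed from a master seed and a mixed key.

    String key parts are folded in via CRC32 so the scheme is stable
    across processes and platforms.
    """
    ints = [int(master_seed)]
    for part in key:
        if isinstance(part, str):
            ints.append(zlib.crc32(part.encode()))
        else:
            ints.append(int(part) & 0xFFFFFFFF)
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] % (2**31))


_CONFIG_FIELDS = {f.name: f.type for f in fields(TrainingConfig)}
_NETWORK_KEYS = {"n_units", "tau", "dt", "g", "nonlinearity"}


def load_config(path) -> dict:
    """Load a YAML run configuration and validate its keys.

    Returns a dict with two sub-dicts: ``network`` (NetworkParams
    overrides) and ``training`` (TrainingConfig overrides).  A flat file
    is also accepted, with keys routed by name.  Unknown keys raise.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    network = dict(raw.pop("network", {}))
    training = dict(raw.pop("training", {}))
    for key, value in raw.items():
        if key in _NETWORK_KEYS:
            network[key] = value
        elif key in _CONFIG_FIELDS:
            training[key] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    for key in network:
        if key not in _NETWORK_KEYS:
            raise ValueError(f"unknown network config key {key!r}")
    for key in training:
        if key not in _CONFIG_FIELDS:
            raise ValueError(f"unknown training config key {key!r}")
    return {"network": network, "training": training}


@dataclass
class RunManifest:
    """Snapshot of one CLI run: what was run, with which seeds, and
    which files it produced."""

    command: str
    config: dict
    master_seed: int
    seeds: dict = field(default_factory=dict)
    artifacts: list = field(default_factory=list)
    version: str = ""
    created: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.created:
            self.created = datetime.datetime.now(datetime.timezone.utc).isoformat()


def write_manifest(manifest: RunManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, default=str)
        fh.write("\n")
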