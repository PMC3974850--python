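"""Provenance headers for pipeline outputs (config hash, seed, version)."""

from __future__ import annotations

import hashlib
import json


def config_hash(config: dict) -> str:
    """Stable short hash of a (JSON-serializable) config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def header_lines(config: dict, seed: int) -> list[str]:
    from . import __version__

    return [
        f"sparklet v{__version__}",
        f"seed={seed}",
        f"config_sha256={config_hash(config)}",
    ]
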