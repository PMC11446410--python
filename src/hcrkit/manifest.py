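"""Reproducible run manifests: resolved config, input/output digests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

from . import __version__

__all__ = ["sha256_file", "write_manifest"]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_manifest(
    path,
    command: str,
    config,
    inputs: list,
    outputs: list,
    warnings: list[str],
) -> Path:
    """Write the run manifest JSON: tool version, resolved config, sha256 of
    every input and output file, warnings, timestamp. Re-running with the
    same inputs and config reproduces every non-timestamp field."""
    manifest = {
        "tool": "hcrkit",
        "version": __version__,
        "command": command,
        "config": _jsonable(config),
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "outputs": {str(p): sha256_file(p) for p in outputs},
        "warnings": list(warnings),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
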