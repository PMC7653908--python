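"""Run manifests: enough metadata to re-run a command bit-identically."""

from __future__ import annotations

import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    command: str,
    params: dict,
    input_files: dict[str, str | Path] | None = None,
    extra: dict | None = None,
) -> dict:
    """Write a JSON run manifest recording command, parameters, seeds and inputs."""
    from . import __version__

    manifest = {
        "tool": "sigsolve",
        "version": __version__,
        "command": command,
        "parameters": params,
        "inputs": {
            name: {"path": str(p), "sha256": _digest(p)}
            for name, p in (input_files or {}).items()
        },
        "python": sys.version.split()[0],
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
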