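"""Run manifests: enough provenance to replay a deterministic run."""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

from .. import __version__

__all__ = ["RunManifest"]


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Config snapshot, input digests, seeds and version of one run."""

    def __init__(self, command: str, config: dict | None = None,
                 seeds: dict | None = None):
        self.data = {
            "tool": "ngvkit",
            "version": __version__,
            "command": command,
            "config": config or {},
            "seeds": seeds or {},
            "inputs": {},
            "python": platform.python_version(),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }

    def add_input(self, path) -> None:
        p = Path(path)
        self.data["inputs"][p.name] = _digest(p)

    def add(self, key: str, value) -> None:
        self.data[key] = value

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        p = out / "run_manifest.json"
        with open(p, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
        return p
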