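"""Run manifests: enough provenance to reproduce any CLI run."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

__all__ = ["write_manifest", "read_manifest"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config_snapshot: dict | None = None,
    inputs: dict[str, str | Path] | None = None,
    seed: int | None = None,
) -> Path:
    """Write ``manifest.json`` into ``out_dir``: the command, a config
    snapshot, SHA-256 of every input file, the seed and the package version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        pkg_version = version("abstractmyo")
    except PackageNotFoundError:
        pkg_version = "unknown"
    manifest = {
        "command": command,
        "config": config_snapshot or {},
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (inputs or {}).items()
        },
        "seed": seed,
        "package_version": pkg_version,
        "written_at": datetime.now(timezone.utc).isoformat(timespec="milliseconds"),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / "manifest.json").read_text())
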