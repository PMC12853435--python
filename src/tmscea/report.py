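"""Report writers: incremental tables, CEAC/OSA CSVs and run manifests.

Numeric output uses fixed decimal formatting so two runs with identical
configuration and seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

__all__ = ["RunManifest", "write_report", "write_csv"]

_FLOAT_FORMAT = "%.6f"


@dataclass
class RunManifest:
    """Provenance of one model run."""

    seed: int
    n_sims: int
    config_hash: str = ""
    n_excluded_draws: int = 0
    started_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)
    notes: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def config_hash(payload) -> str:
    """Stable hash of a JSON-serialisable configuration payload."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def write_report(
    outdir: str | Path,
    manifest: RunManifest,
    incremental: pd.DataFrame | None = None,
    ceac: pd.DataFrame | None = None,
    osa: pd.DataFrame | None = None,
    extra_tables: dict[str, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write the run's tables and a JSON manifest listing every output."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    tables = dict(extra_tables or {})
    if incremental is not None:
        tables["incremental_table"] = incremental
    if ceac is not None:
        tables["ceac"] = ceac
    if osa is not None:
        tables["osa_grid"] = osa
    for name, frame in tables.items():
        written[name] = write_csv(frame, outdir / f"{name}.csv")
    manifest.outputs = sorted(str(p.name) for p in written.values()) + [
        "manifest.json"
    ]
    mpath = outdir / "manifest.json"
    mpath.write_text(manifest.to_json())
    written["manifest"] = mpath
    return written
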