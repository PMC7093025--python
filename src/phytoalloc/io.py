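"""Tabular I/O helpers: provenance-stamped CSV round-trips.

CSV dialect is fixed package-wide: comma separator, UTF-8, '.' decimal,
mandatory header row.  Floats are written with Python repr precision so a
read-back reproduces the values bit for bit.  Every file starts with
comment lines recording the package version, the seed, and a hash of the
run configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def config_hash(config: object) -> str:
    """Short stable hash of an arbitrary JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(seed: int | None, config: object) -> list[str]:
    return [
        f"# phytoalloc {__version__}",
        f"# seed={seed}",
        f"# config_hash={config_hash(config)}",
    ]


def write_csv(df: pd.DataFrame, path: str | Path, seed: int | None = None,
              config: object = None) -> None:
    """Write a DataFrame with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in provenance_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv` (comment lines skipped)."""
    return pd.read_csv(path, comment="#")
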