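"""Result serialisation: tidy CSV plus a JSON manifest.

CSV floats are written at full repr precision, so a read round-trips
bit-exactly for integers and to better than 1e-12 relative for reals.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

__all__ = ["write_results", "read_results"]


def _package_version() -> str:
    try:
        return version("nutrilat")
    except PackageNotFoundError:
        return "unknown"


def write_results(df: pd.DataFrame, manifest: dict, out_dir: str | Path,
                  name: str) -> tuple[Path, Path]:
    """Write ``<name>.csv`` and ``<name>.manifest.json`` under ``out_dir``;
    returns the two paths."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        csv_path = out / f"{name}.csv"
        manifest_path = out / f"{name}.manifest.json"
        df.to_csv(csv_path, index=False)
        payload = dict(manifest)
        payload.setdefault("software_version", _package_version())
        manifest_path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    except OSError as err:
        raise OSError(f"failed writing results under {out}: {err}") from err
    return csv_path, manifest_path


def read_results(csv_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(csv_path)
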