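"""Reading and writing the package's delimited-text formats.

The canonical interchange format is the long reading table with columns
plant_id, spectrum, intensity, co2, replicate, an (units fixed
package-wide: PPFD and A_n in umol m-2 s-1, CO2 in ppm). Wide
publication-style grids are export-only. A "comma" decimal dialect is
accepted on read and available on write to mirror how the source tables
were typeset; everything internal uses dot decimals.
"""

from __future__ import annotations

import hashlib
import json
import datetime as _dt
from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd

from co2resp import __version__ as _pkg_version
from co2resp.nlme import validate_dataset
from co2resp.util import round_half_up

REQUIRED_COLUMNS = ("plant_id", "spectrum", "intensity", "co2", "replicate", "an")


def read_dataset(path, dialect: str = "dot") -> pd.DataFrame:
    """Read and validate a long-format reading table.

    ``dialect="comma"`` converts comma-decimal numeric cells (e.g. "7,21")
    on read. Validation failures report offending rows/plants.
    """
    if dialect not in ("dot", "comma"):
        raise ValueError(f"unknown decimal dialect {dialect!r}")
    df = pd.read_csv(path, dtype=str, sep=None, engine="python")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("intensity", "co2", "replicate", "an"):
        raw = df[col].astype(str)
        if dialect == "comma":
            raw = raw.str.replace(",", ".", regex=False)
        vals = pd.to_numeric(raw, errors="coerce")
        if vals.isna().any():
            lines = [int(i) + 2 for i in df.index[vals.isna()][:5]]  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric {col!r} cells at line(s) {lines}")
        df[col] = vals
    df["replicate"] = df["replicate"].astype(int)
    validate_dataset(df)
    if {"blue_pct", "green_pct", "red_pct"}.issubset(df.columns):
        from co2resp.curve_model import SPECTRUM_MIXES
        for lab, grp in df.groupby("spectrum"):
            if lab in SPECTRUM_MIXES:
                want = SPECTRUM_MIXES[lab]
                got = tuple(float(str(grp[c].iloc[0]).replace(",", ".")) for c in
                            ("blue_pct", "green_pct", "red_pct"))
                if max(abs(a - b) for a, b in zip(want, got)) > 1e-6:
                    raise ValueError(
                        f"{path}: spectrum {lab!r} photon fractions {got} disagree "
                        f"with the registry {want}"
                    )
    return df[list(REQUIRED_COLUMNS)]


def write_dataset(df: pd.DataFrame, path, dialect: str = "dot") -> None:
    validate_dataset(df)
    out = df[list(REQUIRED_COLUMNS)].sort_values(
        ["spectrum", "plant_id", "intensity", "co2", "replicate"], kind="stable"
    )
    _write_csv(out, path, dialect)


def read_params_csv(path, dialect: str = "dot") -> pd.DataFrame:
    """Read a cell-parameter table (spectrum, intensity, c, d, b)."""
    df = pd.read_csv(path, dtype=str)
    missing = {"spectrum", "intensity", "c", "d", "b"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("intensity", "c", "d", "b"):
        raw = df[col].astype(str)
        if dialect == "comma":
            raw = raw.str.replace(",", ".", regex=False)
        df[col] = pd.to_numeric(raw)
    return df


def write_params_csv(cells: pd.DataFrame, path, dialect: str = "dot") -> None:
    out = cells.sort_values(["spectrum", "intensity"], kind="stable")
    _write_csv(out, path, dialect)


def write_grid_csv(
    grid: pd.DataFrame,
    path,
    value_col: str,
    dialect: str = "dot",
    wide: bool = False,
    decimals: Optional[int] = None,
) -> None:
    """Write a long (spectrum, intensity, co2, value) grid, or its wide
    publication-style layout (one row per spectrum, intensity columns
    grouped by CO2 scenario)."""
    df = grid.copy()
    if decimals is not None:
        df[value_col] = round_half_up(df[value_col].to_numpy(), decimals)
    if wide:
        df = df.pivot_table(
            index="spectrum", columns=["co2", "intensity"], values=value_col, sort=False
        )
        df.columns = [f"co2_{int(c)}_ppfd_{int(i)}" for c, i in df.columns]
        df = df.reset_index()
    _write_csv(df, path, dialect)


def _write_csv(df: pd.DataFrame, path, dialect: str) -> None:
    if dialect == "comma":
        df.to_csv(path, index=False, sep=";", decimal=",")
    else:
        df.to_csv(path, index=False)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(
    path,
    config: Dict,
    inputs: Sequence = (),
    extra: Optional[Dict] = None,
) -> None:
    """Sidecar JSON with package version, timestamp, config echo and input hashes."""
    block = {
        "package": "co2resp",
        "version": _pkg_version,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "config": config,
        "input_hashes": {str(p): sha256_of(p) for p in inputs},
    }
    if extra:
        block.update(extra)
    Path(path).write_text(json.dumps(block, indent=2, default=str) + "\n")
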