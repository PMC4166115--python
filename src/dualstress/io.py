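"""Readers and writers for spot tables, sample sheets and result bundles.

Spot tables travel as tab-delimited GPR-like text with the columns
``Block, Row, Column, ID, Name, F532 Median, B532 Median, F635 Median,
B635 Median, Flags, SpotClass``.  Per the staining convention of the
experiment the 532 nm (Cy3) channel is always the *treated* sample and the
635 nm (Cy5) channel the *control*, so F532 maps to ``f_treat`` and F635 to
``f_ctrl``.  Flags follow the GenePix convention: negative = bad.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "GPR_COLUMNS",
    "read_spot_table",
    "write_spot_table",
    "write_spot_tables",
    "read_sample_sheet",
    "write_results",
    "read_supplementary_workbook",
]

GPR_COLUMNS = [
    "Block", "Row", "Column", "ID", "Name",
    "F532 Median", "B532 Median", "F635 Median", "B635 Median",
    "Flags", "SpotClass",
]

_CANON = ["array_id", "probe_id", "spot_class",
          "f_treat", "b_treat", "f_ctrl", "b_ctrl", "flag"]

_GPR_TO_CANON = {
    "ID": "probe_id",
    "SpotClass": "spot_class",
    "F532 Median": "f_treat",
    "B532 Median": "b_treat",
    "F635 Median": "f_ctrl",
    "B635 Median": "b_ctrl",
}

_REQUIRED_GPR = ["ID", "F532 Median", "B532 Median",
                 "F635 Median", "B635 Median", "Flags"]


def write_spot_table(spots: pd.DataFrame, path, array_id: str | None = None) -> Path:
    """Write one array's spots as a GPR-like tab-delimited file."""
    path = Path(path)
    df = spots
    if array_id is not None:
        df = df[df["array_id"] == array_id]
    n = len(df)
    out = pd.DataFrame(
        {
            "Block": np.ones(n, dtype=int),
            "Row": np.arange(n) // 32 + 1,
            "Column": np.arange(n) % 32 + 1,
            "ID": df["probe_id"].to_numpy(),
            "Name": df["probe_id"].to_numpy(),
            "F532 Median": df["f_treat"].to_numpy(),
            "B532 Median": df["b_treat"].to_numpy(),
            "F635 Median": df["f_ctrl"].to_numpy(),
            "B635 Median": df["b_ctrl"].to_numpy(),
            "Flags": np.where(df["flag"].to_numpy() == "bad", -100, 0),
            "SpotClass": df["spot_class"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)
    return path


def write_spot_tables(spots: pd.DataFrame, out_dir) -> list[Path]:
    """Write one ``<array_id>.gpr.txt`` file per array; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for array_id, sub in spots.groupby("array_id", sort=False):
        paths.append(write_spot_table(sub, out_dir / f"{array_id}.gpr.txt"))
    return paths


def read_spot_table(path, array_id: str | None = None, dialect: str = "gpr") -> pd.DataFrame:
    """Read a GPR-like spot file into the canonical spot-record layout.

    Unknown columns are preserved untouched.  Raises :class:`FormatError`
    naming the first missing required column, and :class:`ValidationError`
    listing rows with negative intensities.
    """
    path = Path(path)
    if dialect != "gpr":
        raise FormatError(f"unknown dialect {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t")
    for col in _REQUIRED_GPR:
        if col not in raw.columns:
            raise FormatError(f"missing required column {col!r} in {path.name}")
    df = raw.rename(columns=_GPR_TO_CANON)
    if "spot_class" not in df.columns:
        df["spot_class"] = "experimental"
    for col in ("f_treat", "b_treat", "f_ctrl", "b_ctrl"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = list(df.index[vals.isna()][:10])
            raise ValidationError(f"non-numeric {col} at rows {bad} in {path.name}")
        df[col] = vals
    neg = (df[["f_treat", "b_treat", "f_ctrl", "b_ctrl"]] < 0).any(axis=1)
    if neg.any():
        raise ValidationError(
            f"negative intensities at rows {list(df.index[neg][:10])} in {path.name}"
        )
    flags = pd.to_numeric(df["Flags"], errors="coerce").fillna(-100)
    df["flag"] = np.where(flags < 0, "bad", "good")
    if array_id is None:
        name = path.name
        for suffix in (".gpr.txt", ".gpr", ".txt", ".tsv"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
                break
        array_id = name
    df["array_id"] = array_id
    extras = [c for c in df.columns if c not in _CANON]
    return df[_CANON + extras]


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate the array -> (run, treatment, time_h, replicate) map."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValidationError(f"sample sheet {path.name} is empty")
    sheet = pd.read_csv(path)
    required = ["array_id", "run", "treatment", "time_h", "replicate"]
    for col in required:
        if col not in sheet.columns:
            raise FormatError(f"sample sheet missing column {col!r}")
    if len(sheet) == 0:
        raise ValidationError(f"sample sheet {path.name} has no rows")
    dup = sheet["array_id"][sheet["array_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate array_id(s): {sorted(set(dup))}")
    for col in ("run", "replicate"):
        vals = pd.to_numeric(sheet[col], errors="coerce")
        if vals.isna().any():
            raise ValidationError(f"non-numeric values in {col!r}")
        sheet[col] = vals.astype(int)
    times = pd.to_numeric(sheet["time_h"], errors="coerce")
    if times.isna().any():
        raise ValidationError("non-numeric values in 'time_h'")
    sheet["time_h"] = times
    return sheet[required]


def design_balance(sheet: pd.DataFrame) -> pd.DataFrame:
    """Replicate counts per (run, treatment, time_h) design cell."""
    return (sheet.groupby(["run", "treatment", "time_h"])
            .size().rename("n_reps").reset_index())


def write_results(tables: dict[str, pd.DataFrame], out_dir,
                  params: dict | None = None, seed: int | None = None) -> dict:
    """Write each table as ``<name>.csv`` plus a JSON run manifest.

    Output is deterministic: the manifest carries parameters, seed and row
    counts but no timestamps, so identical inputs give identical bytes.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_test"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc
    files = []
    for name, table in tables.items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname, index=False)
        files.append({"file": fname, "rows": int(len(table)),
                      "columns": list(map(str, table.columns))})
    manifest = {
        "package": "dualstress",
        "seed": seed,
        "parameters": params or {},
        "files": files,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def read_supplementary_workbook(path) -> dict[str, pd.DataFrame]:
    """Best-effort reader for the deposited Excel dataset of 60 arrays.

    Treats every sheet that carries the required GPR-like columns as one
    array's spot table.  This is a convenience for users who obtained the
    workbook; nothing in the package requires it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    book = pd.read_excel(path, sheet_name=None)
    out = {}
    for sheet_name, raw in book.items():
        if not all(c in raw.columns for c in _REQUIRED_GPR):
            continue
        df = raw.rename(columns=_GPR_TO_CANON)
        if "spot_class" not in df.columns:
            df["spot_class"] = "experimental"
        flags = pd.to_numeric(df["Flags"], errors="coerce").fillna(-100)
        df["flag"] = np.where(flags < 0, "bad", "good")
        df["array_id"] = sheet_name
        extras = [c for c in df.columns if c not in _CANON]
        out[sheet_name] = df[_CANON + extras]
    if not out:
        raise FormatError(f"no GPR-like sheets found in {path.name}")
    return out
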