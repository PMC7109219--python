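"""Registry CSV input/output with schema validation and run manifests.

All files are UTF-8 RFC-4180 CSV with a header row; dates are ISO-8601
calendar dates.  Loading is schema-checked: a missing required column is a
hard error, while a row that fails to parse (e.g. a malformed date) is
skipped and counted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("vitalink")

BIRTH_SCHEMA = {
    "birth_id": "str", "encoded_identifier": "str", "dob": "date",
    "sex": "str", "place_code": "str", "postal_code": "str",
    "birthweight_g": "int", "ga_weeks": "int", "maternal_age": "str",
    "parity": "str", "plurality": "str", "income_quintile": "str",
    "region": "str", "rural": "bool", "stillbirth_flag": "bool",
    "orphan_flag": "bool", "bw_bin": "str", "ga_bin": "str",
}

DEATH_SCHEMA = {
    "death_id": "str", "encoded_identifier": "str", "dob": "date",
    "dod": "date", "place_of_death_code": "str", "sex": "str",
    "postal_code": "str", "icd10_cause": "str", "age_at_death_days": "int",
}

TRUTH_SCHEMA = {"death_id": "str", "birth_id": "str", "reason": "str"}


def write_registry_csv(df: pd.DataFrame, path) -> Path:
    """Write a registry frame as UTF-8 CSV; dates serialize as ISO-8601."""
    path = Path(path)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return path


def read_registry_csv(path, schema: dict) -> tuple[pd.DataFrame, int]:
    """Schema-checked CSV load.

    Returns ``(frame, n_rejected)``; rows whose typed fields fail to parse
    are dropped and logged with their line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")

    bad = pd.Series(False, index=df.index)
    for col, kind in schema.items():
        if kind == "date":
            parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
            bad |= parsed.isna() & (df[col] != "")
            df[col] = parsed
        elif kind == "int":
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad |= parsed.isna() & (df[col] != "")
            df[col] = parsed.astype("Int64")
        elif kind == "float":
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad |= parsed.isna() & (df[col] != "")
            df[col] = parsed
        elif kind == "bool":
            lowered = df[col].str.lower()
            ok = lowered.isin(["true", "false", ""])
            bad |= ~ok
            df[col] = lowered == "true"
    n_rejected = int(bad.sum())
    if n_rejected:
        lines = (df.index[bad] + 2).tolist()  # header is line 1
        log.warning("%s: rejected %d malformed row(s) at line(s) %s",
                    path.name, n_rejected, lines[:20])
    return df[~bad].reset_index(drop=True), n_rejected


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config_hash: str, seed: int,
                   stage_counts: dict) -> Path:
    """Record config hash, seed, per-stage row counts and a checksum for
    every emitted file."""
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": config_hash,
        "seed": seed,
        "stage_counts": stage_counts,
        "files": {p.name: sha256_file(p) for p in files},
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
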