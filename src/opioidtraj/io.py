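"""Delimited-text table I/O, run manifests, and table validation.

All pipeline artifacts are UTF-8 comma-separated text with RFC-4180 quoting
and ISO-8601 dates; every table starts with a versioned schema comment line
(``# opioidtraj-table-v1 schema=<name>``).  Writes are atomic (temp file +
rename) so a failed stage never leaves partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

SCHEMA_VERSION = "opioidtraj-table-v1"

#: Required columns per table schema (validation and stage contracts).
SCHEMAS = {
    "region": ["region_id", "region_name"],
    "practice": ["practice_id", "region_id"],
    "staff": ["staff_id", "practice_id"],
    "patient": [
        "patient_id",
        "staff_id",
        "sex",
        "age_at_index",
        "birth_year",
        "ethnicity",
        "townsend_quintile",
        "registration_start",
        "registration_end",
    ],
    "therapy": [
        "patient_id",
        "prescriber_id",
        "ingredient",
        "route",
        "unit_strength",
        "quantity",
        "daily_count",
        "issue_date",
    ],
    "conditions": ["patient_id", "condition", "flag_date"],
    "denominators": ["year", "n_registered"],
}


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> Path:
    """Atomically write a table with its schema header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    header = f"# {SCHEMA_VERSION} schema={schema or path.stem}\n"
    with open(tmp, "w", encoding="utf-8", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    tmp.replace(path)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Append-only record of pipeline stages, seeds, and output digests."""

    def __init__(self, path):
        self.path = Path(path)
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"version": SCHEMA_VERSION, "stages": []}

    def record(self, stage: str, outputs: dict, seed=None, config_hash=None, extra=None):
        entry = {
            "stage": stage,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "seed": seed,
            "config_hash": config_hash,
            "outputs": {name: {"path": str(p), "sha256": file_digest(p)} for name, p in outputs.items()},
        }
        if extra:
            entry.update(extra)
        self.data["stages"].append(entry)
        tmp = self.path.with_name(self.path.name + ".tmp")
        tmp.write_text(json.dumps(self.data, indent=1, sort_keys=True))
        tmp.replace(self.path)
        return entry

    def verify(self) -> list[str]:
        """Check that every recorded output still exists and matches its digest."""
        problems = []
        for stage in self.data["stages"]:
            for name, rec in stage["outputs"].items():
                p = Path(rec["path"])
                if not p.exists():
                    problems.append(f"{stage['stage']}:{name}: missing file {p}")
                elif file_digest(p) != rec["sha256"]:
                    problems.append(f"{stage['stage']}:{name}: digest mismatch for {p}")
        return problems


def config_hash(config_dict: dict) -> str:
    return hashlib.sha256(json.dumps(config_dict, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_tables(paths: dict) -> pd.DataFrame:
    """Validate a directory of pipeline input tables.

    Checks column schemas, foreign-key integrity across the population
    tables, strict hierarchy nesting, date parsability, and value ranges.
    Violations are report rows (table, row, column, message), not errors.
    """
    violations: list[dict] = []

    def add(table, row, column, message):
        violations.append({"table": table, "row": row, "column": column, "message": message})

    tables = {}
    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            add(name, None, None, f"file missing: {path}")
            continue
        try:
            tables[name] = read_table(path)
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            add(name, None, None, f"unparseable: {exc}")

    for name, df in tables.items():
        required = SCHEMAS.get(name)
        if required:
            for col in required:
                if col not in df.columns:
                    add(name, None, col, "required column missing")

    def have(name, *cols):
        return name in tables and all(c in tables[name].columns for c in cols)

    if have("practice", "practice_id", "region_id") and have("region", "region_id"):
        known = set(tables["region"]["region_id"])
        for i, v in tables["practice"]["region_id"].items():
            if v not in known:
                add("practice", int(i), "region_id", f"orphan region id {v!r}")
    if have("staff", "staff_id", "practice_id") and have("practice", "practice_id"):
        known = set(tables["practice"]["practice_id"])
        for i, v in tables["staff"]["practice_id"].items():
            if v not in known:
                add("staff", int(i), "practice_id", f"orphan practice id {v!r}")
        dup = tables["staff"].groupby("staff_id")["practice_id"].nunique()
        for sid in dup[dup > 1].index:
            add("staff", None, "staff_id", f"prescriber {sid!r} assigned to more than one practice")
    if have("patient", "staff_id") and have("staff", "staff_id"):
        known = set(tables["staff"]["staff_id"])
        for i, v in tables["patient"]["staff_id"].items():
            if v not in known:
                add("patient", int(i), "staff_id", f"orphan staff id {v!r}")
    if have("therapy", "patient_id") and have("patient", "patient_id"):
        known = set(tables["patient"]["patient_id"])
        for i, v in tables["therapy"]["patient_id"].items():
            if v not in known:
                add("therapy", int(i), "patient_id", f"orphan patient id {v!r}")

    for name, col in [("therapy", "issue_date"), ("conditions", "flag_date"), ("patient", "registration_start"), ("patient", "registration_end")]:
        if have(name, col):
            parsed = pd.to_datetime(tables[name][col], format="%Y-%m-%d", errors="coerce")
            for i in tables[name].index[parsed.isna() & tables[name][col].notna()]:
                add(name, int(i), col, f"unparseable date {tables[name].loc[i, col]!r}")

    if have("therapy", "quantity"):
        qty = pd.to_numeric(tables["therapy"]["quantity"], errors="coerce")
        for i in tables["therapy"].index[qty < 0]:
            add("therapy", int(i), "quantity", f"negative quantity {qty[i]}")
    if have("denominators", "n_registered"):
        for i, v in tables["denominators"]["n_registered"].items():
            if v <= 0:
                add("denominators", int(i), "n_registered", "non-positive denominator")

    return pd.DataFrame(violations, columns=["table", "row", "column", "message"])
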