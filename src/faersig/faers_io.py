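"""Reading, writing and joining FAERS-style quarterly ASCII tables.

The public FAERS Quarterly Data Extract ships each quarter as a set of
"$"-delimited text files (DEMO, DRUG, REAC, THER, OUTC, INDI, RPSR), one
header row, no quoting, rows linked across tables by PRIMARYID.  This module
encodes that dialect: :func:`read_table` / :func:`write_table` handle single
files with lossless round-trips for non-missing fields, and
:func:`assemble_quarter` joins a quarter's tables into a
:class:`QuarterBundle` keyed by PRIMARYID, dropping and counting orphan rows
whose PRIMARYID never appears in DEMO.

Design notes
------------
* Field names are case-insensitive on read and normalised to lower case.
* A literal "$" inside a value cannot be represented (the dialect has no
  escaping) and raises on write.
* Files are decoded as UTF-8 with replacement of undecodable bytes; every
  replacement and every malformed line is recorded in ``RawTable.anomalies``
  (a list of dicts, serialisable as JSON lines).
* Unknown extra columns are preserved but never interpreted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

DELIMITER = "$"

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "THER", "OUTC", "INDI", "RPSR")

#: Columns that must be present (lower-case) for each table kind.
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": ("primaryid", "caseid", "fda_dt"),
    "DRUG": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "REAC": ("primaryid", "pt"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt"),
    "OUTC": ("primaryid", "outc_cod"),
    "INDI": ("primaryid", "indi_drug_seq", "indi_pt"),
    "RPSR": ("primaryid", "rpsr_cod"),
}


class SchemaError(ValueError):
    """A table is missing a mandatory column for its declared kind."""


class TableWriteError(ValueError):
    """A row cannot be represented in the FAERS ASCII dialect."""


@dataclass
class RawTable:
    """One FAERS-style table: a string DataFrame plus parse anomalies."""

    table_kind: str
    frame: pd.DataFrame
    quarter_label: str = ""
    anomalies: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        kind = self.table_kind.upper()
        if kind not in REQUIRED_COLUMNS:
            raise SchemaError(f"unknown table kind {self.table_kind!r}")
        self.table_kind = kind
        self.frame = self.frame.rename(columns=str.lower)
        missing = [c for c in REQUIRED_COLUMNS[kind] if c not in self.frame.columns]
        if missing:
            raise SchemaError(
                f"{kind} table is missing mandatory column(s): {', '.join(missing)}"
            )

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def rows(self) -> list[dict[str, str]]:
        """Rows as field-name -> string mappings (convenience view)."""
        return self.frame.to_dict(orient="records")

    def dump_anomalies(self, path: str | Path) -> Path:
        """Write parse anomalies as JSON lines; returns the path."""
        path = Path(path)
        with path.open("w") as fh:
            for rec in self.anomalies:
                fh.write(json.dumps(rec) + "\n")
        return path


def read_table(
    path: str | Path, table_kind: str, quarter_label: str = ""
) -> RawTable:
    """Parse one "$"-delimited FAERS-style file.

    Rows whose field count does not match the header (beyond a tolerated
    trailing delimiter) and rows with an empty PRIMARYID are skipped and
    logged as anomalies rather than aborting the read — schema drift and
    stray bytes are endemic across historical quarters.
    """
    path = Path(path)
    raw = path.read_bytes()
    text = raw.decode("utf-8", errors="replace")
    anomalies: list[dict] = []
    if "�" in text:
        anomalies.append(
            {"kind": "undecodable_bytes", "count": text.count("�")}
        )
    lines = text.splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file, no header")
    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    ncol = len(header)
    kind = table_kind.upper()
    required = REQUIRED_COLUMNS.get(kind)
    if required is None:
        raise SchemaError(f"unknown table kind {table_kind!r}")
    for col in required:
        if col not in header:
            raise SchemaError(f"{path}: {kind} header lacks mandatory column {col!r}")
    pid_pos = header.index("primaryid")

    records: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        fields = line.split(DELIMITER)
        if len(fields) == ncol + 1 and fields[-1] == "":
            fields = fields[:-1]  # trailing delimiter tolerated
        if len(fields) != ncol:
            anomalies.append(
                {"kind": "malformed_line", "line": lineno, "n_fields": len(fields)}
            )
            continue
        if fields[pid_pos].strip() == "":
            anomalies.append({"kind": "missing_primaryid", "line": lineno})
            continue
        records.append(fields)

    frame = pd.DataFrame(records, columns=header, dtype=str)
    if anomalies:
        log.warning("%s: %d parse anomalies", path, len(anomalies))
    return RawTable(kind, frame, quarter_label=quarter_label, anomalies=anomalies)


def write_table(table: RawTable, path: str | Path) -> Path:
    """Write a RawTable in the "$"-delimited dialect; round-trips losslessly."""
    path = Path(path)
    frame = table.frame.fillna("")
    cols = list(frame.columns)
    pid = frame["primaryid"].astype(str).str.strip()
    if (pid == "").any():
        raise TableWriteError("row with empty PRIMARYID cannot be written")
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(DELIMITER.join(cols) + "\n")
        for row in frame.itertuples(index=False):
            values = [str(v) for v in row]
            for v in values:
                if DELIMITER in v:
                    raise TableWriteError(
                        f"literal {DELIMITER!r} inside value {v!r} is not representable"
                    )
            fh.write(DELIMITER.join(values) + "\n")
    return path


@dataclass
class QuarterBundle:
    """A quarter's tables joined on PRIMARYID, orphans removed and counted."""

    tables: dict[str, RawTable]
    orphans_removed: dict[str, int] = field(default_factory=dict)

    @property
    def primaryids(self) -> pd.Index:
        return pd.Index(self.tables["DEMO"].frame["primaryid"])

    def table(self, kind: str) -> pd.DataFrame:
        """The frame for ``kind``; an empty schema-conformant frame if absent."""
        kind = kind.upper()
        if kind in self.tables:
            return self.tables[kind].frame
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS[kind]), dtype=str)

    @property
    def n_orphans(self) -> int:
        return sum(self.orphans_removed.values())


def assemble_quarter(tables: Iterable[RawTable]) -> QuarterBundle:
    """Join a set of RawTables into a QuarterBundle.

    DEMO, DRUG and REAC must be present.  Rows in non-DEMO tables whose
    PRIMARYID is absent from DEMO are orphans: they are excluded and counted
    per table.  Duplicate PRIMARYIDs within DEMO keep the first occurrence so
    that every indexed PRIMARYID resolves to exactly one DEMO row.
    Idempotent: assembling an assembled bundle's tables changes nothing.
    """
    by_kind: dict[str, RawTable] = {}
    for t in tables:
        if t.table_kind in by_kind:
            # same kind supplied twice (e.g. two quarters): concatenate
            prev = by_kind[t.table_kind]
            frame = pd.concat([prev.frame, t.frame], ignore_index=True)
            by_kind[t.table_kind] = RawTable(
                t.table_kind, frame, quarter_label=prev.quarter_label or t.quarter_label,
                anomalies=prev.anomalies + t.anomalies,
            )
        else:
            by_kind[t.table_kind] = t
    for needed in ("DEMO", "DRUG", "REAC"):
        if needed not in by_kind:
            raise SchemaError(f"cannot assemble quarter without a {needed} table")

    demo = by_kind["DEMO"]
    demo_frame = demo.frame.drop_duplicates(subset="primaryid", keep="first")
    n_dropped = len(demo.frame) - len(demo_frame)
    if n_dropped:
        log.warning("DEMO: dropped %d duplicate PRIMARYID rows", n_dropped)
    known = pd.Index(demo_frame["primaryid"])

    out: dict[str, RawTable] = {
        "DEMO": RawTable(
            "DEMO", demo_frame.reset_index(drop=True),
            quarter_label=demo.quarter_label, anomalies=list(demo.anomalies),
        )
    }
    orphans: dict[str, int] = {}
    for kind, t in by_kind.items():
        if kind == "DEMO":
            continue
        mask = t.frame["primaryid"].isin(known)
        n_orphan = int((~mask).sum())
        if n_orphan:
            orphans[kind] = n_orphan
            log.info("%s: excluded %d orphan rows", kind, n_orphan)
        out[kind] = RawTable(
            kind, t.frame[mask].reset_index(drop=True),
            quarter_label=t.quarter_label, anomalies=list(t.anomalies),
        )
    return QuarterBundle(out, orphans)


def concat_bundles(bundles: Iterable[QuarterBundle]) -> QuarterBundle:
    """Concatenate several quarter bundles into one (row counts add)."""
    tables: list[RawTable] = []
    for b in bundles:
        tables.extend(b.tables.values())
    return assemble_quarter(tables)


#: default file names used by write_bundle / read_quarter_dir
_FILENAMES = {kind: f"{kind.lower()}.txt" for kind in TABLE_KINDS}


def write_bundle(bundle: QuarterBundle, directory: str | Path) -> Path:
    """Export a bundle as a directory of "$"-delimited files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind, table in bundle.tables.items():
        write_table(table, directory / _FILENAMES[kind])
    return directory


def read_quarter_dir(directory: str | Path, quarter_label: str = "") -> QuarterBundle:
    """Read a directory of FAERS-style files (demo.txt, drug.txt, ...)."""
    directory = Path(directory)
    tables = []
    for kind, name in _FILENAMES.items():
        p = directory / name
        if p.exists():
            tables.append(read_table(p, kind, quarter_label=quarter_label))
    return assemble_quarter(tables)
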