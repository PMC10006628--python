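"""Reading and writing the simplified tab-delimited ADAT dialect.

The dialect keeps three blocks, each introduced by a caret-prefixed header
line::

    ^SOMAMER
    somamer_id  protein_symbol  dilution_set  is_hyb_control  flagged_removed
    ...
    ^SAMPLE
    sample_id   sample_type     plate_id
    ...
    ^RFU
    sample_id   <somamer_id_1>  <somamer_id_2> ...
    <sample>    <value>         <value> ...

Tab-separated ASCII, UNIX newlines, numeric output at a configurable number
of significant digits (default 6).  Clinical and outcome tables travel as
plain TSV with a header row; the patient id is the join key across files.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, OutcomeData, SomamerTable

_SOMAMER_COLS = ["protein_symbol", "dilution_set", "is_hyb_control", "flagged_removed"]
_SAMPLE_COLS = ["sample_type", "plate_id"]


class AdatParseError(ValueError):
    """Raised when a file does not conform to the ADAT dialect."""


def _fmt(x: float, precision: int) -> str:
    return format(float(x), f".{precision}g")


def write_adat(table: SomamerTable, path, precision: int = 6) -> None:
    """Write *table* to *path* in the simplified ADAT dialect.

    Output is deterministic: block order is fixed, rows follow the table's
    own ordering, and RFU values are printed with ``precision`` significant
    digits.
    """
    table.validate()
    buf = io.StringIO()
    buf.write("^SOMAMER\n")
    buf.write("somamer_id\t" + "\t".join(_SOMAMER_COLS) + "\n")
    for sid, row in table.somamer_meta.iterrows():
        buf.write(
            f"{sid}\t{row['protein_symbol']}\t{int(row['dilution_set'])}"
            f"\t{int(bool(row['is_hyb_control']))}\t{int(bool(row['flagged_removed']))}\n"
        )
    buf.write("^SAMPLE\n")
    buf.write("sample_id\t" + "\t".join(_SAMPLE_COLS) + "\n")
    for sid, row in table.sample_meta.iterrows():
        buf.write(f"{sid}\t{row['sample_type']}\t{row['plate_id']}\n")
    buf.write("^RFU\n")
    buf.write("sample_id\t" + "\t".join(map(str, table.rfu.columns)) + "\n")
    vals = table.rfu.to_numpy()
    for i, sid in enumerate(table.rfu.index):
        buf.write(str(sid) + "\t" + "\t".join(_fmt(v, precision) for v in vals[i]) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="ascii", newline="\n")


def read_adat(path) -> SomamerTable:
    """Parse a simplified ADAT-dialect file into a validated SomamerTable."""
    lines = Path(path).read_text(encoding="ascii").splitlines()
    blocks: dict[str, list[tuple[int, str]]] = {}
    current = None
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("^"):
            current = line[1:].strip()
            blocks[current] = []
        elif current is not None and line.strip():
            blocks[current].append((lineno, line))
    for name in ("SOMAMER", "SAMPLE", "RFU"):
        if name not in blocks:
            raise AdatParseError(f"{path}: missing required ^{name} block")

    somamer_meta = _parse_meta_block(blocks["SOMAMER"], "somamer_id", _SOMAMER_COLS, path)
    somamer_meta["dilution_set"] = somamer_meta["dilution_set"].astype(int)
    somamer_meta["is_hyb_control"] = somamer_meta["is_hyb_control"].astype(int).astype(bool)
    somamer_meta["flagged_removed"] = somamer_meta["flagged_removed"].astype(int).astype(bool)
    if somamer_meta.index.has_duplicates:
        dup = somamer_meta.index[somamer_meta.index.duplicated()].unique()
        raise AdatParseError(f"{path}: duplicate somamer_id {list(dup)}")

    sample_meta = _parse_meta_block(blocks["SAMPLE"], "sample_id", _SAMPLE_COLS, path)

    rows = blocks["RFU"]
    lineno, header = rows[0]
    cols = header.split("\t")
    if cols[0] != "sample_id":
        raise AdatParseError(f"{path}:{lineno}: RFU header must start with sample_id")
    somamer_ids = cols[1:]
    data = np.empty((len(rows) - 1, len(somamer_ids)), dtype=float)
    index = []
    for i, (lineno, line) in enumerate(rows[1:]):
        parts = line.split("\t")
        if len(parts) != len(cols):
            raise AdatParseError(
                f"{path}:{lineno}: expected {len(cols)} fields, found {len(parts)}"
            )
        index.append(parts[0])
        for j, tok in enumerate(parts[1:]):
            try:
                data[i, j] = float(tok)
            except ValueError:
                raise AdatParseError(
                    f"{path}:{lineno}: non-numeric RFU {tok!r} in column "
                    f"{somamer_ids[j]!r}"
                ) from None
    if np.isnan(data).any():
        i, j = np.argwhere(np.isnan(data))[0]
        raise AdatParseError(
            f"{path}: missing RFU value at sample {index[i]!r}, "
            f"somamer {somamer_ids[j]!r}"
        )
    rfu = pd.DataFrame(data, index=pd.Index(index, name="sample_id"), columns=somamer_ids)
    try:
        return SomamerTable(rfu, somamer_meta, sample_meta)
    except ValueError as exc:
        raise AdatParseError(f"{path}: {exc}") from exc


def _parse_meta_block(rows, index_name, expected_cols, path) -> pd.DataFrame:
    lineno, header = rows[0]
    cols = header.split("\t")
    if cols[0] != index_name or cols[1:] != expected_cols:
        raise AdatParseError(
            f"{path}:{lineno}: expected header {[index_name] + expected_cols}, got {cols}"
        )
    records, index = [], []
    for lineno, line in rows[1:]:
        parts = line.split("\t")
        if len(parts) != len(cols):
            raise AdatParseError(
                f"{path}:{lineno}: expected {len(cols)} fields, found {len(parts)}"
            )
        index.append(parts[0])
        records.append(parts[1:])
    return pd.DataFrame(records, index=pd.Index(index, name=index_name), columns=expected_cols)


# ---------------------------------------------------------------------------
# clinical / outcome TSV
# ---------------------------------------------------------------------------

def write_clinical(clinical: ClinicalTable, path) -> None:
    df = clinical.values.copy()
    df.index.name = df.index.name or "patient_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_clinical(path, binary_vars=()) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return ClinicalTable(df, tuple(binary_vars))


def write_outcomes(outcomes: OutcomeData, path) -> None:
    df = outcomes.to_frame()
    df.index.name = df.index.name or "patient_id"
    df.to_csv(path, sep="\t")


def read_outcomes(path) -> OutcomeData:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OutcomeData(df["time"], df["cause"])
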