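"""File I/O: FASTA sequences, measurement/readings tables, plan output."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .balancing import SignalReading
from .errors import AlphabetError, InputError, SchemaError
from .fragment_quant import ConcentrationMeasurement


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read DNA records: (id up to first whitespace, uppercased sequence).

    RNA (``U``) is rejected — templates are double-stranded DNA. An empty
    file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(
            i + 1 for i, line in enumerate(text.splitlines()) if line.strip()
        )
        raise SchemaError(f"{path}: not FASTA (line {first_bad} is not a header)")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise AlphabetError(f"{path}: record {rec.id} contains U (RNA?)")
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_measurements(path: str | Path) -> list[ConcentrationMeasurement]:
    """Read a wide replicate table: fragment_id, rep1..repN (ng/µL).

    Missing cells are permitted and dropped per fragment.
    """
    df = pd.read_csv(path)
    if "fragment_id" not in df.columns:
        raise SchemaError(f"{path}: missing 'fragment_id' column")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise SchemaError(f"{path}: no replicate columns (rep1..repN)")
    out = []
    for _, row in df.iterrows():
        reps = tuple(float(row[c]) for c in rep_cols if pd.notna(row[c]))
        if not reps:
            raise SchemaError(
                f"{path}: fragment {row['fragment_id']!r} has no replicate values"
            )
        out.append(ConcentrationMeasurement(str(row["fragment_id"]), reps))
    return out


def read_readings(path: str | Path) -> list[SignalReading]:
    """Read a long RFU table: target, copies, condition, replicate, rfu."""
    df = pd.read_csv(path)
    required = {"target", "copies", "condition", "replicate", "rfu"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return [
        SignalReading(
            target_name=str(r["target"]),
            template_copies=float(r["copies"]),
            condition=str(r["condition"]),
            replicate=int(r["replicate"]),
            rfu=float(r["rfu"]),
        )
        for _, r in df.iterrows()
    ]
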