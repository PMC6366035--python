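"""Readers and writers for the package's plain-text formats.

* FASTA for UTR / mature / precursor sequences (Biopython).
* Vienna-style structure files: id line, sequence line, dot-bracket line.
* Long-format site-count tables: TSV with columns
  mirna_id, transcript_id, algorithm, count.
* Expression matrices: TSV with a 2-row header — first row sample ids,
  second row ``condition:time_h`` per sample.
* Fitted models and synthetic-truth sidecars as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import DataError, SequenceParseError
from .expression import ExpressionMatrix
from .interaction import COUNT_TABLE_COLUMNS, WeightedTargetMatrix, validate_count_table
from .model import FittedModel


# ---------------------------------------------------------------- sequences

def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_vienna(path) -> tuple[dict[str, str], dict[str, str]]:
    """Vienna structure file -> (sequences, dot-bracket structures).

    Each record is three lines: ``>id``, sequence, structure.
    """
    sequences: dict[str, str] = {}
    structures: dict[str, str] = {}
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise SequenceParseError(f"expected '>' header at line {i + 1} of {path}")
        if i + 2 >= len(lines):
            raise SequenceParseError(f"truncated record at end of {path}")
        name = lines[i][1:].split()[0]
        sequences[name] = lines[i + 1].upper()
        structures[name] = lines[i + 2].split()[0]
        i += 3
    return sequences, structures


def write_vienna(sequences: dict[str, str], structures: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n{structures[name]}\n")


# ------------------------------------------------------------- count tables

def read_count_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"count": np.int64})
    return validate_count_table(table)


def write_count_table(table: pd.DataFrame, path) -> None:
    validate_count_table(table)
    table.to_csv(path, sep="\t", index=False, columns=list(COUNT_TABLE_COLUMNS))


def write_weighted_matrix(matrix: WeightedTargetMatrix, path, dense: bool = False) -> None:
    """Write C' as a sparse triplet table (or a dense matrix with ``dense``)."""
    if dense:
        matrix.to_frame().rename_axis("transcript_id").to_csv(path, sep="\t")
        return
    rows, cols = np.nonzero(matrix.values)
    pd.DataFrame(
        {
            "transcript_id": [matrix.transcript_ids[r] for r in rows],
            "mirna_id": [matrix.mirna_ids[c] for c in cols],
            "weight": matrix.values[rows, cols],
        }
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------- expression matrices

def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        samples = list(expr.values.columns)
        fh.write("feature_id\t" + "\t".join(samples) + "\n")
        meta = [
            f"{expr.sample_meta.loc[s, 'condition']}:{expr.sample_meta.loc[s, 'time_h']}"
            for s in samples
        ]
        fh.write("#condition:time_h\t" + "\t".join(meta) + "\n")
        expr.values.to_csv(fh, sep="\t", header=False)


def read_expression_matrix(path, gene_map: pd.Series | None = None) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        meta_line = fh.readline().rstrip("\n").split("\t")
        if not meta_line or not meta_line[0].startswith("#"):
            raise DataError(f"{path}: missing metadata header row")
        values = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    samples = header[1:]
    values.columns = samples
    values.index.name = "feature_id"
    conditions, times = [], []
    for cell in meta_line[1:]:
        condition, _, time_h = cell.partition(":")
        conditions.append(condition)
        times.append(float(time_h) if time_h else 0.0)
    meta = pd.DataFrame({"condition": conditions, "time_h": times}, index=samples)
    return ExpressionMatrix(values, meta, gene_map)


# --------------------------------------------------------------------- JSON

def write_fitted_model(model: FittedModel, path) -> None:
    payload = {
        "dk": {m: float(v) for m, v in zip(model.mirna_ids, model.dk)},
        "b0": model.b0,
        "rho_train": model.rho_train,
        "rank_of_design": model.rank_of_design,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fitted_model(path) -> FittedModel:
    payload = json.loads(Path(path).read_text())
    mirna_ids = list(payload["dk"])
    return FittedModel(
        dk=np.array([payload["dk"][m] for m in mirna_ids]),
        b0=float(payload["b0"]),
        mirna_ids=mirna_ids,
        rho_train=float(payload["rho_train"]),
        rank_of_design=int(payload.get("rank_of_design", 0)),
    )
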