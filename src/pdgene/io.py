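"""Readers and writers for the curated-evidence TSV dialects.

One dialect per layer: UTF-8, tab-separated, one header row, lines starting
with ``#`` ignored. Missing optional values are written as empty cells and
read back as ``None``; ``NA`` (any case) is also accepted on input. Every
malformed cell raises a located error naming its data row (1-based, comment
lines not counted) and column — no row is ever silently dropped.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from .records import (
    ASSOCIATION_LAYERS,
    AssociationRecord,
    CNVRecord,
    CNVType,
    Consequence,
    Direction,
    EvidenceRecord,
    Layer,
    ValidationError,
    VariantRecord,
)

#: Column order of each layer's TSV schema (also the write order).
LAYER_COLUMNS: Dict[Layer, List[str]] = {
    Layer.RARE_VARIANT: [
        "gene", "chrom", "pos", "ref", "alt", "consequence",
        "maf", "patho_score", "study_id", "patient_id", "aao",
    ],
    Layer.CNV: ["gene", "cnv_type", "study_id"],
    Layer.GWAS_SNP: ["gene", "p_value", "marker_id", "direction", "study_id"],
    Layer.DEG: ["gene", "p_value", "marker_id", "direction", "study_id"],
    Layer.DMG: ["gene", "p_value", "marker_id", "direction", "study_id"],
}

_MISSING = {"", "na", "nan", "none", "."}


class ParseError(ValueError):
    """A cell could not be parsed; names the data row and column."""

    def __init__(self, message: str, row: int, column: str):
        super().__init__(f"{message} (row {row}, column {column!r})")
        self.row = row
        self.column = column


def _opt_str(cell: str) -> Optional[str]:
    return None if cell.strip().lower() in _MISSING else cell.strip()


def _opt_float(cell: str, row: int, column: str) -> Optional[float]:
    s = cell.strip()
    if s.lower() in _MISSING:
        return None
    try:
        return float(s)
    except ValueError:
        raise ParseError(f"expected a number, got {s!r}", row, column) from None


def _req_float(cell: str, row: int, column: str) -> float:
    val = _opt_float(cell, row, column)
    if val is None:
        raise ParseError("value required", row, column)
    return val


def _req_int(cell: str, row: int, column: str) -> int:
    s = cell.strip()
    try:
        return int(s)
    except ValueError:
        raise ParseError(f"expected an integer, got {s!r}", row, column) from None


def _enum(cls, cell: str, row: int, column: str, default=None):
    s = cell.strip().lower()
    if s in _MISSING and default is not None:
        return default
    try:
        return cls(s)
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise ValidationError(
            f"unknown {column} label {cell.strip()!r}; expected one of: {valid}",
            row=row, column=column,
        ) from None


def _iter_rows(path: Union[str, Path], layer: Layer):
    """Yield (data_row_number, {column: cell}) for each non-comment row."""
    columns = LAYER_COLUMNS[layer]
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file: missing header", 0, columns[0]) from None
        missing = [c for c in columns if c not in header]
        if missing:
            raise ValidationError(
                f"header missing required column(s) {missing} for layer "
                f"{layer.value!r}; found {header}"
            )
        pos = {c: header.index(c) for c in columns}
        for i, cells in enumerate(reader, start=1):
            if not any(c.strip() for c in cells):
                continue
            yield i, {c: (cells[j] if j < len(cells) else "") for c, j in pos.items()}


def read_evidence_table(path: Union[str, Path], layer: Union[Layer, str]) -> List[EvidenceRecord]:
    """Read one layer's TSV into validated records.

    Parameters
    ----------
    path
        TSV file following the layer's documented schema.
    layer
        Which of the five layer dialects to expect.

    Raises
    ------
    ParseError
        A numeric cell is malformed (names row and column).
    ValidationError
        A cell violates a record invariant or uses an unknown enum label.
    """
    layer = Layer(layer)
    records: List[EvidenceRecord] = []
    for row, c in _iter_rows(path, layer):
        try:
            if layer is Layer.RARE_VARIANT:
                rec: EvidenceRecord = VariantRecord(
                    gene=c["gene"].strip(),
                    chrom=c["chrom"].strip(),
                    pos=_req_int(c["pos"], row, "pos"),
                    ref=c["ref"].strip(),
                    alt=c["alt"].strip(),
                    consequence=_enum(Consequence, c["consequence"], row, "consequence"),
                    maf=_opt_float(c["maf"], row, "maf"),
                    patho_score=_opt_float(c["patho_score"], row, "patho_score"),
                    study_id=c["study_id"].strip(),
                    patient_id=_opt_str(c["patient_id"]),
                    aao=_opt_float(c["aao"], row, "aao"),
                )
            elif layer is Layer.CNV:
                rec = CNVRecord(
                    gene=c["gene"].strip(),
                    cnv_type=_enum(CNVType, c["cnv_type"], row, "cnv_type",
                                   default=CNVType.UNKNOWN),
                    study_id=c["study_id"].strip(),
                )
            else:
                rec = AssociationRecord(
                    gene=c["gene"].strip(),
                    layer_tag=layer,
                    p_value=_req_float(c["p_value"], row, "p_value"),
                    marker_id=_opt_str(c["marker_id"]),
                    direction=_enum(Direction, c["direction"], row, "direction",
                                    default=Direction.NA),
                    study_id=c["study_id"].strip(),
                )
        except ValidationError as err:
            if err.row is None:
                raise ValidationError(str(err), row=row) from None
            raise
        records.append(rec)
    return records


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, (Layer, Consequence, CNVType, Direction)):
        return value.value
    if isinstance(value, float):
        return repr(value)  # shortest round-trippable form
    return str(value)


def write_evidence_table(
    records: Sequence[EvidenceRecord],
    path: Union[str, Path],
    layer: Union[Layer, str, None] = None,
) -> None:
    """Write records of one layer to TSV; lossless under :func:`read_evidence_table`.

    ``layer`` is inferred from the records when omitted; it must be given to
    write a header-only file from an empty list.

    Raises
    ------
    ValueError
        Records from more than one layer are mixed in one table, or the
        records contradict an explicit ``layer``.
    """
    if not records:
        if layer is None:
            raise ValueError(
                "cannot infer layer from an empty record list; pass layer="
            )
        return write_empty_table(path, layer)
    layers = {r.layer for r in records}
    if layer is not None and layers != {Layer(layer)}:
        raise ValueError(
            f"records are layer {sorted(l.value for l in layers)} but "
            f"layer={Layer(layer).value!r} was requested"
        )
    if len(layers) > 1:
        raise ValueError(
            f"records mix layers {sorted(l.value for l in layers)}; "
            "one table holds one layer"
        )
    layer = records[0].layer
    columns = LAYER_COLUMNS[layer]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for r in records:
            if isinstance(r, AssociationRecord):
                values = {
                    "gene": r.gene, "p_value": r.p_value, "marker_id": r.marker_id,
                    "direction": r.direction, "study_id": r.study_id,
                }
            else:
                values = {cname: getattr(r, cname) for cname in columns}
            writer.writerow([_cell(values[cname]) for cname in columns])


def write_empty_table(path: Union[str, Path], layer: Union[Layer, str]) -> None:
    """Write a header-only table for the given layer."""
    layer = Layer(layer)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(LAYER_COLUMNS[layer]) + "\n")
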