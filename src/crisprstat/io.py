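"""Reading and writing the tabular dialects of the pipeline.

Two TSV inputs drive every analysis: an *array table* (one row per CRISPR
array, emulating a CRISPRdb complete-genome export) and a *cas table* (one
row per cas1-anchored operon, emulating the 2015 classification supplement).
Neither upstream resource publishes a fixed file schema, so this module owns
a canonical dialect for each and a pluggable column-mapping layer
(:func:`register_array_dialect` / :func:`register_cas_dialect`) for real
exports whose headers differ.

Reading is strict: a missing column raises :class:`SchemaError` naming the
column, and any cell that violates a record invariant raises
:class:`RowValidationError` carrying the 1-based file row.  Reading never
filters — questionable arrays and plasmid loci are kept so that filtering
remains an explicit, testable step.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .records import (
    ArrayRecord,
    CasOperon,
    IntegratedSystem,
    ValidationError,
    VALID_CLASSES,
    VALID_TYPES,
)

ARRAY_COLUMNS = (
    "accession",
    "organism",
    "replicon_kind",
    "replicon_length",
    "array_id",
    "start_bp",
    "end_bp",
    "n_spacers",
    "strand",
    "questionable",
)

CAS_COLUMNS = (
    "accession",
    "system_class",
    "system_type",
    "subtype",
    "operon_start_bp",
    "operon_end_bp",
    "strand",
    "has_cas1",
)

# dialect name -> {canonical column: column name in file}
_ARRAY_DIALECTS: Dict[str, Dict[str, str]] = {
    "canonical": {c: c for c in ARRAY_COLUMNS},
}
_CAS_DIALECTS: Dict[str, Dict[str, str]] = {
    "canonical": {c: c for c in CAS_COLUMNS},
}


class SchemaError(ValueError):
    """The file header does not expose a mandatory column."""


class RowValidationError(ValueError):
    """A data row violates a record invariant; carries the file row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


def register_array_dialect(name: str, mapping: Dict[str, str]) -> None:
    """Register a column mapping {canonical name: file column name}."""
    missing = set(ARRAY_COLUMNS) - set(mapping)
    if missing:
        raise SchemaError(f"dialect {name!r} lacks mappings for {sorted(missing)}")
    _ARRAY_DIALECTS[name] = dict(mapping)


def register_cas_dialect(name: str, mapping: Dict[str, str]) -> None:
    missing = set(CAS_COLUMNS) - set(mapping)
    if missing:
        raise SchemaError(f"dialect {name!r} lacks mappings for {sorted(missing)}")
    _CAS_DIALECTS[name] = dict(mapping)


def _load_frame(path, mapping: Dict[str, str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [file_col for file_col in mapping.values() if file_col not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    inverse = {v: k for k, v in mapping.items()}
    return df.rename(columns=inverse)[list(inverse.values())]


def _parse_int(value: str, name: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValidationError(f"{name} must be an integer, got {value!r}")


def _parse_bool(value: str, name: str) -> bool:
    if value in ("0", "1"):
        return value == "1"
    raise ValidationError(f"{name} must be 0 or 1, got {value!r}")


def read_array_table(path, dialect: str = "canonical") -> List[ArrayRecord]:
    """Read an array table, validating every row; row order is preserved."""
    mapping = _ARRAY_DIALECTS[dialect]
    df = _load_frame(path, mapping)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                ArrayRecord(
                    accession=row.accession,
                    organism=row.organism,
                    replicon_kind=row.replicon_kind,
                    replicon_length=_parse_int(row.replicon_length, "replicon_length"),
                    array_id=row.array_id,
                    start_bp=_parse_int(row.start_bp, "start_bp"),
                    end_bp=_parse_int(row.end_bp, "end_bp"),
                    n_spacers=_parse_int(row.n_spacers, "n_spacers"),
                    strand=row.strand,
                    questionable=_parse_bool(row.questionable, "questionable"),
                )
            )
        except ValidationError as exc:
            # +2: one for the header line, one for 1-based numbering
            raise RowValidationError(i + 2, str(exc)) from exc
    _check_unique_array_ids(records)
    return records


def _check_unique_array_ids(records: Sequence[ArrayRecord]) -> None:
    seen = set()
    for rec in records:
        key = (rec.accession, rec.array_id)
        if key in seen:
            raise ValidationError(
                f"duplicate array_id {rec.array_id!r} on {rec.accession}"
            )
        seen.add(key)


def read_cas_table(path, dialect: str = "canonical") -> List[CasOperon]:
    """Read a cas table; accessions listed repeatedly yield multiple operons."""
    mapping = _CAS_DIALECTS[dialect]
    df = _load_frame(path, mapping)
    operons = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            try:
                system_class = int(row.system_class)
            except ValueError:
                system_class = -1
            if system_class not in VALID_CLASSES:
                raise ValidationError(
                    f"system_class {row.system_class!r} not among "
                    f"accepted tokens {sorted(VALID_CLASSES)}"
                )
            if row.system_type not in VALID_TYPES:
                raise ValidationError(
                    f"system_type {row.system_type!r} not among "
                    f"accepted tokens {sorted(VALID_TYPES)}"
                )
            operons.append(
                CasOperon(
                    accession=row.accession,
                    system_class=system_class,
                    system_type=row.system_type,
                    subtype=row.subtype or None,
                    operon_start_bp=_parse_int(row.operon_start_bp, "operon_start_bp"),
                    operon_end_bp=_parse_int(row.operon_end_bp, "operon_end_bp"),
                    strand=row.strand,
                    has_cas1=_parse_bool(row.has_cas1, "has_cas1"),
                )
            )
        except ValidationError as exc:
            raise RowValidationError(i + 2, str(exc)) from exc
    return operons


def _array_row(rec: ArrayRecord) -> List[str]:
    return [
        rec.accession,
        rec.organism,
        rec.replicon_kind,
        str(rec.replicon_length),
        rec.array_id,
        str(rec.start_bp),
        str(rec.end_bp),
        str(rec.n_spacers),
        rec.strand,
        "1" if rec.questionable else "0",
    ]


def _cas_row(op: CasOperon) -> List[str]:
    return [
        op.accession,
        str(op.system_class),
        op.system_type,
        op.subtype or "",
        str(op.operon_start_bp),
        str(op.operon_end_bp),
        op.strand,
        "1" if op.has_cas1 else "0",
    ]


def _write_tsv(path, header: Sequence[str], rows) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_array_table(records: Sequence[ArrayRecord], path) -> None:
    """Write the canonical dialect; inverse of :func:`read_array_table`."""
    _write_tsv(path, ARRAY_COLUMNS, (_array_row(r) for r in records))


def write_cas_table(operons: Sequence[CasOperon], path) -> None:
    _write_tsv(path, CAS_COLUMNS, (_cas_row(o) for o in operons))


INTEGRATED_COLUMNS = (
    "accession",
    "system_class",
    "system_type",
    "subtype",
    "operon_start_bp",
    "operon_end_bp",
    "operon_strand",
    "proximal_array_id",
    "proximal_start_bp",
    "proximal_end_bp",
    "proximal_n_spacers",
    "proximal_strand",
    "distance_bp",
    "n_arrays_on_replicon",
)


def write_integrated_table(systems: Sequence[IntegratedSystem], path) -> None:
    """One row per operon-array pairing, in the order systems were built."""
    rows = (
        [
            s.accession,
            str(s.operon.system_class),
            s.operon.system_type,
            s.operon.subtype or "",
            str(s.operon.operon_start_bp),
            str(s.operon.operon_end_bp),
            s.operon.strand,
            s.proximal_array.array_id,
            str(s.proximal_array.start_bp),
            str(s.proximal_array.end_bp),
            str(s.proximal_array.n_spacers),
            s.proximal_array.strand,
            str(s.distance_bp),
            str(s.n_arrays_on_replicon),
        ]
        for s in systems
    )
    _write_tsv(path, INTEGRATED_COLUMNS, rows)


def write_unpaired_report(unpaired: Sequence[CasOperon], path) -> None:
    """JSON sidecar of operons whose accession carries no array."""
    payload = [
        {
            "accession": op.accession,
            "system_class": op.system_class,
            "system_type": op.system_type,
            "subtype": op.subtype,
            "operon_start_bp": op.operon_start_bp,
            "operon_end_bp": op.operon_end_bp,
        }
        for op in unpaired
    ]
    with open(path, "w") as fh:
        json.dump({"n_unpaired": len(payload), "operons": payload}, fh, indent=2)
        fh.write("\n")


def arrays_to_frame(records: Sequence[ArrayRecord]) -> pd.DataFrame:
    return pd.DataFrame([_array_row(r) for r in records], columns=ARRAY_COLUMNS)


def cas_to_frame(operons: Sequence[CasOperon]) -> pd.DataFrame:
    return pd.DataFrame([_cas_row(o) for o in operons], columns=CAS_COLUMNS)
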