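"""Reading and writing of on-disk artifacts with strict validation.

Count matrices and expression matrices are tab-separated tables whose first
column holds the entity identifier (miRNA name) and whose remaining columns
are one sequencing library each.  Library metadata (condition, stage in days
after flowering, total clean reads) comes as TSV or JSON.  Candidate and
annotation sequences are plain FASTA.

All malformed input raises :class:`ParseError` naming the offending row or
column — nothing is silently coerced.  In particular a missing cell is an
error, not a zero: "not expressed" (count 0) and "absent datum" are distinct
states, and conflating them would corrupt the downstream 0.01-TPM floor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

CONDITIONS = ("superior", "inferior")

#: Significant digits used when rendering floats to disk.
FLOAT_DIGITS = 6


class ParseError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


@dataclass(frozen=True)
class LibraryMeta:
    """One sequencing library of the two-condition, multi-stage design.

    ``total_clean_reads`` is the library-size denominator used both for TPM
    normalization and as N1/N2 in the exact two-library count test.  Whether
    "total clean reads" counts redundant reads or distinct tags is a choice
    the caller makes when supplying the number; the package uses whatever is
    given, consistently, for both purposes.
    """

    library_id: str
    condition: str
    stage_daf: int
    total_clean_reads: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ParseError(
                f"library {self.library_id!r}: unknown condition "
                f"{self.condition!r} (expected one of {CONDITIONS})"
            )
        if self.stage_daf <= 0:
            raise ParseError(
                f"library {self.library_id!r}: stage_daf must be a positive "
                f"integer, got {self.stage_daf}"
            )
        if self.total_clean_reads <= 0:
            raise ParseError(
                f"library {self.library_id!r}: total_clean_reads must be "
                f"positive, got {self.total_clean_reads}"
            )


# A CountMatrix is a pandas DataFrame with a unique string index of entity
# ids, one column per library, and non-negative integer values.  An
# ExpressionMatrix has the same shape with non-negative float (TPM) values.
# They are plain DataFrames so the whole pandas toolbox applies; the
# constructors below are validating factories, not wrapper classes.
CountMatrix = pd.DataFrame
ExpressionMatrix = pd.DataFrame


def _validate_frame(df: pd.DataFrame, source: str) -> None:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{source}: duplicate entity_id(s) {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{source}: duplicate library column(s) {dupes}")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise ParseError(
            f"{source}: missing cell(s) in row(s) {rows}; absent data must "
            "be stated explicitly, not left blank"
        )
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{source}: negative values are not permitted")


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV raw-count table (entities x libraries, integer cells).

    The header row carries library ids; the first column entity ids.  Lines
    starting with ``#`` are comments.  Row and column order of the file is
    preserved.  Non-integer cells, duplicate ids and missing cells raise
    :class:`ParseError`.
    """
    path = Path(path)
    df = _read_table(path)
    _validate_frame(df, path.name)  # missing cells diagnosed before typing
    for col in df.columns:
        for entity, value in df[col].items():
            if isinstance(value, float) and not float(value).is_integer():
                raise ParseError(
                    f"{path.name}: non-integer count {value!r} at "
                    f"row {entity!r}, column {col!r}"
                )
    df = df.astype("int64")
    _validate_frame(df, path.name)
    return df


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV TPM table; same dialect as :func:`read_count_matrix`."""
    path = Path(path)
    df = _read_table(path).astype(float)
    _validate_frame(df, path.name)
    return df


def _read_table(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"{path.name}: cannot parse table: {exc}") from exc
    if df.columns.size == 0:
        raise ParseError(f"{path.name}: no library columns found in header")
    df.index = df.index.astype(str)
    out = {}
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path.name}: non-numeric cell in column {col!r}: {exc}"
            ) from exc
    res = pd.DataFrame(out, index=df.index)
    res.index.name = df.index.name or "entity_id"
    return res


def read_metadata(path: str | Path) -> list[LibraryMeta]:
    """Read library metadata from TSV or JSON.

    Required fields per record: ``library_id``, ``condition``
    (superior/inferior), ``stage_daf``, ``total_clean_reads``.  Records are
    returned sorted by condition then ascending stage; duplicate library ids
    and unknown condition tokens are errors.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ParseError(f"{path.name}: JSON metadata must be a list")
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"library_id", "condition", "stage_daf", "total_clean_reads"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"{path.name}: missing metadata column(s) {sorted(missing)}")
        records = df.to_dict("records")

    metas = []
    for rec in records:
        try:
            metas.append(
                LibraryMeta(
                    library_id=str(rec["library_id"]),
                    condition=str(rec["condition"]),
                    stage_daf=int(rec["stage_daf"]),
                    total_clean_reads=int(rec["total_clean_reads"]),
                )
            )
        except KeyError as exc:
            raise ParseError(f"{path.name}: metadata record missing field {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path.name}: malformed metadata record {rec!r}: {exc}") from exc
    ids = [m.library_id for m in metas]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"{path.name}: duplicate library_id(s) {dupes}")
    metas.sort(key=lambda m: (m.condition, m.stage_daf))
    return metas


def check_totals(counts: CountMatrix, meta: Sequence[LibraryMeta]) -> None:
    """Verify each library's total_clean_reads covers its column sum."""
    by_id = {m.library_id: m for m in meta}
    for col in counts.columns:
        m = by_id.get(col)
        if m is None:
            raise ParseError(f"no metadata for library column {col!r}")
        colsum = int(counts[col].sum())
        if colsum > m.total_clean_reads:
            raise ParseError(
                f"library {col!r}: column sum {colsum} exceeds "
                f"total_clean_reads {m.total_clean_reads}"
            )


def write_results(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as TSV with stable column order.

    Floats are rendered with :data:`FLOAT_DIGITS` significant digits so the
    file round-trips losslessly at that precision; integer and string
    columns are untouched.  An empty table yields a header-only file.
    """
    path = Path(path)
    out = records.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(_format_float)
    out.to_csv(path, sep="\t", index=records.index.name is not None)
    return path


def _format_float(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "nan"
    return f"{x:.{FLOAT_DIGITS}g}"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: uppercase sequence}`` map."""
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path.name}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def validate_design(
    meta: Iterable[LibraryMeta],
    stages: Sequence[int] = (10, 15, 21, 27, 35),
) -> dict[int, dict[str, LibraryMeta]]:
    """Check a one-library-per-condition-per-stage design and index it.

    Returns ``{stage: {"superior": meta, "inferior": meta}}`` and raises
    :class:`ParseError` when a stage lacks exactly one library of each
    condition.
    """
    table: dict[int, dict[str, LibraryMeta]] = {s: {} for s in stages}
    for m in meta:
        if m.stage_daf not in table:
            raise ParseError(
                f"library {m.library_id!r}: stage {m.stage_daf} DAF is not in "
                f"the declared design {tuple(stages)}"
            )
        if m.condition in table[m.stage_daf]:
            raise ParseError(
                f"stage {m.stage_daf} DAF: more than one {m.condition} library"
            )
        table[m.stage_daf][m.condition] = m
    for stage, pair in table.items():
        if set(pair) != set(CONDITIONS):
            raise ParseError(
                f"stage {stage} DAF: need exactly one superior and one "
                f"inferior library, got {sorted(pair)}"
            )
    return table
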