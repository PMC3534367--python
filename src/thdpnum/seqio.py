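"""Sequence and alignment I/O.

Reads unaligned FASTA, aligned FASTA and Stockholm, and writes the tool's
numbered-residue TSV.  Parsing is delegated to Biopython; this module adds
the validation the numbering pipeline depends on: a closed 21-letter
alphabet, unique ids, equal-length alignment rows and gap normalisation.

Gap dialects: ``-`` and ``.`` are accepted on input, ``-`` only on output.
Ambiguity codes B/Z/U/O/J are folded to ``X`` with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from ._alphabet import ALPHABET, FOLD_TO_X, GAP, UNKNOWN
from .errors import InputError

logger = logging.getLogger(__name__)

_VALID = set(ALPHABET)
_VALID_ALIGNED = _VALID | {GAP}


@dataclass(frozen=True)
class SequenceRecord:
    """An unaligned protein sequence over the 20 amino acids plus X."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise InputError(f"invalid sequence id {self.id!r}")
        if not self.residues:
            raise InputError(f"sequence {self.id!r} is empty")
        bad = next((i for i, c in enumerate(self.residues) if c not in _VALID), None)
        if bad is not None:
            raise InputError(
                f"sequence {self.id!r}: invalid character "
                f"{self.residues[bad]!r} at offset {bad + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows; no all-gap columns after normalisation."""

    records: tuple  # tuple[AlignedRow, ...]; see AlignedRow below
    n_columns: int = field(init=False, default=0)

    def __post_init__(self):
        if not self.records:
            raise InputError("alignment has no rows")
        ncol = len(self.records[0].residues)
        ragged = [r.id for r in self.records if len(r.residues) != ncol]
        if ragged:
            raise InputError(f"alignment rows differ in length: {', '.join(ragged)}")
        object.__setattr__(self, "n_columns", ncol)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, seq_id: str) -> "AlignedRow":
        for r in self.records:
            if r.id == seq_id:
                return r
        raise InputError(f"id {seq_id!r} not present in alignment")

    def ungapped(self, seq_id: str) -> SequenceRecord:
        r = self.row(seq_id)
        return SequenceRecord(id=r.id, residues=r.residues.replace(GAP, ""),
                              description=r.description)


@dataclass(frozen=True)
class AlignedRow:
    """One row of a multiple alignment (gaps allowed)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise InputError(f"invalid sequence id {self.id!r}")
        bad = next((i for i, c in enumerate(self.residues)
                    if c not in _VALID_ALIGNED), None)
        if bad is not None:
            raise InputError(
                f"alignment row {self.id!r}: invalid character "
                f"{self.residues[bad]!r} at column {bad + 1}"
            )
        if not self.residues.replace(GAP, ""):
            raise InputError(f"alignment row {self.id!r} contains no residues")


def _normalise(raw: str, rec_id: str, *, aligned: bool) -> str:
    """Upper-case, strip '*', fold ambiguity codes, normalise gap dialects."""
    s = raw.upper()
    if "*" in s:
        warnings.warn(f"sequence {rec_id!r}: stripped '*' stop character(s)")
        s = s.replace("*", "")
    if aligned:
        s = s.replace(".", GAP)
    if any(c in FOLD_TO_X for c in s):
        warnings.warn(f"sequence {rec_id!r}: ambiguity codes mapped to X")
        s = "".join(UNKNOWN if c in FOLD_TO_X else c for c in s)
    return s


def _check_unique_ids(ids: Sequence[str], path) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise InputError(f"{path}: duplicate id {i!r}")
        seen.add(i)


def read_fasta(path) -> list[SequenceRecord]:
    """Read unaligned FASTA. Gap characters in the input are an error."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        raw = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as e:
        raise InputError(f"{path}: {e}") from e
    if not raw:
        raise InputError(f"{path}: no FASTA records found")
    _check_unique_ids([r.id for r in raw], path)
    out = []
    for r in raw:
        s = _normalise(str(r.seq), r.id, aligned=False)
        if GAP in s or "." in s:
            raise InputError(f"{path}: gap character in unaligned record {r.id!r}")
        try:
            out.append(SequenceRecord(id=r.id, residues=s, description=r.description))
        except InputError as e:
            raise InputError(f"{path}: {e}") from e
    return out


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(header + "\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i:i + width] + "\n")


def _drop_allgap_columns(rows: list[AlignedRow]) -> list[AlignedRow]:
    ncol = len(rows[0].residues)
    keep = [c for c in range(ncol)
            if any(r.residues[c] != GAP for r in rows)]
    dropped = ncol - len(keep)
    if dropped:
        logger.info("removed %d all-gap column(s)", dropped)
        rows = [AlignedRow(id=r.id,
                           residues="".join(r.residues[c] for c in keep),
                           description=r.description)
                for r in rows]
    return rows


def read_alignment(path, format: str = "fasta") -> MultipleAlignment:
    """Read an aligned-FASTA or Stockholm multiple alignment.

    '.' and '-' both normalise to '-'; all-gap columns are removed (the
    removal count is logged); ragged rows raise an error naming the ids.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    fmt = {"fasta": "fasta", "aligned-fasta": "fasta",
           "stockholm": "stockholm"}.get(format)
    if fmt is None:
        raise InputError(f"unknown alignment format {format!r}")
    try:
        raw = list(SeqIO.parse(str(path), fmt))
    except ValueError as e:
        raise InputError(f"{path}: {e}") from e
    if not raw:
        raise InputError(f"{path}: no alignment rows found")
    _check_unique_ids([r.id for r in raw], path)
    rows = []
    for r in raw:
        s = _normalise(str(r.seq), r.id, aligned=True)
        try:
            rows.append(AlignedRow(id=r.id, residues=s, description=r.description))
        except InputError as e:
            raise InputError(f"{path}: {e}") from e
    lengths = {len(r.residues) for r in rows}
    if len(lengths) > 1:
        ragged = [r.id for r in rows
                  if len(r.residues) != len(rows[0].residues)]
        raise InputError(f"{path}: alignment rows differ in length: "
                         f"{', '.join(ragged)}")
    rows = _drop_allgap_columns(rows)
    return MultipleAlignment(records=tuple(rows))


def write_alignment(msa: MultipleAlignment, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in msa.records:
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(header + "\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i:i + width] + "\n")


def write_numbered(numbered, path) -> None:
    """Write a numbered sequence as TSV.

    Columns: query_index (1-based), amino acid, standard number (or '-'),
    insertion code (or empty), semicolon-joined annotations.  Header comment
    lines carry the query id, reference id, profile checksum and gate score.
    """
    with open(path, "w") as fh:
        fh.write(f"# query_id\t{numbered.query.id}\n")
        fh.write(f"# reference_id\t{numbered.reference_id}\n")
        fh.write(f"# profile_checksum\t{numbered.profile_checksum}\n")
        fh.write(f"# gate_score_bits\t{numbered.gate_score:.4f}\n")
        fh.write("query_index\tamino_acid\tstandard_number\t"
                 "insertion_code\tannotations\n")
        for row in numbered.rows():
            fh.write("\t".join(row) + "\n")
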