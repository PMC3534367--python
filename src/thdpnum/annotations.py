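"""Curated standard-position annotations and domain definitions.

The packaged defaults cover the functionally and structurally relevant
positions of the reference pyruvate decarboxylase (ScPDC) that are well
established in the literature: the catalytic glutamate E51, the HH motif
(114/115), the GDGX cofactor-binding motif (443-446), the Mg2+ site N471,
the S-pocket (26, 27, 476, 477), the effector binding site 221, the
activation loop 286-304 and the PYR/TH3/PP domain anchors.  Users extend
the table via a simple TSV format (position, label, provenance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError


@dataclass
class AnnotationTable:
    """standard position -> {label: provenance}."""

    _entries: dict = field(default_factory=dict)

    def add(self, position: int, label: str, provenance: str = "") -> None:
        if position < 1:
            raise InputError(f"annotation position must be >= 1, got {position}")
        if not label:
            raise InputError("annotation label must be non-empty")
        self._entries.setdefault(int(position), {})[label] = provenance

    def lookup(self, position: int) -> set[str]:
        """Labels at a standard position; empty set if none."""
        return set(self._entries.get(position, {}))

    def provenance(self, position: int, label: str) -> str:
        return self._entries.get(position, {}).get(label, "")

    def positions(self) -> list[int]:
        return sorted(self._entries)

    def items(self):
        for pos in self.positions():
            for label, prov in sorted(self._entries[pos].items()):
                yield pos, label, prov

    def __len__(self) -> int:
        return sum(len(v) for v in self._entries.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationTable) and \
            self._entries == other._entries


@dataclass(frozen=True)
class DomainDefinition:
    """A structural domain delimited by standard positions."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if self.name not in ("PYR", "TH3", "PP"):
            raise InputError(f"unknown domain name {self.name!r}")
        if not self.start < self.end:
            raise InputError(f"domain {self.name}: start must precede end")


def default_domains() -> list[DomainDefinition]:
    """PYR/TH3/PP boundaries in standard numbering.

    The TH3 termini are structurally variable, so the working anchors sit
    four positions inside the structural start and five inside the
    structural end; both variants are returned (same domain name, the
    shifted anchors are the canonical ones used by the annotations).
    """
    return [
        DomainDefinition("PYR", 6, 168),
        DomainDefinition("TH3", 197, 336),   # gap-free shifted anchors
        DomainDefinition("TH3", 193, 341),   # structural boundaries
        DomainDefinition("PP", 367, 540),
    ]


def default_annotations() -> AnnotationTable:
    """The packaged annotation set (main-text literature positions)."""
    t = AnnotationTable()
    lit = "literature"
    t.add(51, "active site glutamate", lit)
    t.add(114, "HH motif", lit)
    t.add(115, "HH motif", lit)
    for p in (443, 444, 445, 446):
        t.add(p, "GDGX motif", lit)
    t.add(471, "Mg2+ binding site", lit)
    for p in (26, 27, 476, 477):
        t.add(p, "S-pocket", lit)
    t.add(6, "start of the PYR domain", lit)
    t.add(168, "end of the PYR domain", lit)
    t.add(197, "start of the TH3 domain (shifted anchor)", lit)
    t.add(336, "end of the TH3 domain (shifted anchor)", lit)
    t.add(193, "structural start of the TH3 domain", lit)
    t.add(341, "structural end of the TH3 domain", lit)
    t.add(367, "start of the PP domain", lit)
    t.add(540, "end of the PP domain", lit)
    t.add(221, "effector binding site", lit)
    for p in range(286, 305):
        t.add(p, "activation loop 286-304", lit)
    # highly conserved positions without an assigned function
    for p, aa in ((58, "A"), (94, "P"), (219, "G"), (286, "G")):
        t.add(p, f"highly conserved ({aa})", lit)
    t.add(280, "conserved D/E", lit)
    return t


def save_annotations(table: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tlabel\tprovenance\n")
        for pos, label, prov in table.items():
            fh.write(f"{pos}\t{label}\t{prov}\n")


def load_annotations(path) -> AnnotationTable:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    table = AnnotationTable()
    lines = path.read_text().splitlines()
    body = [(i, ln) for i, ln in enumerate(lines, start=1)
            if ln.strip() and not ln.startswith("#")]
    if body and body[0][1].split("\t")[0] == "position":
        body = body[1:]
    if not body:
        warnings.warn(f"{path}: empty annotation table")
        return table
    for lineno, ln in body:
        parts = ln.split("\t")
        if len(parts) < 2:
            raise InputError(f"{path}:{lineno}: expected at least "
                             "position<TAB>label")
        try:
            pos = int(parts[0])
        except ValueError:
            raise InputError(f"{path}:{lineno}: malformed position "
                             f"token {parts[0]!r}") from None
        prov = parts[2] if len(parts) > 2 else ""
        try:
            table.add(pos, parts[1], prov)
        except InputError as e:
            raise InputError(f"{path}:{lineno}: {e}") from e
    return table
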