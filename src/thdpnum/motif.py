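"""PROSITE-style sequence motifs derived from conserved regions.

A motif is an ordered run of consecutive standard positions, each with an
allowed amino-acid set (or a wildcard).  Derivation takes, at every
position of a conservation table slice, the amino acids above a minority
frequency cutoff; scanning is substring-style and position-independent,
the way a motif search runs against a sequence database.  Evaluation is at
the sequence level: a sequence is predicted to belong to the family iff
the motif matches anywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from ._alphabet import AA20, UNKNOWN
from .conservation import ConservationTable
from .errors import InputError
from .seqio import SequenceRecord

#: minority-frequency cutoff for an amino acid to enter the allowed set;
#: mirrors the group-2 minority threshold.  The cutoff behind the family's
#: published motifs is not documented, so this default is a package choice.
DEFAULT_MIN_FREQ = 0.03
DEFAULT_WILDCARD_SIZE = 10


@dataclass(frozen=True)
class MotifPosition:
    position: int
    allowed: Optional[frozenset] = None   # None = wildcard

    def __post_init__(self):
        if self.allowed is not None:
            if not self.allowed:
                raise InputError(f"position {self.position}: empty allowed set")
            bad = set(self.allowed) - set(AA20)
            if bad:
                raise InputError(f"position {self.position}: invalid "
                                 f"amino acids {sorted(bad)}")

    def matches(self, aa: str) -> bool:
        if self.allowed is None:
            return True      # wildcard matches everything, including X
        return aa in self.allowed  # X never sits in an allowed set

    def render(self) -> str:
        if self.allowed is None:
            return "x"
        letters = "".join(sorted(self.allowed))
        return letters if len(letters) == 1 else f"[{letters}]"


@dataclass(frozen=True)
class Motif:
    positions: tuple  # tuple[MotifPosition, ...], consecutive standard numbers

    def __post_init__(self):
        if len(self.positions) < 2:
            raise InputError("a motif needs at least two positions")
        nums = [p.position for p in self.positions]
        if any(b != a + 1 for a, b in zip(nums, nums[1:])):
            raise InputError("motif positions must be consecutive")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def start(self) -> int:
        return self.positions[0].position

    def render(self) -> str:
        """Compact rendering, e.g. ``[DHN]-E-[AEGLQ]-...-A``."""
        return "-".join(p.render() for p in self.positions)

    def render_prosite(self) -> str:
        """PROSITE-flavoured rendering with position subscripts."""
        return "-".join(f"{p.render()}_{p.position}" for p in self.positions)


def parse_motif(text: str, start: int = 1) -> Motif:
    """Parse the compact rendering back into a Motif (anchored at start)."""
    tokens = text.strip().split("-")
    positions = []
    for i, tok in enumerate(tokens):
        tok = tok.strip()
        if not tok:
            raise InputError(f"motif token {i + 1} is empty")
        if tok in ("x", "X"):
            allowed = None
        else:
            m = re.fullmatch(r"\[([A-WY]+)\]|([A-WY])", tok)
            if not m:
                raise InputError(f"malformed motif token {tok!r}")
            allowed = frozenset(m.group(1) or m.group(2))
        positions.append(MotifPosition(position=start + i, allowed=allowed))
    return Motif(positions=tuple(positions))


def derive_motif(table: ConservationTable, start: int, end: int,
                 min_freq: float = DEFAULT_MIN_FREQ,
                 wildcard_size: int = DEFAULT_WILDCARD_SIZE) -> Motif:
    """Motif over standard positions start..end from a conservation table.

    The allowed set at each position contains the amino acids with
    frequency strictly above ``min_freq`` (alphabetical); a set larger
    than ``wildcard_size`` collapses to a wildcard.
    """
    if start > end:
        raise InputError("motif start must not exceed end")
    positions = []
    for pos in range(start, end + 1):
        if pos not in table.counts.index or \
                table.counts.loc[pos].sum() == 0:
            raise InputError(f"position {pos} has no coverage in the table")
        freqs = table.frequencies(pos)
        allowed = frozenset(a for a in AA20 if freqs[a] > min_freq)
        if not allowed:
            raise InputError(f"position {pos}: no amino acid above "
                             f"min_freq={min_freq}")
        if len(allowed) > wildcard_size:
            positions.append(MotifPosition(position=pos, allowed=None))
        else:
            positions.append(MotifPosition(position=pos, allowed=allowed))
    return Motif(positions=tuple(positions))


def scan(seq: SequenceRecord, motif: Motif) -> list[int]:
    """All 1-based offsets at which the motif matches the sequence.

    X matches only wildcard positions.
    """
    s = seq.residues
    m = len(motif)
    hits = []
    for i in range(len(s) - m + 1):
        if all(p.matches(s[i + j]) for j, p in enumerate(motif.positions)):
            hits.append(i + 1)
    return hits


@dataclass(frozen=True)
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None


def evaluate(motif: Motif, positives: Sequence[SequenceRecord],
             negatives: Sequence[SequenceRecord]) -> EvaluationResult:
    """Sequence-level confusion counts for motif-based family detection."""
    pos_ids = {s.id for s in positives}
    neg_ids = {s.id for s in negatives}
    if pos_ids & neg_ids:
        raise InputError("positive and negative sets share ids: "
                         f"{sorted(pos_ids & neg_ids)}")
    tp = sum(1 for s in positives if scan(s, motif))
    fn = len(positives) - tp
    fp = sum(1 for s in negatives if scan(s, motif))
    tn = len(negatives) - fp
    return EvaluationResult(tp=tp, fp=fp, fn=fn, tn=tn)
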