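"""Transfer of standard residue numbers from the reference to queries.

A query is aligned to the family profile; every residue that lands in
match state k receives the reference's absolute position number for k.
Residues emitted by interior insert states are labelled with the number
of the preceding match state plus an insertion ordinal (rendered ``168i1``
by default, or ``168a`` in lettered style).  Flanking residues outside the
modelled region carry no number.  Non-family sequences are kept out by a
forward-score gate, the package's stand-in for a database prescreen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._alphabet import AA20, background20
from .annotations import AnnotationTable, default_annotations
from .errors import GateRejection, InputError
from .profile_hmm import (AlignedPath, ProfileHMM, ReferenceMap,
                          build_profile, forward_score, viterbi_align)
from .seqio import MultipleAlignment, SequenceRecord

#: default acceptance gate in bits.  Forward log-odds of i.i.d. background
#: sequences concentrate near zero with an empirical ceiling around +10
#: bits regardless of model size, while family members score roughly
#: 0.3 bits per match state and more; 20 bits clears the background
#: ceiling with a wide margin yet stays far below family scores for any
#: realistic model length.  For very short profiles (K below ~100) use
#: calibrate_gate_threshold instead.
DEFAULT_GATE_BITS: float = 20.0

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class StandardNumber:
    """A standard position, optionally with an insertion ordinal."""

    base: int
    insertion_ordinal: int = 0

    def render(self, style: str = "i") -> str:
        if self.insertion_ordinal == 0:
            return str(self.base)
        if style == "i":
            return f"{self.base}i{self.insertion_ordinal}"
        if style == "letter":
            n = self.insertion_ordinal - 1
            suffix = ""
            while True:
                suffix = _LETTERS[n % 26] + suffix
                n = n // 26 - 1
                if n < 0:
                    break
            return f"{self.base}{suffix}"
        raise InputError(f"unknown insertion style {style!r}")


@dataclass(frozen=True)
class GateResult:
    score: float
    threshold: float
    accepted: bool

    def __post_init__(self):
        if self.accepted != (self.score >= self.threshold):
            raise InputError("inconsistent gate result")


@dataclass(frozen=True)
class NumberedSequence:
    """A query with per-residue standard numbers and annotations."""

    query: SequenceRecord
    numbers: tuple          # tuple[StandardNumber | None, ...], one per residue
    annotations: tuple      # tuple[tuple[str, ...], ...], one per residue
    gate_score: float
    accepted: bool
    reference_id: str
    profile_checksum: str
    path: AlignedPath = field(compare=False)
    missing_annotated: tuple = ()   # annotated standard positions absent here

    def __post_init__(self):
        L = len(self.query.residues)
        if len(self.numbers) != L or len(self.annotations) != L:
            raise InputError("per-residue arrays must match sequence length")
        bases = [n.base for n in self.numbers
                 if n is not None and n.insertion_ordinal == 0]
        if any(b >= c for b, c in zip(bases, bases[1:])):
            raise InputError("match-residue standard numbers must increase")

    def standard_of(self, query_index: int) -> Optional[StandardNumber]:
        """Standard number of the residue at 1-based query position."""
        return self.numbers[query_index - 1]

    def query_index_of(self, standard_position: int) -> Optional[int]:
        """1-based query index of a standard position (ordinal 0), if present."""
        for i, n in enumerate(self.numbers, start=1):
            if n is not None and n.insertion_ordinal == 0 \
                    and n.base == standard_position:
                return i
        return None

    def rows(self, style: str = "i"):
        """TSV rows: index, residue, standard number, insertion code, labels."""
        for i, (aa, num, labels) in enumerate(
                zip(self.query.residues, self.numbers, self.annotations),
                start=1):
            if num is None:
                std, code = "-", ""
            elif num.insertion_ordinal == 0:
                std, code = str(num.base), ""
            else:
                std = str(num.base)
                code = num.render(style)[len(std):]
            yield (str(i), aa, std, code, ";".join(labels))


def gate(profile: ProfileHMM, seq: SequenceRecord,
         threshold_bits: float = DEFAULT_GATE_BITS) -> GateResult:
    """Score a query against the profile and test it against the gate."""
    score = forward_score(profile, seq)
    return GateResult(score=score, threshold=threshold_bits,
                      accepted=score >= threshold_bits)


def calibrate_gate_threshold(profile: ProfileHMM, n: int = 1000,
                             length: Optional[int] = None, seed: int = 0,
                             margin_bits: float = 1.0) -> float:
    """Threshold rejecting i.i.d. background sequences of the given length.

    Draws ``n`` sequences from the profile's background composition and
    returns the maximum forward score plus a safety margin, so that
    background sequences are rejected at (empirically) 100%.
    """
    if length is None:
        length = profile.K
    rng = np.random.default_rng(seed)
    bg = profile.background[:20] / profile.background[:20].sum()
    aas = np.array(list(AA20))
    best = -np.inf
    for i in range(n):
        s = "".join(rng.choice(aas, size=length, p=bg))
        best = max(best, forward_score(profile, SequenceRecord(
            id=f"bg{i}", residues=s)))
    return best + margin_bits


def assign_numbers(profile: ProfileHMM, refmap: ReferenceMap,
                   annotations: Optional[AnnotationTable],
                   seq: SequenceRecord,
                   gate_threshold_bits: float = DEFAULT_GATE_BITS,
                   bypass_gate: bool = False) -> NumberedSequence:
    """Number one query sequence by aligning it to the profile.

    Raises :class:`GateRejection` if the query scores below the gate and
    the gate is not bypassed.
    """
    if refmap.n_match_states != profile.K:
        raise InputError("reference map does not match the profile")
    g = gate(profile, seq, gate_threshold_bits)
    if not g.accepted and not bypass_gate:
        raise GateRejection(
            f"sequence {seq.id!r} rejected by the acceptance gate "
            f"({g.score:.1f} < {g.threshold:.1f} bits)", gate_result=g)

    path = viterbi_align(profile, seq)
    L = len(seq.residues)
    numbers: list[Optional[StandardNumber]] = [None] * L
    ordinal = 0
    for step in path.steps:
        if step.kind == "M":
            numbers[step.query_index - 1] = StandardNumber(
                base=refmap.standard_number(step.node))
            ordinal = 0
        elif step.kind == "I":
            if 1 <= step.node <= profile.K - 1:
                ordinal += 1
                numbers[step.query_index - 1] = StandardNumber(
                    base=refmap.standard_number(step.node),
                    insertion_ordinal=ordinal)
            # flank inserts (node 0 / node K) stay unnumbered
        else:
            ordinal = 0

    labels: list[tuple] = [()] * L
    missing: tuple = ()
    if annotations is not None:
        present = {n.base for n in numbers
                   if n is not None and n.insertion_ordinal == 0}
        for i, n in enumerate(numbers):
            if n is not None and n.insertion_ordinal == 0:
                found = annotations.lookup(n.base)
                if found:
                    labels[i] = tuple(sorted(found))
        missing = tuple(sorted(p for p in annotations.positions()
                               if p not in present
                               and p <= refmap.standard_numbers[-1]
                               and p >= refmap.standard_numbers[0]))
    return NumberedSequence(query=seq, numbers=tuple(numbers),
                            annotations=tuple(labels),
                            gate_score=g.score, accepted=g.accepted,
                            reference_id=refmap.reference_id,
                            profile_checksum=profile.checksum,
                            path=path, missing_annotated=missing)


@dataclass(frozen=True)
class RejectionReport:
    accepted_ids: tuple
    rejections: tuple   # tuple[(id, score_bits), ...]


def number_batch(profile: ProfileHMM, refmap: ReferenceMap,
                 annotations: Optional[AnnotationTable],
                 seqs: Sequence[SequenceRecord],
                 gate_policy: str = "reject",
                 gate_threshold_bits: float = DEFAULT_GATE_BITS,
                 ) -> tuple[list[NumberedSequence], RejectionReport]:
    """Number a batch of queries, preserving order.

    ``gate_policy``: ``reject`` skips failing sequences and reports them,
    ``error`` raises on the first failure, ``bypass`` numbers everything.
    """
    if gate_policy not in ("reject", "error", "bypass"):
        raise InputError(f"unknown gate policy {gate_policy!r}")
    numbered: list[NumberedSequence] = []
    accepted: list[str] = []
    rejected: list[tuple] = []
    for seq in seqs:
        try:
            ns = assign_numbers(profile, refmap, annotations, seq,
                                gate_threshold_bits=gate_threshold_bits,
                                bypass_gate=(gate_policy == "bypass"))
        except GateRejection as e:
            if gate_policy == "error":
                raise
            rejected.append((seq.id, e.gate_result.score))
            continue
        numbered.append(ns)
        accepted.append(seq.id)
    return numbered, RejectionReport(accepted_ids=tuple(accepted),
                                     rejections=tuple(rejected))


class StandardNumberer(TransformerMixin, BaseEstimator):
    """Estimator wrapping the numbering pipeline.

    ``fit`` builds the profile HMM from a reference multiple alignment;
    ``transform`` aligns query sequences to it and returns
    :class:`NumberedSequence` objects carrying the transferred standard
    numbers and annotations.

    Parameters
    ----------
    reference_id : str
        Id of the reference row inside the alignment passed to ``fit``.
    weighting : {"henikoff", "none"}
        Sequence weighting used when estimating profile parameters.
    pseudocount_weight : float
        Weight of the background-mixture pseudocount.
    gate_threshold_bits : float
        Forward-score acceptance gate (bits).
    gate_policy : {"reject", "error", "bypass"}
        Batch behaviour for gate failures.
    annotations : AnnotationTable, "default" or None
        Standard-position annotations to transfer.
    """

    def __init__(self, reference_id: str = "ref",
                 weighting: str = "henikoff",
                 pseudocount_weight: float = 1.0,
                 gate_threshold_bits: float = DEFAULT_GATE_BITS,
                 gate_policy: str = "reject",
                 annotations="default"):
        self.reference_id = reference_id
        self.weighting = weighting
        self.pseudocount_weight = pseudocount_weight
        self.gate_threshold_bits = gate_threshold_bits
        self.gate_policy = gate_policy
        self.annotations = annotations

    def _annotation_table(self) -> Optional[AnnotationTable]:
        if self.annotations == "default":
            return default_annotations()
        return self.annotations

    def fit(self, X: MultipleAlignment, y=None) -> "StandardNumberer":
        """Build the profile from a reference multiple alignment."""
        self.profile_, self.reference_map_ = build_profile(
            X, self.reference_id, weighting=self.weighting,
            pseudocount_weight=self.pseudocount_weight)
        self.checksum_ = self.profile_.checksum
        return self

    def transform(self, X: Iterable[SequenceRecord]) -> list[NumberedSequence]:
        """Number query sequences; gate failures follow ``gate_policy``."""
        numbered, self.rejection_report_ = number_batch(
            self.profile_, self.reference_map_, self._annotation_table(),
            list(X), gate_policy=self.gate_policy,
            gate_threshold_bits=self.gate_threshold_bits)
        return numbered

    def score_sequence(self, seq: SequenceRecord) -> GateResult:
        return gate(self.profile_, seq, self.gate_threshold_bits)
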