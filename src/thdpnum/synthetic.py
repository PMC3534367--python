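"""Synthetic protein families and labelled datasets with known ground truth.

Everything the pipeline consumes can be generated here with its true
answer recorded: homolog families with exact residue correspondences and
the implied true multiple alignment, alignment pairs with planted column
perturbations for the comparison metric, and labelled motif datasets with
planted match structure.  All generators are pure functions of their seed
and parameters.

The mutation model is deliberately simple: the reference is drawn i.i.d.
from a globular-protein background composition; each homolog substitutes
every site independently with probability (1 - identity) to a uniformly
chosen different amino acid, and indel events start at a per-site rate
with geometric lengths, insertions and deletions equiprobable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._alphabet import AA20, GAP, background20
from .errors import InputError
from .motif import Motif, scan
from .seqio import AlignedRow, MultipleAlignment, SequenceRecord


@dataclass(frozen=True)
class SyntheticFamily:
    """A reference, its homologs, and the exact correspondence truth.

    ``correspondence[hom_id][i]`` is the 1-based reference position of the
    homolog's (i+1)-th residue, or None for an inserted residue.
    """

    reference: SequenceRecord
    homologs: tuple   # tuple[SequenceRecord, ...]
    correspondence: dict
    alignment: MultipleAlignment
    params: dict = field(compare=False)

    @property
    def all_records(self) -> list[SequenceRecord]:
        return [self.reference, *self.homologs]


def _draw_sequence(rng: np.random.Generator, length: int,
                   p: np.ndarray) -> str:
    return "".join(rng.choice(list(AA20), size=length, p=p))


def make_family(seed: int, n: int = 16, length: int = 300,
                identity: float = 0.7, indel_rate: float = 0.01,
                mean_indel_len: float = 2.0,
                background: Optional[np.ndarray] = None,
                reference_id: str = "ref") -> SyntheticFamily:
    """Generate a homolog family around a random reference sequence."""
    if not 0 < identity <= 1:
        raise InputError("identity must lie in (0, 1]")
    if n < 1 or length < 1:
        raise InputError("n and length must be positive")
    if indel_rate < 0 or not 0 <= indel_rate < 1:
        raise InputError("indel_rate must lie in [0, 1)")
    if mean_indel_len < 1:
        raise InputError("mean_indel_len must be >= 1")
    rng = np.random.default_rng(seed)
    bg = background20() if background is None else np.asarray(background)
    bg = bg / bg.sum()
    aas = list(AA20)
    ref = _draw_sequence(rng, length, bg)
    p_geom = 1.0 / mean_indel_len

    homologs = []
    correspondence: dict[str, tuple] = {}
    insertions: dict[str, dict[int, str]] = {}   # anchor ref pos -> residues
    for h in range(n):
        hid = f"hom{h + 1:03d}"
        residues: list[str] = []
        corr: list[Optional[int]] = []
        ins: dict[int, str] = {}
        pos = 1
        while pos <= length:
            if indel_rate and rng.random() < indel_rate:
                g = int(rng.geometric(p_geom))
                if rng.random() < 0.5:       # deletion of g positions
                    pos += g
                    continue
                frag = _draw_sequence(rng, g, bg)   # insertion before pos
                ins[pos - 1] = ins.get(pos - 1, "") + frag
                residues.extend(frag)
                corr.extend([None] * g)
            aa = ref[pos - 1]
            if rng.random() < 1.0 - identity:
                choice = rng.integers(0, 19)
                others = [a for a in aas if a != aa]
                aa = others[choice]
            residues.append(aa)
            corr.append(pos)
            pos += 1
        if not residues:     # degenerate: everything deleted
            residues = [ref[0]]
            corr = [1]
        homologs.append(SequenceRecord(id=hid, residues="".join(residues)))
        correspondence[hid] = tuple(corr)
        insertions[hid] = ins

    alignment = _true_alignment(reference_id, ref, homologs,
                                correspondence, insertions, length)
    params = dict(seed=seed, n=n, length=length, identity=identity,
                  indel_rate=indel_rate, mean_indel_len=mean_indel_len)
    return SyntheticFamily(
        reference=SequenceRecord(id=reference_id, residues=ref),
        homologs=tuple(homologs), correspondence=correspondence,
        alignment=alignment, params=params)


def _true_alignment(reference_id, ref, homologs, correspondence,
                    insertions, length) -> MultipleAlignment:
    """Assemble the ground-truth alignment from the recorded events."""
    ins_len = [0] * (length + 1)   # max insert run after each ref position
    for ins in insertions.values():
        for anchor, frag in ins.items():
            ins_len[anchor] = max(ins_len[anchor], len(frag))

    def build_row(seq_ins: dict[int, str], covered: dict[int, str]) -> str:
        parts = []
        for anchor in range(0, length + 1):
            if anchor >= 1:
                parts.append(covered.get(anchor, GAP))
            frag = seq_ins.get(anchor, "")
            parts.append(frag + GAP * (ins_len[anchor] - len(frag)))
        return "".join(parts)

    rows = [AlignedRow(id=reference_id,
                       residues=build_row({}, {p: ref[p - 1]
                                               for p in range(1, length + 1)}))]
    for hom in homologs:
        covered = {}
        for aa, p in zip(hom.residues, correspondence[hom.id]):
            if p is not None:
                covered[p] = aa
        rows.append(AlignedRow(id=hom.id,
                               residues=build_row(insertions[hom.id],
                                                  covered)))
    return MultipleAlignment(records=tuple(rows))


def perturb_alignment(msa: MultipleAlignment, column_indices: Sequence[int],
                      sequence_ids: Sequence[str], seed: int = 0,
                      anchor_id: Optional[str] = None,
                      ) -> tuple[MultipleAlignment, frozenset]:
    """Shift chosen rows' residues one column right inside chosen columns.

    Each chosen row must have a residue at the chosen column and a gap
    immediately to its right, so the move changes only that column's
    occupancy.  Returns the perturbed alignment and the planted
    (column, sequence id) mismatch set (1-based columns).  Ungapped row
    contents are preserved.  Perturbing the anchor is a contract error.
    """
    if anchor_id is not None and anchor_id in set(sequence_ids):
        raise InputError("cannot perturb the anchor sequence")
    if not column_indices or not sequence_ids:
        return msa, frozenset()
    rows = {r.id: list(r.residues) for r in msa.records}
    planted = set()
    for sid in sequence_ids:
        if sid not in rows:
            raise InputError(f"id {sid!r} not in alignment")
        row = rows[sid]
        for c in column_indices:
            if not 1 <= c < msa.n_columns:
                raise InputError(f"column {c} out of range")
            if row[c - 1] == GAP:
                raise InputError(f"{sid!r} has a gap at column {c}; "
                                 "nothing to shift")
            if row[c] != GAP:
                raise InputError(f"{sid!r} has no gap at column {c + 1}; "
                                 "cannot shift without cascading")
            row[c] = row[c - 1]
            row[c - 1] = GAP
            planted.add((c, sid))
    records = tuple(AlignedRow(id=r.id, residues="".join(rows[r.id]),
                               description=r.description)
                    for r in msa.records)
    return MultipleAlignment(records=records), frozenset(planted)


def shift_row(msa: MultipleAlignment, seq_id: str) -> MultipleAlignment:
    """Shift one whole row right by a column (a maximal perturbation)."""
    if seq_id not in msa.ids:
        raise InputError(f"id {seq_id!r} not in alignment")
    records = []
    for r in msa.records:
        if r.id == seq_id:
            residues = GAP + r.residues
        else:
            residues = r.residues + GAP
        records.append(AlignedRow(id=r.id, residues=residues,
                                  description=r.description))
    # drop a trailing all-gap column if the shifted row ended in a gap
    if all(r.residues[-1] == GAP for r in records):
        records = [AlignedRow(id=r.id, residues=r.residues[:-1],
                              description=r.description) for r in records]
    return MultipleAlignment(records=tuple(records))


def plant_comparison_pair(seed: int, n_other: int = 15, length: int = 60,
                          columns: Sequence[int] = (),
                          sequence_ids: Sequence[str] = (),
                          anchor_id: str = "ref",
                          ) -> tuple[MultipleAlignment, MultipleAlignment,
                                     frozenset]:
    """An alignment pair with an exactly known column-mismatch structure.

    Builds a gapless family alignment, adds one donor insert column after
    every planted anchor position (so the chosen rows have a gap to shift
    into), and perturbs the chosen rows there.  Returns (A, B, planted)
    where planted is the {(standard position, sequence id)} truth.
    """
    fam = make_family(seed, n=n_other, length=length, identity=0.6,
                      indel_rate=0.0, reference_id=anchor_id)
    rng = np.random.default_rng(seed + 1)
    columns = sorted(set(columns))
    sequence_ids = list(sequence_ids)
    if anchor_id in sequence_ids:
        raise InputError("cannot perturb the anchor sequence")
    donor_pool = [i for i in fam.alignment.ids
                  if i != anchor_id and i not in sequence_ids]
    if not donor_pool:
        raise InputError("need at least one unperturbed non-anchor row "
                         "to donate insert columns")
    rows = {r.id: list(r.residues) for r in fam.alignment.records}
    # insert donor columns right of each planted position, descending
    for c in reversed(columns):
        if not 1 <= c <= length:
            raise InputError(f"column {c} out of range 1..{length}")
        donor = donor_pool[int(rng.integers(len(donor_pool)))]
        for sid, row in rows.items():
            row.insert(c, rng.choice(list(AA20)) if sid == donor else GAP)
    aln_a = MultipleAlignment(records=tuple(
        AlignedRow(id=r.id, residues="".join(rows[r.id]))
        for r in fam.alignment.records))
    # planted positions in A's column coordinates (1-based)
    col_of = {c: c + sum(1 for c2 in columns if c2 < c) for c in columns}
    aln_b, _ = perturb_alignment(
        aln_a, [col_of[c] for c in columns], sequence_ids,
        anchor_id=anchor_id)
    planted = frozenset((c, sid) for c in columns for sid in sequence_ids)
    return aln_a, aln_b, planted


def make_motif_dataset(motif: Motif, n_pos: int, n_neg: int, seed: int = 0,
                       length: int = 100, n_broken: int = 0,
                       background: Optional[np.ndarray] = None,
                       ) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Labelled sequences with planted motif-match structure.

    Positives embed one sampled motif realisation at a random offset;
    the first ``n_broken`` positives instead carry a realisation broken at
    one position (and are verified to contain no match at all), so a
    sequence-level evaluation recovers TP = n_pos - n_broken exactly.
    Negatives are background sequences rejection-sampled to match nowhere.
    """
    if n_broken > n_pos:
        raise InputError("cannot break more positives than exist")
    if length < len(motif):
        raise InputError("sequences must be at least as long as the motif")
    rng = np.random.default_rng(seed)
    bg = background20() if background is None else np.asarray(background)
    bg = bg / bg.sum()

    def realisation(broken: bool) -> str:
        out = []
        break_at = -1
        if broken:
            candidates = [j for j, p in enumerate(motif.positions)
                          if p.allowed is not None
                          and len(p.allowed) < len(AA20)]
            if not candidates:
                raise InputError("motif has no breakable position")
            break_at = int(rng.choice(candidates))
        for j, p in enumerate(motif.positions):
            if j == break_at:
                outside = sorted(set(AA20) - p.allowed)
                out.append(outside[int(rng.integers(len(outside)))])
            elif p.allowed is None:
                out.append(AA20[int(rng.integers(len(AA20)))])
            else:
                allowed = sorted(p.allowed)
                out.append(allowed[int(rng.integers(len(allowed)))])
        return "".join(out)

    positives = []
    for i in range(n_pos):
        broken = i < n_broken
        while True:
            insert = realisation(broken)
            offset = int(rng.integers(0, length - len(motif) + 1))
            s = _draw_sequence(rng, length - len(motif), bg)
            full = s[:offset] + insert + s[offset:]
            rec = SequenceRecord(id=f"pos{i + 1:04d}", residues=full)
            hits = scan(rec, motif)
            if broken and not hits:
                break
            if not broken and hits:
                break
        positives.append(rec)

    negatives = []
    for i in range(n_neg):
        for _ in range(10000):
            rec = SequenceRecord(id=f"neg{i + 1:04d}",
                                 residues=_draw_sequence(rng, length, bg))
            if not scan(rec, motif):
                break
        else:
            raise InputError("motif matches almost everything; cannot "
                             "sample negatives")
        negatives.append(rec)
    return positives, negatives
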