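"""Column-wise agreement between two multiple alignments of the same set.

Columns are paired through an anchor sequence (normally the numbering
reference): for each anchor residue, the column it occupies in alignment A
is compared with the column it occupies in alignment B.  For every other
sequence, a mismatch is recorded iff a *different residue of that
sequence* (by ordinal position, gap counting as a value) occupies the two
columns; identical amino-acid letters at different ordinals still
mismatch.  Mismatch counts are binned into five similarity categories;
with 15 non-anchor sequences the bins are {0}, [1,3], [4,8], [9,12],
[13,15], and for other n the same fractions of n apply.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._alphabet import GAP
from .errors import InputError
from .seqio import MultipleAlignment

CATEGORIES = ("identical", "highly_similar", "similar", "dissimilar",
              "divergent")

# exclusive-left fraction boundaries of the non-identical bins
_BOUNDS = ((3, 15), (8, 15), (12, 15))


def category_of(mismatch_count: int, n: int) -> str:
    """Similarity category for a column with the given mismatch count."""
    if n < 1:
        raise InputError("need at least one non-anchor sequence")
    if not 0 <= mismatch_count <= n:
        raise InputError(f"mismatch count {mismatch_count} out of range 0..{n}")
    if mismatch_count == 0:
        return "identical"
    for cat, (num, den) in zip(CATEGORIES[1:], _BOUNDS):
        if mismatch_count * den <= n * num:
            return cat
    return "divergent"


def category_bins(n: int) -> dict[str, tuple[int, int]]:
    """Inclusive integer mismatch-count ranges per category (empty bins
    omitted).  For n = 15 these are the canonical {0}, [1,3], [4,8],
    [9,12], [13,15]."""
    if n < 1:
        raise InputError("need at least one non-anchor sequence")
    edges = [0] + [n * num // den for num, den in _BOUNDS] + [n]
    bins = {"identical": (0, 0)}
    for cat, lo, hi in zip(CATEGORIES[1:], edges[:-1], edges[1:]):
        if hi >= lo + 1:
            bins[cat] = (lo + 1, hi)
    return bins


@dataclass(frozen=True)
class ColumnComparison:
    anchor_position: int     # ordinal of the anchor residue (standard number)
    mismatch_count: int
    n: int

    @property
    def category(self) -> str:
        return category_of(self.mismatch_count, self.n)


@dataclass(frozen=True)
class ComparisonReport:
    columns: tuple  # tuple[ColumnComparison, ...]
    n_sequences: int  # non-anchor sequences

    @property
    def histogram(self) -> dict[str, int]:
        h = {c: 0 for c in CATEGORIES}
        for col in self.columns:
            h[col.category] += 1
        return h

    @property
    def fractions(self) -> dict[str, float]:
        total = len(self.columns)
        return {c: v / total for c, v in self.histogram.items()}


def _ordinals(msa: MultipleAlignment) -> dict[str, list[int]]:
    """Per id, the residue ordinal occupying each column (-1 for gap)."""
    out = {}
    for rec in msa.records:
        ords = []
        k = 0
        for a in rec.residues:
            if a == GAP:
                ords.append(-1)
            else:
                k += 1
                ords.append(k)
        out[rec.id] = ords
    return out


def _residue_columns(msa: MultipleAlignment, seq_id: str) -> list[int]:
    """Column index (0-based) of each residue of ``seq_id``, in order."""
    row = msa.row(seq_id).residues
    return [c for c, a in enumerate(row) if a != GAP]


def compare_alignments(aln_a: MultipleAlignment, aln_b: MultipleAlignment,
                       anchor_id: str) -> ComparisonReport:
    """Compare two alignments of the same sequences, column by column.

    Both alignments must contain exactly the same ids with identical
    ungapped sequences; columns are anchored on the anchor sequence's
    residues, so the report has one entry per anchor residue.
    """
    ids_a, ids_b = set(aln_a.ids), set(aln_b.ids)
    if ids_a != ids_b:
        missing = sorted(ids_a ^ ids_b)
        raise InputError(f"alignments contain different ids: {missing}")
    if anchor_id not in ids_a:
        raise InputError(f"anchor id {anchor_id!r} not in alignments")
    for i in sorted(ids_a):
        if aln_a.ungapped(i).residues != aln_b.ungapped(i).residues:
            raise InputError(f"sequence {i!r} differs between the two "
                             "alignments (not the same protein)")
    others = sorted(ids_a - {anchor_id})
    n = len(others)
    if n < 1:
        raise InputError("need at least one non-anchor sequence")
    ords_a = _ordinals(aln_a)
    ords_b = _ordinals(aln_b)
    cols_a = _residue_columns(aln_a, anchor_id)
    cols_b = _residue_columns(aln_b, anchor_id)

    columns = []
    for pos, (ca, cb) in enumerate(zip(cols_a, cols_b), start=1):
        mismatches = sum(1 for s in others
                         if ords_a[s][ca] != ords_b[s][cb])
        columns.append(ColumnComparison(anchor_position=pos,
                                        mismatch_count=mismatches, n=n))
    return ComparisonReport(columns=tuple(columns), n_sequences=n)


def write_report(report: ComparisonReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("anchor_position\tmismatch_count\tn\tcategory\n")
        for col in report.columns:
            fh.write(f"{col.anchor_position}\t{col.mismatch_count}\t"
                     f"{col.n}\t{col.category}\n")
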