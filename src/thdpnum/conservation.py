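"""Per-position amino-acid conservation over a numbered sequence set.

Counts are taken at match-state residues only (insertion ordinals are
excluded), so every count is keyed by a standard position.  Positions
deleted in a sequence do not contribute to that sequence's counts; by
default frequencies are computed among the sequences covering a position,
with an optional all-sequences denominator.

Positions are classified into the family's conservation groups:

* group 1 — one amino acid in more than 90% of members and no other
  amino acid above 1% (e.g. G27 and G443 in the decarboxylase family),
* group 2 — a >90% majority plus a distinct minority above 3%
  (e.g. E51 with a valine minority),
* variable — everything else (e.g. the HH-motif positions 114/115).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._alphabet import AA20
from .errors import InputError
from .numbering import NumberedSequence

#: classification thresholds (strict inequalities, family defaults)
MAJORITY_THRESHOLD = 0.90
GROUP1_OTHER_MAX = 0.01
GROUP2_MINORITY_MIN = 0.03


@dataclass(frozen=True)
class ConservationClass:
    group: str            # "group1" | "group2" | "variable"
    majority_aa: str
    majority_freq: float
    runner_up_aa: str
    runner_up_freq: float


@dataclass(frozen=True)
class ConservationTable:
    """Counts per standard position over the 20 amino acids."""

    counts: pd.DataFrame      # index: standard positions, columns: AA20
    n_sequences: int

    def __post_init__(self):
        if list(self.counts.columns) != list(AA20):
            raise InputError("count columns must be the 20 amino acids")

    @property
    def positions(self) -> list[int]:
        return [int(p) for p in self.counts.index]

    def coverage(self, position: int) -> float:
        """Fraction of sequences possessing the position (ordinal 0)."""
        return float(self.counts.loc[position].sum()) / self.n_sequences

    def frequencies(self, position: int,
                    denominator: str = "covering") -> pd.Series:
        """Amino-acid frequencies at a position.

        ``denominator='covering'`` divides by the sequences covering the
        position; ``'all'`` divides by the total number of sequences, so
        deletions dilute every frequency.
        """
        row = self.counts.loc[position].astype(float)
        if denominator == "covering":
            total = row.sum()
        elif denominator == "all":
            total = float(self.n_sequences)
        else:
            raise InputError(f"unknown denominator {denominator!r}")
        if total == 0:
            raise InputError(f"position {position} has no coverage")
        return row / total


def tabulate(numbered: Sequence[NumberedSequence]) -> ConservationTable:
    """Tabulate match-residue amino-acid counts per standard position.

    Unknown residues (X) are not counted; insertions are excluded.
    """
    numbered = list(numbered)
    if not numbered:
        raise InputError("need at least one numbered sequence")
    rows: dict[int, np.ndarray] = {}
    aa_idx = {a: i for i, a in enumerate(AA20)}
    for ns in numbered:
        for aa, num in zip(ns.query.residues, ns.numbers):
            if num is None or num.insertion_ordinal != 0:
                continue
            if aa not in aa_idx:
                continue  # X
            rows.setdefault(num.base, np.zeros(len(AA20)))[aa_idx[aa]] += 1
    if not rows:
        raise InputError("no numbered match residues to tabulate")
    index = sorted(rows)
    frame = pd.DataFrame([rows[p] for p in index], index=index,
                         columns=list(AA20), dtype=float)
    return ConservationTable(counts=frame, n_sequences=len(numbered))


def classify(frequencies: Mapping[str, float] | pd.Series,
             majority_threshold: float = MAJORITY_THRESHOLD,
             group1_other_max: float = GROUP1_OTHER_MAX,
             group2_minority_min: float = GROUP2_MINORITY_MIN,
             ) -> ConservationClass:
    """Classify one position's frequency vector.

    Group 1 requires a majority strictly above ``majority_threshold`` with
    every other amino acid at or below ``group1_other_max``; group 2 the
    same majority with a runner-up strictly above ``group2_minority_min``.
    All comparisons are strict, so a majority of exactly 0.90 is variable.
    """
    s = pd.Series(frequencies, dtype=float)
    if s.empty or (s < 0).any() or s.sum() == 0:
        raise InputError("invalid frequency vector")
    s = s / s.sum()   # scale-free: raw counts classify identically
    order = s.sort_values(ascending=False, kind="stable")
    top_aa, top = order.index[0], float(order.iloc[0])
    if len(order) > 1:
        run_aa, run = order.index[1], float(order.iloc[1])
    else:
        run_aa, run = "", 0.0
    if top > majority_threshold:
        others = order.iloc[1:]
        if (others <= group1_other_max).all():
            group = "group1"
        elif run > group2_minority_min:
            group = "group2"
        else:
            group = "variable"
    else:
        group = "variable"
    return ConservationClass(group=group, majority_aa=top_aa,
                             majority_freq=top, runner_up_aa=run_aa,
                             runner_up_freq=run)


def report_conserved(table: ConservationTable,
                     majority_threshold: float = MAJORITY_THRESHOLD,
                     group1_other_max: float = GROUP1_OTHER_MAX,
                     group2_minority_min: float = GROUP2_MINORITY_MIN,
                     denominator: str = "covering") -> pd.DataFrame:
    """Classify every covered position; sorted by standard position."""
    records = []
    for pos in table.positions:
        if table.counts.loc[pos].sum() == 0:
            continue
        cls = classify(table.frequencies(pos, denominator=denominator),
                       majority_threshold, group1_other_max,
                       group2_minority_min)
        records.append({
            "position": pos,
            "group": cls.group,
            "majority_aa": cls.majority_aa,
            "majority_freq": cls.majority_freq,
            "runner_up_aa": cls.runner_up_aa,
            "runner_up_freq": cls.runner_up_freq,
            "coverage": table.coverage(pos),
        })
    return pd.DataFrame.from_records(
        records, columns=["position", "group", "majority_aa", "majority_freq",
                          "runner_up_aa", "runner_up_freq", "coverage"])


def save_table(table: ConservationTable, path) -> None:
    frame = table.counts.copy()
    frame.insert(0, "position", table.positions)
    with open(path, "w") as fh:
        fh.write(f"# n_sequences\t{table.n_sequences}\n")
        frame.to_csv(fh, sep="\t", index=False)


def load_table(path) -> ConservationTable:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# n_sequences\t"):
            raise InputError(f"{path}: missing n_sequences header")
        n = int(first.split("\t")[1])
        frame = pd.read_csv(fh, sep="\t")
    frame = frame.set_index("position")
    frame.index = frame.index.astype(int)
    frame.index.name = None
    return ConservationTable(counts=frame[list(AA20)].astype(float),
                             n_sequences=n)
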