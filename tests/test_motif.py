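import re

import numpy as np
import pandas as pd
import pytest

from thdpnum import (InputError, SequenceRecord, derive_motif, evaluate,
                     parse_motif, scan)
from thdpnum._alphabet import AA20
from thdpnum.conservation import ConservationTable
from thdpnum.motif import Motif, MotifPosition

# the family motif around the catalytic glutamate (positions 50-58)
E51_SETS = ["DHN", "E", "AEGLQ", "AGNSTV", "AGLMV", "AGISTV", "FHLMY",
            "AFILM", "A"]
E51_RENDERED = ("[DHN]-E-[AEGLQ]-[AGNSTV]-[AGLMV]-[AGISTV]-[FHLMY]"
                "-[AFILM]-A")
D280_SETS = ["DE", "ACFLTV", "ILMV", "FILV", "ACGLMNSTV", "AFILV", "G"]


def planted_table(sets, start, n=100):
    """Counts whose above-threshold residues are exactly the given sets."""
    positions = list(range(start, start + len(sets)))
    counts = pd.DataFrame(0.0, index=positions, columns=list(AA20))
    for pos, allowed in zip(positions, sets):
        share = n / len(allowed)
        for aa in allowed:
            counts.loc[pos, aa] = share
    return ConservationTable(counts=counts, n_sequences=n)


def regex_oracle(seq, motif):
    """Independent matcher: translate the motif to a regex and scan."""
    parts = []
    for p in motif.positions:
        if p.allowed is None:
            parts.append(".")
        else:
            parts.append("[" + "".join(sorted(p.allowed)) + "]")
    pattern = re.compile("(?=(" + "".join(parts) + "))")
    return [m.start() + 1 for m in pattern.finditer(seq.residues)]


class TestDerive:
    def test_catalytic_glutamate_motif_renders_exactly(self):
        table = planted_table(E51_SETS, start=50)
        motif = derive_motif(table, 50, 58)
        assert motif.render() == E51_RENDERED

    def test_th3_strand_motif_renders_exactly(self):
        table = planted_table(D280_SETS, start=280)
        motif = derive_motif(table, 280, 286)
        assert motif.render() == \
            "[DE]-[ACFLTV]-[ILMV]-[FILV]-[ACGLMNSTV]-[AFILV]-G"

    def test_unique_residue_renders_bare_letter(self):
        table = planted_table(["A", "C"], start=10)
        assert derive_motif(table, 10, 11).render() == "A-C"

    def test_wide_set_collapses_to_wildcard(self):
        table = planted_table([AA20, "G"], start=5, n=2000)
        motif = derive_motif(table, 5, 6, min_freq=0.0, wildcard_size=10)
        assert motif.render() == "x-G"

    def test_no_residue_above_cutoff_is_an_error(self):
        table = planted_table([AA20, "G"], start=5)
        with pytest.raises(InputError, match="position 5"):
            derive_motif(table, 5, 6, min_freq=0.5)

    def test_uncovered_position_is_an_error(self):
        table = planted_table(["A", "C"], start=10)
        with pytest.raises(InputError, match="coverage"):
            derive_motif(table, 10, 12)

    def test_zero_cutoff_motif_accepts_all_training_sequences(
            self, small_family, small_profile):
        from thdpnum import assign_numbers, tabulate
        profile, refmap = small_profile
        numbered = [assign_numbers(profile, refmap, None, r,
                                   bypass_gate=True)
                    for r in small_family.all_records]
        table = tabulate(numbered)
        start, end = 30, 38
        motif = derive_motif(table, start, end, min_freq=0.0,
                             wildcard_size=20)
        for ns in numbered:
            covered = [ns.query_index_of(p) for p in range(start, end + 1)]
            if None in covered or covered != list(
                    range(covered[0], covered[0] + len(covered))):
                continue   # deletion or insertion inside the window
            assert covered[0] in scan(ns.query, motif)


class TestScan:
    def test_simple_match_offsets_are_one_based(self):
        motif = parse_motif("A-C")
        assert scan(SequenceRecord(id="s", residues="AAC"), motif) == [2]

    def test_wildcards_match_every_offset(self):
        motif = Motif(positions=(MotifPosition(1, None),
                                 MotifPosition(2, None)))
        assert scan(SequenceRecord(id="s", residues="MKTWY"), motif) == \
            [1, 2, 3, 4]

    def test_x_matches_only_wildcards(self):
        motif = parse_motif("A-C")
        assert scan(SequenceRecord(id="s", residues="AXC"), motif) == []
        wild = Motif(positions=(MotifPosition(1, frozenset("A")),
                                MotifPosition(2, None)))
        assert scan(SequenceRecord(id="s", residues="AX"), wild) == [1]

    def test_overlapping_matches_all_reported(self):
        motif = parse_motif("A-A")
        assert scan(SequenceRecord(id="s", residues="AAAA"), motif) == \
            [1, 2, 3]

    @pytest.mark.parametrize("batch", range(2))
    def test_agrees_with_regex_oracle(self, batch):
        rng = np.random.default_rng(60 + batch)
        for _ in range(500):
            m = int(rng.integers(2, 7))
            positions = []
            for j in range(m):
                if rng.random() < 0.15:
                    positions.append(MotifPosition(j + 1, None))
                else:
                    size = int(rng.integers(1, 8))
                    allowed = frozenset(
                        rng.choice(list(AA20), size=size, replace=False))
                    positions.append(MotifPosition(j + 1, allowed))
            motif = Motif(positions=tuple(positions))
            seq = SequenceRecord(
                id="s", residues="".join(rng.choice(
                    list(AA20), size=int(rng.integers(2, 40)))))
            assert scan(seq, motif) == regex_oracle(seq, motif)


class TestParse:
    def test_round_trip(self):
        motif = parse_motif(E51_RENDERED, start=50)
        assert motif.render() == E51_RENDERED
        assert motif.start == 50
        assert motif.positions[1].allowed == frozenset("E")

    def test_prosite_rendering_carries_positions(self):
        motif = parse_motif("A-C", start=10)
        assert motif.render_prosite() == "A_10-C_11"

    def test_malformed_token_rejected(self):
        with pytest.raises(InputError):
            parse_motif("A-[C")

    def test_single_position_rejected(self):
        with pytest.raises(InputError):
            parse_motif("A")


class TestEvaluate:
    def _motif(self):
        return parse_motif("W-C-Y-D")

    def test_sensitivity_thirteen_of_twenty(self):
        motif = self._motif()
        hit = SequenceRecord(id="h", residues="AAWCYDAA")
        positives = [SequenceRecord(id=f"p{i}", residues="AAWCYDAA")
                     for i in range(13)]
        positives += [SequenceRecord(id=f"m{i}", residues="AAAAAAAA")
                      for i in range(7)]
        res = evaluate(motif, positives, [])
        assert (res.tp, res.fn) == (13, 7)
        assert res.sensitivity == pytest.approx(0.65)
        assert res.precision == pytest.approx(1.0)
        assert hit.id == "h"

    def test_no_matches_gives_zero_sensitivity_undefined_precision(self):
        motif = self._motif()
        positives = [SequenceRecord(id="p", residues="AAAA")]
        res = evaluate(motif, positives, [])
        assert res.sensitivity == 0.0
        assert res.precision is None

    def test_order_invariance(self):
        motif = self._motif()
        pos = [SequenceRecord(id=f"p{i}", residues=r)
               for i, r in enumerate(["WCYDAA", "AAAA", "GWCYDG"])]
        neg = [SequenceRecord(id=f"n{i}", residues=r)
               for i, r in enumerate(["CCCC", "WCYD"])]
        fwd = evaluate(motif, pos, neg)
        rev = evaluate(motif, pos[::-1], neg[::-1])
        assert (fwd.tp, fwd.fp, fwd.fn, fwd.tn) == \
            (rev.tp, rev.fp, rev.fn, rev.tn)

    def test_shared_ids_rejected(self):
        motif = self._motif()
        s = SequenceRecord(id="x", residues="AAAA")
        with pytest.raises(InputError, match="share ids"):
            evaluate(motif, [s], [s])
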