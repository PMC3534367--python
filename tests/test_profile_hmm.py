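import json

import numpy as np
import pytest

from dp_oracle import oracle_forward, oracle_viterbi
from thdpnum import (InputError, MultipleAlignment, SequenceRecord,
                     build_profile, forward_score, load_profile, save_profile,
                     viterbi_align)
from thdpnum._alphabet import AA20
from thdpnum.seqio import AlignedRow
from thdpnum.synthetic import make_family


def random_toy_msa(rng, K, nrows, gap_p=0.25):
    """Random alignment whose first row (the reference) has K residues."""
    ncol = K + int(rng.integers(0, 3))
    ref_cols = set(int(c) for c in rng.choice(ncol, size=K, replace=False))
    letters = list(AA20)
    rows = []
    for r in range(nrows):
        chars = []
        for c in range(ncol):
            if r == 0:
                chars.append(letters[rng.integers(20)]
                             if c in ref_cols else "-")
            else:
                chars.append(letters[rng.integers(20)]
                             if rng.random() > gap_p else "-")
        row = "".join(chars)
        if not row.replace("-", ""):
            row = letters[rng.integers(20)] + row[1:]
        rows.append(AlignedRow(id=f"s{r}", residues=row))
    return MultipleAlignment(records=tuple(rows))


class TestBuildProfile:
    def test_match_states_equal_ungapped_reference_length(self, small_family,
                                                          small_profile):
        profile, refmap = small_profile
        assert profile.K == len(small_family.reference.residues)
        assert refmap.n_match_states == profile.K

    def test_single_row_no_smoothing_gives_indicator_emissions(self):
        msa = MultipleAlignment(records=(AlignedRow(id="r", residues="ACD"),))
        with pytest.warns(UserWarning, match="single row"):
            profile, _ = build_profile(msa, "r", weighting="none",
                                       pseudocount_weight=0.0)
        for k, aa in enumerate("ACD"):
            row = profile.match_emissions[k]
            assert row[AA20.index(aa)] == pytest.approx(1.0)
            assert row.sum() == pytest.approx(1.0)

    def test_duplicated_rows_leave_profile_unchanged_without_weighting(self):
        one = MultipleAlignment(records=(AlignedRow(id="r", residues="ACDW"),))
        two = MultipleAlignment(records=(AlignedRow(id="r", residues="ACDW"),
                                         AlignedRow(id="r2", residues="ACDW")))
        with pytest.warns(UserWarning):
            p1, _ = build_profile(one, "r", weighting="none")
        p2, _ = build_profile(two, "r", weighting="none")
        np.testing.assert_allclose(p1.match_emissions, p2.match_emissions)
        np.testing.assert_allclose(p1.tmm, p2.tmm)

    def test_missing_reference_id_rejected(self, small_family):
        with pytest.raises(InputError, match="reference id"):
            build_profile(small_family.alignment, "nonesuch")

    @pytest.mark.parametrize("seed", range(8))
    def test_normalisation_invariants(self, seed):
        rng = np.random.default_rng(seed)
        msa = random_toy_msa(rng, int(rng.integers(1, 8)),
                             int(rng.integers(2, 7)))
        pc = float(rng.choice([0.3, 1.0, 3.0]))
        weighting = ["none", "henikoff"][seed % 2]
        profile, _ = build_profile(msa, "s0", weighting=weighting,
                                   pseudocount_weight=pc)
        profile.validate()   # raises on any unnormalised row
        assert (profile.match_emissions > 0).all()
        assert (profile.background > 0).all()


class TestViterbi:
    def test_reference_self_alignment_is_all_match(self, small_family,
                                                   small_profile):
        profile, _ = small_profile
        path = viterbi_align(profile, small_family.reference)
        assert [s.kind for s in path.steps] == ["M"] * profile.K
        assert [s.node for s in path.steps] == list(range(1, profile.K + 1))
        assert path.entry_index == 0
        assert path.exit_index == profile.K

    def test_single_deleted_residue_yields_one_delete_state(self):
        fam = make_family(seed=3, n=6, length=40, identity=0.9,
                          indel_rate=0.0)
        profile, _ = build_profile(fam.alignment, "ref")
        ref = fam.reference.residues
        query = SequenceRecord(id="q", residues=ref[:20] + ref[21:])
        path = viterbi_align(profile, query)
        kinds = [s.kind for s in path.steps]
        assert kinds.count("D") == 1
        assert kinds.count("I") == 0
        assert path.steps[20].kind == "D"

    def test_empty_sequence_rejected(self, small_profile):
        profile, _ = small_profile
        with pytest.raises(InputError):
            SequenceRecord(id="q", residues="")

    def test_path_covers_query_exactly_once(self, small_family,
                                            small_profile):
        profile, _ = small_profile
        for hom in small_family.homologs[:4]:
            path = viterbi_align(profile, hom)
            consumed = [s.query_index for s in path.steps
                        if s.kind in ("M", "I")]
            assert consumed == list(range(1, len(hom.residues) + 1))
            match_nodes = [s.node for s in path.steps if s.kind in ("M", "D")]
            assert match_nodes == sorted(match_nodes)
            assert set(match_nodes) == set(range(1, profile.K + 1))


class TestOracleEquivalence:
    @pytest.mark.parametrize("batch", range(4))
    def test_dp_equals_exhaustive_enumeration(self, batch):
        """Viterbi and forward match brute-force path enumeration."""
        rng = np.random.default_rng(100 + batch)
        for case in range(50):
            K = int(rng.integers(1, 7))
            msa = random_toy_msa(rng, K, int(rng.integers(2, 6)))
            profile, _ = build_profile(
                msa, "s0",
                weighting=str(rng.choice(["none", "henikoff"])),
                pseudocount_weight=float(rng.choice([0.5, 1.0, 2.0])))
            L = int(rng.integers(1, 7))
            seq = SequenceRecord(
                id="q", residues="".join(rng.choice(list(AA20 + "X"),
                                                    size=L)))
            v = viterbi_align(profile, seq).score
            f = forward_score(profile, seq)
            assert v == pytest.approx(oracle_viterbi(profile, seq),
                                      rel=1e-9, abs=1e-9)
            assert f == pytest.approx(oracle_forward(profile, seq),
                                      rel=1e-9, abs=1e-9)

    def test_forward_never_below_viterbi(self):
        rng = np.random.default_rng(77)
        for case in range(30):
            msa = random_toy_msa(rng, int(rng.integers(1, 10)),
                                 int(rng.integers(2, 6)))
            profile, _ = build_profile(msa, "s0")
            seq = SequenceRecord(
                id="q", residues="".join(rng.choice(list(AA20),
                                                    size=rng.integers(1, 15))))
            assert forward_score(profile, seq) >= \
                viterbi_align(profile, seq).score - 1e-9


class TestScoreProperties:
    def test_appending_conserved_column_never_lowers_score(self):
        rng = np.random.default_rng(5)
        for case in range(10):
            fam = make_family(seed=200 + case, n=8,
                              length=int(rng.integers(20, 60)),
                              identity=0.7, indel_rate=0.02)
            profile, _ = build_profile(fam.alignment, "ref")
            query = fam.homologs[0]
            base = viterbi_align(profile, query).score
            aa = AA20[rng.integers(20)]
            extended = MultipleAlignment(records=tuple(
                AlignedRow(id=r.id, residues=r.residues + aa)
                for r in fam.alignment.records))
            profile2, _ = build_profile(extended, "ref")
            query2 = SequenceRecord(id="q", residues=query.residues + aa)
            assert viterbi_align(profile2, query2).score >= base - 1e-9

    def test_training_sequences_beat_their_shuffles(self, small_family,
                                                    small_profile):
        profile, _ = small_profile
        rng = np.random.default_rng(9)
        for rec in small_family.all_records[:5]:
            score = viterbi_align(profile, rec).score
            beaten = 0
            for _ in range(20):
                shuffled = "".join(rng.permutation(list(rec.residues)))
                s = viterbi_align(profile, SequenceRecord(
                    id="sh", residues=shuffled)).score
                beaten += s < score
            assert beaten >= 19   # above 95% of length-matched shuffles


class TestSaveLoad:
    def test_round_trip_preserves_scores_bit_exactly(self, tmp_path,
                                                     small_profile):
        profile, refmap = small_profile
        path = tmp_path / "profile.json"
        save_profile(profile, refmap, path)
        loaded, refmap2 = load_profile(path)
        assert loaded.checksum == profile.checksum
        assert refmap2 == refmap
        rng = np.random.default_rng(4)
        for _ in range(10):
            seq = SequenceRecord(
                id="q", residues="".join(rng.choice(list(AA20),
                                                    size=rng.integers(5, 80))))
            assert viterbi_align(loaded, seq).score == \
                viterbi_align(profile, seq).score
            assert forward_score(loaded, seq) == forward_score(profile, seq)

    def test_truncated_file_rejected(self, tmp_path, small_profile):
        profile, refmap = small_profile
        path = tmp_path / "profile.json"
        save_profile(profile, refmap, path)
        path.write_text(path.read_text()[:200])
        with pytest.raises(InputError):
            load_profile(path)

    def test_version_mismatch_rejected(self, tmp_path, small_profile):
        profile, refmap = small_profile
        path = tmp_path / "profile.json"
        save_profile(profile, refmap, path)
        doc = json.loads(path.read_text())
        doc["version"] = 999
        path.write_text(json.dumps(doc))
        with pytest.raises(InputError, match="version"):
            load_profile(path)

    def test_tampered_parameters_fail_checksum(self, tmp_path, small_profile):
        profile, refmap = small_profile
        path = tmp_path / "profile.json"
        save_profile(profile, refmap, path)
        doc = json.loads(path.read_text())
        doc["match_emissions"][0][0] += 1e-6
        path.write_text(json.dumps(doc))
        with pytest.raises(InputError, match="checksum"):
            load_profile(path)
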