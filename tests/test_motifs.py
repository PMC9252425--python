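"""Motif scanning, clade rules, motif comparison, subfamily assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mybscope import motifs, simulate
from mybscope.motifs import (MotifMatrix, POACEAE_MOTIFS,
                             build_presence_table, classify_clades,
                             classify_poaceae_clade, compare_motifs,
                             presence_correlation, read_meme, scan_motif,
                             assign_subfamily, write_meme)
from mybscope.simulate import AA20, make_motif_matrix


@pytest.fixture(scope="module")
def ps_motifs():
    consensi = {"PS1": "WDEKLRAMYCE", "PS2": "HNIKQWFAMGD",
                "PS3": "CYQRTPLENVW", "PS4": "MGDHAWKYLTR",
                "PS5": "ENQFCVMIRGA", "motif12": "KRTYWQPLDSH"}
    return {mid: make_motif_matrix(c, mid) for mid, c in consensi.items()}


class TestMotifMatrix:
    def test_width_bounds_enforced(self):
        with pytest.raises(ValueError):
            make_motif_matrix("ACDEF")  # width 5 < 6
        with pytest.raises(ValueError):
            make_motif_matrix("A" * 54)

    def test_columns_must_sum_to_one(self):
        bad = np.full((8, 20), 0.04)
        with pytest.raises(ValueError):
            MotifMatrix("bad", bad)

    def test_tsv_round_trip(self, ps_motifs, tmp_path):
        m = ps_motifs["PS1"]
        m.to_tsv(tmp_path / "m.tsv")
        back = MotifMatrix.from_tsv(tmp_path / "m.tsv", "PS1")
        assert np.allclose(back.probs, m.probs)

    def test_meme_round_trip(self, ps_motifs, tmp_path):
        mats = list(ps_motifs.values())
        write_meme(mats, tmp_path / "m.meme")
        back = read_meme(tmp_path / "m.meme")
        assert [m.motif_id for m in back] == [m.motif_id for m in mats]
        for a, b in zip(mats, back):
            assert np.allclose(a.probs, b.probs, atol=1e-6)


class TestScanMotif:
    def test_consensus_scores_maximally_and_is_present(self, ps_motifs):
        m = ps_motifs["PS1"]
        seq = "ACDEF" + m.consensus() + "KLMNP"
        hit = scan_motif(seq, m)
        assert hit.present and hit.offset == 5
        assert hit.score == pytest.approx(m.max_score())

    def test_zero_threshold_makes_everything_present(self, ps_motifs):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list(AA20))[rng.integers(0, 20, 50)])
        assert scan_motif(seq, ps_motifs["PS2"], threshold_fraction=0.0).present

    def test_null_presence_rate_below_five_percent(self, ps_motifs):
        m = ps_motifs["PS3"]
        rng = np.random.default_rng(5)
        aa = np.array(list(AA20))
        n_present = sum(
            scan_motif("".join(aa[rng.integers(0, 20, 100)]), m).present
            for _ in range(1000))
        assert n_present / 1000 < 0.05

    def test_short_sequence_absent_with_warning(self, ps_motifs):
        with pytest.warns(UserWarning):
            hit = scan_motif("ACD", ps_motifs["PS1"])
        assert not hit.present and hit.offset == -1


class TestCladeRules:
    def test_exhaustive_truth_table(self):
        """All 64 presence combinations match the documented rule text."""
        for bits in itertools.product([False, True], repeat=6):
            row = dict(zip(POACEAE_MOTIFS, bits))
            got = classify_poaceae_clade(row)
            ps1, ps2, ps3, ps4, ps5, m12 = (row[k] for k in POACEAE_MOTIFS)
            if ps1 and m12 and not ps2:
                expect = "poaceae_specific_A"
            elif ps1 and ps2 and not m12:
                expect = "poaceae_specific_B"
            elif ps3:
                expect = "poaceae_unique"
            elif ps4 and ps5:
                expect = "poaceae_basal"
            else:
                expect = "unclassified"
            assert got == expect

    def test_missing_motif_column_rejected(self):
        with pytest.raises(ValueError, match="PS5"):
            classify_poaceae_clade({m: True for m in POACEAE_MOTIFS[:-2]
                                    } | {"motif12": True})

    def test_planted_motif_sequences_classify_perfectly(self, ps_motifs):
        assignments = {
            "a1": ["PS1", "motif12"], "a2": ["PS1", "motif12"],
            "b1": ["PS1", "PS2"], "b2": ["PS1", "PS2"],
            "u1": ["PS3"], "bas1": ["PS4", "PS5"],
            "none1": [], "none2": [],
        }
        expected = {"a1": "poaceae_specific_A", "a2": "poaceae_specific_A",
                    "b1": "poaceae_specific_B", "b2": "poaceae_specific_B",
                    "u1": "poaceae_unique", "bas1": "poaceae_basal",
                    "none1": "unclassified", "none2": "unclassified"}
        seqs = simulate.plant_motifs_in_sequences(assignments, ps_motifs,
                                                  seed=3)
        table = build_presence_table(seqs, list(ps_motifs.values()))
        clades = classify_clades(table)
        assert dict(zip(clades.sequence_id, clades.clade)) == expected

    def test_override_pins_documented_exceptions(self, ps_motifs):
        seqs = simulate.plant_motifs_in_sequences({"odd": ["PS3"]},
                                                  ps_motifs, seed=4)
        table = build_presence_table(seqs, list(ps_motifs.values()))
        got = classify_clades(table, overrides={"odd": "poaceae_basal"})
        assert got.clade.iloc[0] == "poaceae_basal"


class TestCompareMotifs:
    def test_self_similarity_is_one(self, ps_motifs):
        m = ps_motifs["PS1"]
        assert compare_motifs(m, m) == pytest.approx(1.0)

    def test_symmetry(self, ps_motifs):
        a, b = ps_motifs["PS1"], ps_motifs["PS3"]
        assert abs(compare_motifs(a, b) - compare_motifs(b, a)) < 1e-12

    def test_disjoint_single_residue_columns_not_positive(self):
        m1 = make_motif_matrix("AAAAAA", "m1", sharpness=1.0 - 1e-12)
        m2 = make_motif_matrix("CCCCCC", "m2", sharpness=1.0 - 1e-12)
        assert compare_motifs(m1, m2) <= 0

    def test_invariant_under_joint_residue_permutation(self, ps_motifs):
        a, b = ps_motifs["PS1"], ps_motifs["PS2"]
        perm = np.random.default_rng(7).permutation(20)
        a2 = MotifMatrix("a2", a.probs[:, perm])
        b2 = MotifMatrix("b2", b.probs[:, perm])
        assert compare_motifs(a2, b2) == pytest.approx(compare_motifs(a, b))

    def test_min_overlap_larger_than_short_motif_rejected(self, ps_motifs):
        with pytest.raises(ValueError):
            compare_motifs(ps_motifs["PS1"], ps_motifs["PS2"], min_overlap=99)

    def test_planted_correlation_recovered(self):
        m1, m2 = simulate.make_related_motif_pair(0.6, seed=5)
        assert compare_motifs(m1, m2) == pytest.approx(0.6, abs=1e-3)


class TestPresenceCorrelation:
    def _table(self, cols):
        df = pd.DataFrame(cols)
        return motifs.PresenceTable(df.astype(bool), df * 1.0, df * 0)

    def test_identical_and_complementary_columns(self):
        t = self._table({"A": [1, 0, 1, 0], "B": [1, 0, 1, 0],
                         "C": [0, 1, 0, 1]})
        phi = presence_correlation(t)
        assert phi.loc["A", "B"] == pytest.approx(1.0)
        assert phi.loc["A", "C"] == pytest.approx(-1.0)

    def test_constant_column_reported_missing(self):
        t = self._table({"A": [1, 0, 1], "B": [1, 1, 1]})
        phi = presence_correlation(t)
        assert np.isnan(phi.loc["A", "B"])
        assert phi.loc["B", "B"] == 1.0

    def test_matches_contingency_table_phi(self):
        """Planted ~60%-overlap columns agree with the 2x2-table formula."""
        rng = np.random.default_rng(9)
        n = 43
        a = rng.random(n) < 0.5
        b = a.copy()
        flip = rng.choice(n, size=17, replace=False)
        b[flip] = ~b[flip]
        t = self._table({"A": a.astype(int), "B": b.astype(int)})
        n11 = int(np.sum(a & b)); n10 = int(np.sum(a & ~b))
        n01 = int(np.sum(~a & b)); n00 = int(np.sum(~a & ~b))
        phi_2x2 = (n11 * n00 - n10 * n01) / np.sqrt(
            (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
        assert presence_correlation(t).loc["A", "B"] == pytest.approx(phi_2x2)


class TestSubfamily:
    NEWICK = "((q1:1,ref1:1):1,((ref2:1,ref3:1):1,(q2:1,(refA:1,refB:1):1):1):1);"

    def test_sister_reference_labels_query(self):
        labels = {"ref1": "S1", "ref2": "S20", "ref3": "S20",
                  "refA": "S21", "refB": "S22"}
        out = assign_subfamily(self.NEWICK, labels)
        assert out["q1"] == "S1"

    def test_majority_vote_in_enclosing_clade(self):
        nwk = "(q:1,(r1:1,(r2:1,(r3:1,r4:1):1):1):1);"
        out = assign_subfamily(nwk, {"r1": "S20", "r2": "S20",
                                     "r3": "S20", "r4": "S1"})
        assert out["q"] == "S20"

    def test_tie_reports_ambiguous(self):
        labels = {"ref1": "S1", "ref2": "S20", "ref3": "S20",
                  "refA": "S21", "refB": "S22"}
        out = assign_subfamily(self.NEWICK, labels)
        assert out["q2"] == "ambiguous"

    def test_invariant_under_leaf_rotation(self):
        labels = {"ref1": "S1", "ref2": "S20", "ref3": "S20",
                  "refA": "S21", "refB": "S22"}
        rotated = ("(((q2:1,(refB:1,refA:1):1):1,(ref3:1,ref2:1):1):1,"
                   "(ref1:1,q1:1):1);")
        assert assign_subfamily(self.NEWICK, labels) == \
            assign_subfamily(rotated, labels)

    def test_no_reference_leaf_rejected(self):
        with pytest.raises(ValueError):
            assign_subfamily("(a:1,b:1);", {"zz": "S1"})
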