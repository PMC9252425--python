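"""Repeat scanning, landmark validation, integrity rules, logo statistics."""

import numpy as np
import pytest

from mybscope import domains, simulate
from mybscope.domains import (DomainAnnotation, RepeatHit, build_profile,
                              compute_logo, group_hits, integrity_filter,
                              scan_repeats, validate_landmarks, window_scores)
from mybscope.simulate import AA20, FamilySimSpec, make_template, simulate_family


class TestBuildProfile:
    def test_identical_sequences_give_point_mass_columns(self):
        prof = build_profile(["ACDEFGHIKL"] * 10, pseudocount=0.0)
        assert prof.length == 10
        assert np.allclose(prof.frequencies.max(axis=1), 1.0)

    def test_large_pseudocount_converges_to_background(self):
        prof = build_profile(["ACDEFGHIKL"] * 5, pseudocount=1e9)
        assert np.allclose(prof.frequencies, 0.05, atol=1e-6)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_profile(["ACDEFGHIKL", "ACDEFGHIK"])

    def test_majority_gap_columns_dropped(self):
        prof = build_profile(["AC-DEFGHIKL", "AC-DEFGHIKL", "ACWDEFGHIKL"],
                             pseudocount=0.0)
        assert prof.length == 10  # the 2/3-gap column is gone

    def test_consensus_of_zero_mutation_domains_matches_constraints(self, template):
        spec = FamilySimSpec(n_true_r2r3=200, n_decoys_per_kind=0,
                             mutation_rate=0.0, seed=3)
        seqs, truth = simulate_family(spec, template)
        doms = [seqs[r.seq_id][r.domain_start - 1:r.domain_end]
                for r in truth.itertuples()]
        prof = build_profile(doms, pseudocount=0.0)
        consensus = "".join(AA20[i] for i in prof.frequencies.argmax(axis=1))
        for pos, res in template.constraints().items():
            assert consensus[pos - 1] == res


class TestScanRepeats:
    def test_true_member_yields_two_hits_at_planted_offsets(
            self, clean_family, profile):
        seqs, truth = clean_family
        for row in truth[truth.true_class == "R2R3"].itertuples():
            hits = scan_repeats(seqs[row.seq_id], profile)
            assert len(hits) == 2
            assert hits[0].start == row.r2_start
            assert hits[1].start == row.r3_start
            assert [h.repeat_index for h in hits] == [1, 2]

    def test_single_repeat_decoy_yields_one_hit(self, clean_family, profile):
        seqs, truth = clean_family
        for row in truth[truth.true_class == "single_repeat"].itertuples():
            assert len(scan_repeats(seqs[row.seq_id], profile)) == 1

    def test_short_sequence_warns_and_returns_empty(self, profile):
        with pytest.warns(UserWarning, match="shorter"):
            assert scan_repeats("ACDEF", profile) == []

    def test_null_false_positive_rate_below_five_percent(self, profile):
        """Composition-matched random sequences almost never produce hits."""
        rng = np.random.default_rng(99)
        aa = np.array(list(AA20))
        n_with_hit = 0
        for _ in range(1000):
            seq = "".join(aa[rng.integers(0, 20, size=200)])
            if scan_repeats(seq, profile):
                n_with_hit += 1
        assert n_with_hit / 1000 < 0.05

    def test_hit_count_invariant_under_flanking(self, profile, template):
        dom = make_template(template, seed=21)
        rng = np.random.default_rng(22)
        aa = np.array(list(AA20))
        base_hits = scan_repeats("X" * 0 + dom, profile)
        for flank_len in (5, 40, 120):
            left = "".join(aa[rng.integers(0, 20, size=flank_len)])
            right = "".join(aa[rng.integers(0, 20, size=flank_len)])
            hits = scan_repeats(left + dom + right, profile)
            assert len(hits) == len(base_hits)
            assert [h.start - flank_len for h in hits] == \
                [h.start for h in base_hits]

    def test_window_scores_match_manual_sum(self, profile, template):
        dom = make_template(template, seed=30)
        scores = window_scores(dom, profile)
        lo = profile.log_odds
        manual = sum(lo[j, AA20.index(dom[j])] for j in range(profile.length))
        assert scores[0] == pytest.approx(manual)


class TestGroupHits:
    def test_adjacent_hits_form_one_group(self):
        h = [RepeatHit(1, 52, 30.0, 1), RepeatHit(53, 104, 30.0, 2)]
        assert len(group_hits(h)) == 1

    def test_distant_hits_split_groups(self):
        h = [RepeatHit(1, 52, 30.0, 1), RepeatHit(200, 251, 30.0, 2)]
        groups = group_hits(h)
        assert [len(g) for g in groups] == [1, 1]


class TestLandmarks:
    def test_zero_mutation_domain_reports_all_landmarks(self, template, profile):
        dom = make_template(template, seed=8)
        hits = scan_repeats(dom, profile)
        rep = validate_landmarks(dom, hits[0], hits[1], template)
        assert rep.w_match_count == 5
        assert rep.l35_present and rep.linker_has_LRPD
        assert rep.r3_first_compliant
        assert rep.conserved_matches == 13
        assert sorted(rep.landmark_states) == [6, 26, 46, 78, 97]

    def test_hydrophobic_substitutions_at_r3_landmarks(self, template, profile):
        """W78->F and W97->Y leave three intact tryptophans."""
        dom = list(make_template(template, seed=8))
        dom[77], dom[96] = "F", "Y"
        dom = "".join(dom)
        hits = scan_repeats(dom, profile)
        assert len(hits) == 2
        rep = validate_landmarks(dom, hits[0], hits[1], template)
        assert rep.w_match_count == 3

    def test_overlapping_hits_rejected(self, template):
        with pytest.raises(ValueError, match="overlap"):
            validate_landmarks("A" * 200, RepeatHit(1, 52, 1.0, 1),
                               RepeatHit(40, 91, 1.0, 2), template)


class TestIntegrity:
    @pytest.mark.parametrize("n_destroyed,expect_pass",
                             [(0, True), (1, True), (2, True),
                              (3, False), (4, False), (5, False)])
    def test_tryptophan_boundary_more_than_two_missing_fails(
            self, template, profile, n_destroyed, expect_pass):
        dom = list(make_template(template, seed=13))
        for pos in template.tryptophan_landmarks[:n_destroyed]:
            dom[pos - 1] = "A"
        dom = "".join(dom)
        ann = domains.annotate_domain(dom, profile, template)
        if ann.n_repeats >= 2:
            assert ann.landmark_report.w_match_count == 5 - n_destroyed
            assert ann.integrity_pass is expect_pass
        else:
            # scan itself lost a repeat: destroying landmarks never rescues
            assert not expect_pass
            assert ann.integrity_reason == "incomplete_repeat"

    def test_monotone_in_landmark_destruction(self, template, profile):
        """Destroying one more landmark never turns fail into pass."""
        dom = make_template(template, seed=14)
        passes = []
        chars = list(dom)
        for pos in template.tryptophan_landmarks:
            chars[pos - 1] = "A"
            ann = domains.annotate_domain("".join(chars), profile, template)
            passes.append(bool(ann.integrity_pass))
        for earlier, later in zip(passes, passes[1:]):
            assert earlier or not later

    def test_truncated_decoy_fails_as_incomplete(self, clean_family, profile,
                                                 template):
        seqs, truth = clean_family
        for row in truth[truth.true_class == "truncated_repeat"].itertuples():
            ann = domains.annotate_domain(seqs[row.seq_id], profile, template)
            assert ann.integrity_pass is False
            assert ann.integrity_reason == "incomplete_repeat"

    def test_w_deficient_decoys_fail_validation(self, clean_family, profile,
                                                template):
        seqs, truth = clean_family
        for row in truth[truth.true_class == "w_deficient"].itertuples():
            ann = domains.annotate_domain(seqs[row.seq_id], profile, template)
            assert ann.integrity_pass is False
            if ann.landmark_report is not None:
                assert ann.landmark_report.w_match_count <= 2


class TestEndToEnd:
    def test_classification_recovers_truth_exactly(self, noisy_family,
                                                   noisy_annotations):
        """True members and single-repeat decoys classify perfectly at 5%."""
        _, truth = noisy_family
        classes = truth.set_index("seq_id").true_class
        for sid, ann in noisy_annotations.items():
            if classes[sid] == "R2R3":
                assert ann.myb_class == "R2R3" and ann.integrity_pass
            elif classes[sid] == "single_repeat":
                assert ann.myb_class == "MYB_related"
            if classes[sid] != "R2R3" and classes[sid] != "triple_repeat":
                assert not ann.integrity_pass


class TestLogo:
    def test_all_w_column_attains_maximal_information(self):
        logo = compute_logo(["WA", "WC", "WD", "WW"])
        assert logo.IC_bits.loc[1] == pytest.approx(np.log2(20))
        assert logo.W.loc[1] == pytest.approx(np.log2(20))

    def test_uniform_column_has_zero_information(self):
        logo = compute_logo([a + "W" for a in AA20])
        assert logo.IC_bits.loc[1] == pytest.approx(0.0, abs=1e-12)

    def test_ic_bounds_and_correction_direction(self, noisy_family):
        seqs, truth = noisy_family
        doms = [seqs[r.seq_id][r.domain_start - 1:r.domain_end]
                for r in truth[truth.true_class == "R2R3"].itertuples()]
        raw = compute_logo(doms, small_sample_correction=False)
        corr = compute_logo(doms, small_sample_correction=True)
        assert ((raw.IC_bits >= 0) & (raw.IC_bits <= np.log2(20) + 1e-12)).all()
        assert (corr.IC_bits <= raw.IC_bits + 1e-12).all()

    def test_landmark_columns_attain_maximal_ic(self, noisy_family, template):
        seqs, truth = noisy_family
        doms = [seqs[r.seq_id][r.domain_start - 1:r.domain_end]
                for r in truth[truth.true_class == "R2R3"].itertuples()]
        logo = compute_logo(doms)
        top = logo.IC_bits.max()
        for pos in template.tryptophan_landmarks:
            assert logo.IC_bits.loc[pos] == pytest.approx(top)

    def test_majority_gap_columns_excluded(self):
        logo = compute_logo(["A-C", "A-C", "AWC", "A-C"])
        assert list(logo.index) == [1, 3]

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            compute_logo([])
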