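"""In-silico digestion, peptide uniqueness, FDR filtering and identification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import parser as pyt_parser

from venomine import proteomics
from venomine.precursor import MatureVariant
from venomine.proteomics import (
    PSMRecord,
    amidation_evidence,
    build_peptide_index,
    digest,
    fdr_filter,
    identify_toxins,
    make_protease,
    protease_set_comparison,
    select_isoform,
    sequence_coverage,
    uniqueness_stats,
)

TRYPSIN = make_protease("trypsin")
LYSC = make_protease("lysC")
GLUC = make_protease("gluC")
ASPN = make_protease("aspN")

proteins = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60)


def variant(parent, seq, amidated=False, vid=None):
    return MatureVariant(parent, vid or f"{parent}.v1", seq, amidated, "full")


class TestDigest:
    def test_trypsin_proline_rule(self):
        assert [p.sequence for p in digest("AKRPGKC", TRYPSIN, 0)] == ["AK", "RPGK", "C"]

    def test_trypsin_without_proline_rule(self):
        rule = make_protease("trypsin", trypsin_proline_rule=False)
        assert [p.sequence for p in digest("AKRPGKC", rule, 0)] == ["AK", "R", "PGK", "C"]

    def test_aspn_cuts_nterminal_side(self):
        assert [p.sequence for p in digest("AADCA", ASPN, 0)] == ["AA", "DCA"]

    def test_gluc_configurable_specificity(self):
        assert [p.sequence for p in digest("AEADA", GLUC, 0)] == ["AE", "ADA"]
        wide = make_protease("gluC", gluC_cleaves_D=True)
        assert [p.sequence for p in digest("AEADA", wide, 0)] == ["AE", "AD", "A"]

    def test_cterm_flag_and_missed_counts(self):
        peps = digest("AKCKD", TRYPSIN, 2)
        by_seq = {p.sequence: p for p in peps}
        assert by_seq["AKCKD"].missed_cleavages == 2
        assert by_seq["AKCKD"].is_cterm
        assert by_seq["AK"].missed_cleavages == 0
        assert not by_seq["AK"].is_cterm

    def test_empty_protein_raises(self):
        with pytest.raises(ValueError):
            digest("", TRYPSIN, 0)

    @given(proteins)
    @settings(max_examples=200, deadline=None)
    def test_zero_missed_peptides_partition_protein(self, protein):
        for rule in (TRYPSIN, LYSC, GLUC, ASPN):
            assert "".join(p.sequence for p in digest(protein, rule, 0)) == protein

    @given(proteins, st.integers(min_value=0, max_value=4))
    @settings(max_examples=150, deadline=None)
    def test_peptide_count_matches_combinatorial_oracle(self, protein, max_missed):
        peps = digest(protein, TRYPSIN, max_missed)
        n = len(digest(protein, TRYPSIN, 0))  # number of 0-missed fragments
        expected = sum(max(0, n - m) for m in range(max_missed + 1))
        assert len(peps) == expected

    @given(proteins)
    @settings(max_examples=100, deadline=None)
    def test_trypsin_agrees_with_pyteomics_cleave(self, protein):
        ours = {p.sequence for p in digest(protein, TRYPSIN, 2)}
        theirs = pyt_parser.cleave(protein, r"[KR](?!P)", missed_cleavages=2, min_length=1)
        assert ours == set(theirs)


class TestUniqueness:
    DB = {
        "T1": [variant("T1", "AAAKCCCK")],
        "T2": [variant("T2", "AAAKDDDK")],
    }

    def test_shared_and_unique_peptides(self):
        index = build_peptide_index(self.DB, TRYPSIN, max_missed=0, min_len=3)
        assert index.lookup("AAAK", False).parents == {"T1", "T2"}
        assert not index.lookup("AAAK", False).unique
        assert index.lookup("CCCK", False).parents == {"T1"}
        assert index.lookup("CCCK", False).unique

    def test_single_protein_db_all_unique(self):
        index = build_peptide_index({"T1": [variant("T1", "AAKCCK")]}, TRYPSIN)
        assert all(e.unique for e in index.entries.values())

    def test_isoforms_do_not_break_uniqueness(self):
        db = {"T1": [variant("T1", "AAKCCK", vid="v1"), variant("T1", "AAKCC", vid="v2")]}
        index = build_peptide_index(db, TRYPSIN)
        assert index.lookup("AAK", False).unique

    def test_il_equivalence(self):
        db = {"T1": [variant("T1", "AIAK")], "T2": [variant("T2", "ALAK")]}
        index = build_peptide_index(db, TRYPSIN)
        assert index.lookup("AIAK", False).parents == {"T1", "T2"}

    def test_uniqueness_stats_counts_distinct_sequences(self):
        total, non_unique = uniqueness_stats(self.DB, TRYPSIN, min_len=3)
        # pooled distinct peptides: AAAK (shared), CCCK, DDDK
        assert (total, non_unique) == (3, 1)

    def test_parent_sets_agree_with_pyteomics_per_variant_oracle(self):
        rng = np.random.default_rng(5)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(100):
            db = {
                f"T{i}": [variant(f"T{i}", "".join(rng.choice(aas, size=rng.integers(8, 25))))]
                for i in range(rng.integers(2, 5))
            }
            index = build_peptide_index(db, TRYPSIN, max_missed=1, min_len=1,
                                        il_equivalent=False)
            oracle = {}
            for gid, variants in db.items():
                peps = pyt_parser.cleave(
                    variants[0].sequence, r"[KR](?!P)", missed_cleavages=1, min_length=1
                )
                for pep in peps:
                    oracle.setdefault(pep, set()).add(gid)
            got = {key[0]: e.parents for key, e in index.entries.items() if not key[1]}
            assert got == oracle


class TestFdrFilter:
    @staticmethod
    def psm(score, decoy, peptide="PEPTIDEK"):
        return PSMRecord(peptide, "trypsin", "1", float(score), decoy)

    def test_weak_decoy_excluded_all_targets_pass(self):
        psms = [self.psm(s, False) for s in range(2, 101)] + [self.psm(1, True)]
        accepted = fdr_filter(psms, alpha=0.01)
        assert len(accepted) == 99

    def test_all_decoys_empty(self):
        assert fdr_filter([self.psm(5, True)] * 3, alpha=0.5) == []

    def test_alpha_one_accepts_all_targets(self):
        psms = [self.psm(s, False) for s in (5, 6, 7)] + [self.psm(4, True)]
        assert len(fdr_filter(psms, alpha=1.0)) == 3

    def test_threshold_excludes_low_scoring_targets_below_decoys(self):
        psms = [self.psm(10, False)] * 50 + [self.psm(5, True)] * 5 + [self.psm(4, False)] * 5
        accepted = fdr_filter(psms, alpha=0.01)
        assert all(p.score == 10 for p in accepted)

    def test_agrees_with_bruteforce_threshold_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            scores = np.round(rng.normal(5, 2, size=60), 1)
            decoys = rng.random(60) < 0.4
            psms = [self.psm(s, bool(d)) for s, d in zip(scores, decoys)]
            for alpha in (0.01, 0.1, 0.5):
                accepted = fdr_filter(psms, alpha=alpha)
                best = []
                for t in sorted(set(scores)):
                    n_d = sum(1 for p in psms if p.decoy and p.score >= t)
                    n_t = sum(1 for p in psms if not p.decoy and p.score >= t)
                    if n_t and n_d / n_t <= alpha:
                        cand = [p for p in psms if not p.decoy and p.score >= t]
                        if len(cand) > len(best):
                            best = cand
                assert len(accepted) == len(best)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        psms = [self.psm(s, bool(d)) for s, d in
                zip(rng.normal(5, 2, 40), rng.random(40) < 0.3)]
        a = {(p.score, p.decoy) for p in fdr_filter(psms, 0.1)}
        b = {(p.score, p.decoy) for p in fdr_filter(psms[::-1], 0.1)}
        assert a == b

    def test_lower_alpha_never_adds_psms(self):
        rng = np.random.default_rng(9)
        psms = [self.psm(s, bool(d)) for s, d in
                zip(rng.normal(5, 2, 80), rng.random(80) < 0.3)]
        sizes = [len(fdr_filter(psms, a)) for a in (0.5, 0.2, 0.1, 0.05, 0.01)]
        assert sizes == sorted(sizes, reverse=True)


class TestSequenceCoverage:
    def test_disjoint_intervals(self):
        toxin = "A" * 20 + "C" * 20 + "D" * 10
        assert sequence_coverage(toxin, ["A" * 20, "D" * 10]) == pytest.approx(0.6)

    def test_overlap_counted_once(self):
        toxin = "ACDEFGHIKLMNPQRSTVWY" + "AADDEEFFGG"  # 30 residues
        peptides = [toxin[0:10], toxin[5:15]]  # union covers [0, 15)
        assert sequence_coverage(toxin, peptides) == pytest.approx(0.5)

    def test_no_peptides_zero(self):
        assert sequence_coverage("ACDEF", []) == 0.0

    def test_il_collapsed_matching(self):
        assert sequence_coverage("AILK", ["ALLK"]) == 1.0


# ---------------------------------------------------------------------------
# Identification on a small handcrafted database

DB = {
    "T1": [variant("T1", "AAACDEFKGGGWWWK")],
    "T2": [variant("T2", "AAACDEFKHHHYYYK")],
    "T3": [variant("T3", "MMMNNPPKQQQSSTK")],
}
INDEXES = {"trypsin": build_peptide_index(DB, TRYPSIN)}


def obs(peptide, score=10.0, amid=False):
    return PSMRecord(peptide, "trypsin", "1", score, False, amid)


class TestIdentifyToxins:
    def test_unique_peptide_identifies_toxin(self):
        results, unmatched = identify_toxins([obs("GGGWWWK")], INDEXES, DB)
        by_id = {r.toxin_id: r for r in results}
        assert by_id["T1"].status == "unique_identified"
        assert by_id["T2"].status == "not_detected"
        assert not unmatched

    def test_shared_peptide_gives_group_evidence_only(self):
        results, _ = identify_toxins([obs("AAACDEFK")], INDEXES, DB)
        by_id = {r.toxin_id: r for r in results}
        assert by_id["T1"].status == "group_evidence_only"
        assert by_id["T2"].status == "group_evidence_only"

    def test_unknown_peptide_logged_as_unmatched(self):
        results, unmatched = identify_toxins([obs("ZZZZZZK".replace("Z", "W"))], INDEXES, DB)
        assert len(unmatched) == 1
        assert all(r.status == "not_detected" for r in results)

    def test_coverage_all_at_least_coverage_unique(self):
        results, _ = identify_toxins(
            [obs("GGGWWWK"), obs("AAACDEFK")], INDEXES, DB
        )
        for r in results:
            assert 0.0 <= r.coverage_unique <= r.coverage_all <= 1.0


class TestSelectIsoform:
    def test_unique_evidence_wins(self):
        variants = [variant("T", "AAAKCCCK", vid="a"), variant("T", "AAAK", vid="b")]
        vid, cov_u, cov_a = select_isoform(variants, {"CCCK"}, {"CCCK", "AAAK"})
        assert vid == "a"

    def test_higher_unique_coverage_wins(self):
        variants = [variant("T", "CCCKAAAAAAAAAAAA", vid="a"), variant("T", "CCCKAA", vid="b")]
        vid, cov_u, _ = select_isoform(variants, {"CCCK"}, {"CCCK"})
        assert vid == "b"  # 4/6 coverage beats 4/16

    def test_no_evidence_gives_zero_coverage(self):
        vid, cov_u, cov_a = select_isoform([variant("T", "AAAK", vid="a")], set(), set())
        assert (cov_u, cov_a) == (0.0, 0.0)


class TestAmidationEvidence:
    AMIDB = {
        "T1": [variant("T1", "AAACDEFKGGGWWWKR", vid="full"),
               variant("T1", "AAACDEFKGGGWWW", True, vid="amid")],
        "T2": [variant("T2", "MMMNNPPKQQQSSTK")],
    }
    IDX = {"trypsin": build_peptide_index(AMIDB, TRYPSIN)}

    def test_unique_amidated_cterm_confirms(self):
        ev = amidation_evidence("T1", [obs("GGGWWW", amid=True)], self.IDX, True)
        assert ev.category == "confirmed_unique"

    def test_both_forms_ambiguous(self):
        psms = [obs("GGGWWW", amid=True), obs("GGGWWWKR")]
        ev = amidation_evidence("T1", psms, self.IDX, True)
        assert ev.category == "ambiguous"
        assert ev.n_amidated_psms == 1 and ev.n_plain_psms == 1

    def test_plain_only_not_amidated(self):
        ev = amidation_evidence("T1", [obs("GGGWWWKR")], self.IDX, True)
        assert ev.category == "not_amidated"

    def test_uncovered_cterm_undefined(self):
        ev = amidation_evidence("T1", [obs("AAACDEFK")], self.IDX, True)
        assert ev.category == "undefined"


class TestProteaseSetComparison:
    def test_three_region_partition(self):
        regions = protease_set_comparison({"x": {"A", "B"}, "y": {"B", "C"}})
        assert regions[("x",)] == 1
        assert regions[("y",)] == 1
        assert regions[("x", "y")] == 1

    def test_identical_sets_all_shared(self):
        regions = protease_set_comparison({"x": {"A", "B"}, "y": {"A", "B"}})
        assert regions[("x", "y")] == 2
        assert regions[("x",)] == regions[("y",)] == 0

    def test_disjoint_sets(self):
        regions = protease_set_comparison({"x": {"A"}, "y": {"B"}})
        assert regions[("x", "y")] == 0

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            protease_set_comparison({"x": {"A"}})
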