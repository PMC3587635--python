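import numpy as np
import pytest

from ssrmir.io_formats import Transcript, dna_to_rna, revcomp, rna_to_dna
from ssrmir.rna_fold import duplex_energy
from ssrmir.target_prediction import (
    MISMATCH,
    WC,
    WOBBLE,
    TargetConfig,
    classify_pair,
    predict_targets,
    report_targets,
    scan_targets,
    score_and_filter,
)

MIRNA = "GCGGCUGCAGCGGCUUGGGAG"  # 21 nt, GC-rich
SITE = rna_to_dna("CUCCCAAGCCGCUGCAGCCGC")  # exact antisense match


def _transcript_with_site(site_dna, flank5="ATATAT", flank3="CGCGCG", tid="t"):
    return Transcript(id=tid, seq=flank5 + site_dna + flank3)


class TestScanTargets:
    def test_exact_complement_found_with_zero_mismatches(self):
        t = _transcript_with_site(SITE)
        alns = scan_targets(MIRNA, t)
        perfect = [a for a in alns if all(c == WC for c in a.classes)]
        assert len(perfect) == 1
        a = perfect[0]
        assert a.orientation == "plus"
        assert (a.target_interval.start, a.target_interval.end) == (6, 27)

    def test_equal_length_transcript_gives_two_alignments(self):
        t = Transcript(id="t", seq=SITE)
        assert len(scan_targets(MIRNA, t)) == 2

    def test_shorter_transcript_yields_nothing(self):
        assert scan_targets(MIRNA, Transcript(id="t", seq="ACGT")) == []

    def test_mirna_length_bounds(self):
        with pytest.raises(ValueError):
            scan_targets("ACGU" * 3, Transcript(id="t", seq=SITE))

    def test_minus_orientation_site_found(self):
        t = Transcript(id="t", seq="AATT" + revcomp(SITE) + "GGCC")
        alns = scan_targets(MIRNA, t)
        perfect = [a for a in alns if all(c == WC for c in a.classes)]
        assert len(perfect) == 1
        assert perfect[0].orientation == "minus"
        assert perfect[0].target_interval.start == 4


class TestClassifyPair:
    @pytest.mark.parametrize(
        "m,t,expected",
        [
            ("A", "U", WC), ("G", "C", WC),
            ("G", "U", WOBBLE), ("U", "G", WOBBLE),
            ("A", "G", MISMATCH), ("C", "U", MISMATCH), ("A", "A", MISMATCH),
        ],
    )
    def test_classes(self, m, t, expected):
        assert classify_pair(m, t) == expected


def _site_with_mismatches(positions, wobble=()):
    """Mutate the perfect site so the miRNA mismatches at given 1-based
    miRNA positions (non-pairing base), or wobbles at `wobble` positions."""
    m = len(MIRNA)
    site = list(SITE)
    non_pairing = {"A": "C", "C": "A", "G": "A", "U": "C"}
    for k in positions:
        site[m - k] = rna_to_dna(non_pairing[MIRNA[k - 1]])
    for k in wobble:
        assert MIRNA[k - 1] == "G"
        site[m - k] = "T"  # G:U wobble
    return "".join(site)


def _hit_for(site_dna, cfg=None):
    t = _transcript_with_site(site_dna)
    alns = scan_targets(MIRNA, t)
    (aln,) = [
        a
        for a in alns
        if a.orientation == "plus" and a.target_interval.start == 6
    ]
    return score_and_filter(aln, t, cfg)


class TestScoreAndFilter:
    def test_perfect_complement_passes_with_zero_score(self):
        h = _hit_for(SITE)
        assert h.passed and h.total_mismatch_score == 0.0
        assert h.duplex_mfe == pytest.approx(
            duplex_energy(MIRNA, dna_to_rna(SITE)), abs=1e-6
        )
        assert h.duplex_mfe <= -30

    @pytest.mark.parametrize("pos", [10, 11])
    def test_cleavage_site_mismatch_excluded(self, pos):
        h = _hit_for(_site_with_mismatches([pos]))
        assert not h.passed and "CLEAVAGE" in h.fail_reasons

    def test_cleavage_wobble_also_fails(self):
        # position 10 of the miRNA is a G here: G:U wobble is not WC
        assert MIRNA[9] == "G"
        h = _hit_for(_site_with_mismatches([], wobble=[10]))
        assert "CLEAVAGE" in h.fail_reasons

    def test_three_consecutive_mismatches_fail(self):
        h = _hit_for(_site_with_mismatches([13, 14, 15]))
        assert not h.passed and "CONSECUTIVE" in h.fail_reasons

    def test_two_consecutive_allowed(self):
        h = _hit_for(_site_with_mismatches([13, 14]))
        assert "CONSECUTIVE" not in h.fail_reasons

    def test_total_score_over_three_fails(self):
        h = _hit_for(_site_with_mismatches([1, 8, 13, 16]))
        assert "TOTAL_MM" in h.fail_reasons

    def test_seed_mismatch_fails(self):
        h = _hit_for(_site_with_mismatches([4]))
        assert "SEED" in h.fail_reasons

    def test_one_seed_wobble_tolerated_two_fail(self):
        g_positions = [k for k in range(2, 7) if MIRNA[k - 1] == "G"]
        assert len(g_positions) >= 2
        one = _hit_for(_site_with_mismatches([], wobble=g_positions[:1]))
        assert "SEED" not in one.fail_reasons
        two = _hit_for(_site_with_mismatches([], wobble=g_positions[:2]))
        assert "SEED" in two.fail_reasons

    def test_strict_seed_policy_rejects_single_wobble(self):
        g_positions = [k for k in range(2, 7) if MIRNA[k - 1] == "G"]
        cfg = TargetConfig(seed_policy="strict")
        h = _hit_for(_site_with_mismatches([], wobble=g_positions[:1]), cfg)
        assert "SEED" in h.fail_reasons

    def test_filter_is_monotone_in_mismatches(self, rng):
        # adding one more mismatch to a failing alignment never rescues it
        base_positions = [13, 14, 15]
        base = _hit_for(_site_with_mismatches(base_positions))
        assert not base.passed
        for extra in (1, 8, 17, 20):
            worse = _hit_for(_site_with_mismatches(base_positions + [extra]))
            assert not worse.passed


class TestOracleEquivalence:
    def test_matches_straightforward_enumeration(self, rng):
        """Window enumeration vs an independent quadratic re-implementation."""
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(10):
            mirna = "".join("ACGU"[i] for i in rng.integers(0, 4, size=20))
            tdna = "".join("ACGT"[i] for i in rng.integers(0, 4, size=28))
            t = Transcript(id="t", seq=tdna)
            got = {
                (a.orientation, a.target_interval.start, a.classes)
                for a in scan_targets(mirna, t)
            }
            expected = set()
            m = len(mirna)
            for orient in ("plus", "minus"):
                strand = dna_to_rna(tdna if orient == "plus" else revcomp(tdna))
                for s in range(len(tdna) - m + 1):
                    site = strand[s : s + m]
                    classes = []
                    for k in range(m):
                        a, b = mirna[k], site[m - 1 - k]
                        if comp[a] == b:
                            classes.append(WC)
                        elif {a, b} == {"G", "U"}:
                            classes.append(WOBBLE)
                        else:
                            classes.append(MISMATCH)
                    start = s if orient == "plus" else len(tdna) - s - m
                    expected.add((orient, start, tuple(classes)))
            assert got == expected


class TestTruthTable:
    def test_planted_sites_pass_or_fail_as_designed(self, small_dataset):
        ds = small_dataset
        hits = predict_targets(ds.mirnas, ds.transcripts)
        n_checked = 0
        for rec in ds.truth["transcripts"]:
            for tt in rec["targets"]:
                match = [
                    h
                    for h in hits
                    if h.mirna_id == tt["mirna_id"]
                    and h.target_id == rec["id"]
                    and h.alignment.target_interval.start == tt["start"]
                    and h.alignment.orientation == "plus"
                ]
                assert len(match) == 1
                h = match[0]
                assert h.passed == tt["expect_pass"]
                assert set(h.fail_reasons) == set(tt["expect_fail_reasons"])
                n_checked += 1
        assert n_checked == len(ds.mirnas)


class TestReport:
    def test_passed_only_sorted_by_energy(self, tmp_path):
        good = _hit_for(SITE)
        bad = _hit_for(_site_with_mismatches([10]))
        df = report_targets([bad, good], tmp_path / "t.tsv")
        assert len(df) == 1
        assert df.iloc[0]["passed"]

    def test_include_failed_carries_reasons(self, tmp_path):
        bad = _hit_for(_site_with_mismatches([10]))
        df = report_targets([bad], tmp_path / "t.tsv", include_failed=True)
        assert "CLEAVAGE" in df.iloc[0]["fail_reasons"]

    def test_no_hits_header_only(self, tmp_path):
        path = tmp_path / "t.tsv"
        report_targets([], path)
        assert len(path.read_text().splitlines()) == 1
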