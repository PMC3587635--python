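import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssrmir.io_formats import Interval, Transcript, revcomp
from ssrmir.ssr_mining import (
    SSRHit,
    canonical_class,
    find_ssrs,
    summarize_ssrs,
)


def brute_force_ssrs(seq: str, min_iterations: int = 5):
    """Independent reference scanner: test every (start, motif length)
    for perfect tandem identity, keep leftmost-phase maximal primitive
    tracts. Returns a set of (motif, start, iterations)."""

    def primitive(m):
        return all(
            not (len(m) % d == 0 and m == m[: d] * (len(m) // d))
            for d in range(1, len(m))
        )

    out = set()
    n = len(seq)
    for k in range(2, 6):
        for i in range(n - k + 1):
            motif = seq[i : i + k]
            if "N" in motif or not primitive(motif):
                continue
            # leftmost phase: the character-level run must start here
            if i >= 1 and i + k - 1 < n and seq[i - 1] == seq[i + k - 1]:
                continue
            # extend the run character by character, count full iterations
            j = i + k
            while j < n and seq[j] == seq[j - k] and seq[j] != "N":
                j += 1
            iterations = (j - i) // k
            if iterations >= min_iterations:
                out.add((motif, i, iterations))
    return out


class TestFindSSRs:
    def test_ag5_toy(self):
        hits = find_ssrs(Transcript(id="u", seq="agagagagag"))
        assert len(hits) == 1
        h = hits[0]
        assert (h.motif, h.iterations) == ("AG", 5)
        assert (h.interval.start, h.interval.end) == (0, 10)

    def test_four_iterations_below_threshold(self):
        assert find_ssrs(Transcript(id="u", seq="AGAGAGAG")) == []

    def test_primitive_motif_preferred_over_composite(self):
        hits = find_ssrs(Transcript(id="u", seq="ATATATATATAT"))
        assert len(hits) == 1
        assert (hits[0].motif, hits[0].iterations) == ("AT", 6)

    def test_homopolymer_never_reported_as_dimer(self):
        assert find_ssrs(Transcript(id="u", seq="A" * 30)) == []

    def test_partial_trailing_copy_excluded(self):
        hits = find_ssrs(Transcript(id="u", seq="AGAGAGAGAGA"))
        (h,) = hits
        assert h.iterations == 5
        assert h.interval.end == 10  # trailing lone A not part of the tract

    def test_tract_with_n_skipped(self):
        assert find_ssrs(Transcript(id="u", seq="AGAGNGAGAGAG")) == []

    def test_parameter_validation(self):
        t = Transcript(id="u", seq="ACGT" * 10)
        with pytest.raises(ValueError):
            find_ssrs(t, min_motif=0)
        with pytest.raises(ValueError):
            find_ssrs(t, min_motif=4, max_motif=2)

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(60):
            n = int(rng.integers(20, 200))
            # low-cardinality alphabet yields plenty of incidental repeats
            seq = "".join("AT"[i] for i in rng.integers(0, 2, size=n))
            got = {
                (h.motif, h.interval.start, h.iterations)
                for h in find_ssrs(Transcript(id="u", seq=seq))
            }
            assert got == brute_force_ssrs(seq)

    def test_no_duplicate_hits_and_same_motif_never_overlaps(self, rng):
        for _ in range(25):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=150))
            seq += "TA" * 7 + seq[:30]
            hits = find_ssrs(Transcript(id="u", seq=seq))
            keys = [(h.motif, h.interval.start, h.interval.end) for h in hits]
            assert len(keys) == len(set(keys))
            by_motif = {}
            for h in hits:
                by_motif.setdefault(h.motif, []).append(h.interval)
            for ivs in by_motif.values():
                ivs.sort(key=lambda iv: iv.start)
                for a, b in zip(ivs, ivs[1:]):
                    assert a.end <= b.start

    @given(
        motif=st.sampled_from(["AG", "TA", "TCC", "AAG", "ATGT"]),
        iterations=st.integers(5, 12),
    )
    @settings(max_examples=40, deadline=None)
    def test_planted_tract_recovered_exactly(self, motif, iterations):
        # flank with a base absent from the motif so the tract cannot
        # extend in any phase (a homopolymer flank is never reported)
        flank_base = next(b for b in "CGAT" if b not in motif)
        left = flank_base * 15
        tract = motif * iterations
        seq = left + tract + flank_base * 15
        hits = [
            h
            for h in find_ssrs(Transcript(id="u", seq=seq))
            if h.motif == motif
        ]
        assert len(hits) == 1
        h = hits[0]
        assert h.iterations == iterations
        assert (h.interval.start, h.interval.end) == (
            len(left),
            len(left) + len(tract),
        )


class TestCanonicalClass:
    @pytest.mark.parametrize(
        "motif,expected",
        [
            ("GA", "GA/TC"),
            ("TC", "GA/TC"),
            ("TA", "TA"),
            ("CCG", "CCG/CGG"),
            ("AG", "AG/CT"),
            ("CT", "AG/CT"),
        ],
    )
    def test_examples(self, motif, expected):
        assert canonical_class(motif) == expected

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            canonical_class("AX")

    def test_partition_respects_reverse_complement(self):
        import itertools

        for k in (2, 3):
            for motif in ("".join(p) for p in itertools.product("ACGT", repeat=k)):
                assert canonical_class(motif) == canonical_class(revcomp(motif))


class TestSummarize:
    def _hit(self, tid, motif, iters, start):
        return SSRHit(
            transcript_id=tid,
            motif=motif,
            iterations=iters,
            interval=Interval(start, start + len(motif) * iters),
            canonical_class=canonical_class(motif),
        )

    def test_share_arithmetic_matches_reported_style(self):
        # 615 TA hits among 3913 total -> 15.72% at 2 dp
        assert round(100 * 615 / 3913, 2) == 15.72

    def test_counts_and_density(self):
        hits = [
            self._hit("t1", "AG", 5, 0),
            self._hit("t1", "TCC", 5, 40),
            self._hit("t2", "AG", 6, 10),
        ]
        s = summarize_ssrs(hits, total_scanned_nt=2_000_000)
        assert s.total_hits == 3
        assert s.count_by_length_class == {"di": 2, "tri": 1, "tetra": 0, "penta": 0}
        assert s.count_by_canonical_class["AG/CT"] == 2
        assert s.iteration_histogram == {5: 2, 6: 1}
        assert s.n_transcripts_with_ssr == 2
        assert s.n_transcripts_multi_motif == 1
        assert s.density_per_mb == pytest.approx(1.5)

    def test_zero_hits(self):
        s = summarize_ssrs([], total_scanned_nt=1000)
        assert s.total_hits == 0
        assert s.density_per_mb == 0.0
        assert sum(s.count_by_length_class.values()) == 0

    def test_invalid_denominator(self):
        with pytest.raises(ValueError):
            summarize_ssrs([], total_scanned_nt=0)

    def test_planted_dataset_counts_recovered(self, small_dataset):
        truth_ssrs = [
            (r["id"], s["motif"], s["iterations"], s["start"])
            for r in small_dataset.truth["transcripts"]
            for s in r["ssrs"]
        ]
        got = [
            (h.transcript_id, h.motif, h.iterations, h.interval.start)
            for t in small_dataset.transcripts
            for h in find_ssrs(t)
        ]
        assert sorted(got) == sorted(truth_ssrs)
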