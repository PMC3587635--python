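"""miRNA target prediction under plant-style complementarity rules.

A miRNA is aligned gap-free and antisense against every equal-length window
of each transcript (both strands). Mismatches are scored 0 for Watson-Crick
pairs, 0.5 for G:U wobbles and 1.0 otherwise; a hit passes when the total
score is <= 3, the seed (positions 2-6 from the miRNA 5' end) carries at
most one wobble and no other mismatch, positions 10-11 (the cleavage site)
are perfectly Watson-Crick, no more than two consecutive positions are
disrupted (wobbles count toward runs), and the duplex hybridisation energy
is <= -30 kcal/mol on the model scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import Interval, Transcript, dna_to_rna, revcomp
from .rna_fold import can_pair, duplex_energy

FAIL_REASONS = ("TOTAL_MM", "SEED", "CLEAVAGE", "CONSECUTIVE", "MFE")

# per-position classification codes
WC, WOBBLE, MISMATCH = "=", "o", "x"


@dataclass
class TargetConfig:
    max_total_mm: float = 3.0
    seed_range: tuple = (2, 6)  # 1-based, inclusive, from the miRNA 5' end
    seed_policy: str = "one_wobble"  # or "strict" (no seed mispairs at all)
    cleavage_positions: tuple = (10, 11)
    max_consecutive: int = 2
    duplex_mfe_cutoff: float = -30.0


@dataclass
class Alignment:
    """Gap-free antisense alignment of a miRNA to one transcript window."""

    mirna_id: str
    mirna_seq: str  # RNA 5'->3'
    target_id: str
    target_interval: Interval  # plus-strand transcript coordinates
    orientation: str  # strand of the transcript the site lies on
    classes: tuple  # per miRNA position (1..len), WC/WOBBLE/MISMATCH


@dataclass
class TargetHit:
    alignment: Alignment
    total_mismatch_score: float
    seed_mismatch_score: float
    cleavage_ok: bool
    max_consecutive_mismatches: int
    duplex_mfe: float
    passed: bool
    fail_reasons: set = field(default_factory=set)

    @property
    def mirna_id(self) -> str:
        return self.alignment.mirna_id

    @property
    def target_id(self) -> str:
        return self.alignment.target_id


def classify_pair(m: str, t: str) -> str:
    """Classify one miRNA:target position (both RNA, 5'->3' characters)."""
    if (m, t) in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
        return WC
    if (m, t) in (("G", "U"), ("U", "G")):
        return WOBBLE
    return MISMATCH


def scan_targets(
    mirna_seq: str,
    transcript: Transcript,
    mirna_id: str = "mirna",
) -> list[Alignment]:
    """Align the miRNA antisense against every window of the transcript.

    Both the plus strand and its reverse complement are scanned. miRNA
    position k (1-based from the 5' end) faces site position len-k, i.e. the
    miRNA 5' end pairs opposite the site's 3' end.
    """
    q = mirna_seq.upper().replace("T", "U")
    if not (20 <= len(q) <= 22):
        raise ValueError(f"miRNA length {len(q)} outside 20-22 nt")
    m = len(q)
    n = len(transcript)
    out: list[Alignment] = []
    if n < m:
        return out
    for orientation in ("plus", "minus"):
        strand = transcript.seq if orientation == "plus" else revcomp(transcript.seq)
        strand_rna = dna_to_rna(strand)
        for s in range(0, n - m + 1):
            site = strand_rna[s : s + m]
            classes = tuple(
                classify_pair(q[k], site[m - 1 - k]) for k in range(m)
            )
            if orientation == "plus":
                iv = Interval(s, s + m)
            else:
                iv = Interval(n - (s + m), n - s, orientation="minus")
            out.append(
                Alignment(
                    mirna_id=mirna_id,
                    mirna_seq=q,
                    target_id=transcript.id,
                    target_interval=iv,
                    orientation=orientation,
                    classes=classes,
                )
            )
    return out


def _site_seq(aln: Alignment, transcript: Transcript) -> str:
    site = transcript.subseq(
        Interval(aln.target_interval.start, aln.target_interval.end)
    )
    if aln.orientation == "minus":
        site = revcomp(site)
    return dna_to_rna(site)


def score_and_filter(
    aln: Alignment,
    transcript: Transcript,
    cfg: TargetConfig | None = None,
) -> TargetHit:
    """Apply the complementarity filter to one alignment."""
    cfg = cfg or TargetConfig()
    classes = aln.classes
    m = len(classes)
    score = {WC: 0.0, WOBBLE: 0.5, MISMATCH: 1.0}
    total = sum(score[c] for c in classes)
    lo, hi = cfg.seed_range
    seed = classes[lo - 1 : hi]
    seed_score = sum(score[c] for c in seed)
    seed_ok = (
        MISMATCH not in seed
        and seed.count(WOBBLE) <= (0 if cfg.seed_policy == "strict" else 1)
    )
    cleavage_ok = all(
        classes[p - 1] == WC for p in cfg.cleavage_positions if p <= m
    )
    # longest run of disrupted (non-WC) positions; wobbles count toward runs
    max_run = run = 0
    for c in classes:
        run = run + 1 if c != WC else 0
        max_run = max(max_run, run)
    mfe = duplex_energy(aln.mirna_seq, _site_seq(aln, transcript))
    fail: set[str] = set()
    if total > cfg.max_total_mm:
        fail.add("TOTAL_MM")
    if not seed_ok:
        fail.add("SEED")
    if not cleavage_ok:
        fail.add("CLEAVAGE")
    if max_run > cfg.max_consecutive:
        fail.add("CONSECUTIVE")
    if not mfe <= cfg.duplex_mfe_cutoff:
        fail.add("MFE")
    return TargetHit(
        alignment=aln,
        total_mismatch_score=total,
        seed_mismatch_score=seed_score,
        cleavage_ok=cleavage_ok,
        max_consecutive_mismatches=max_run,
        duplex_mfe=mfe,
        passed=not fail,
        fail_reasons=fail,
    )


def predict_targets(
    mirnas: dict[str, str],
    transcripts: list[Transcript],
    cfg: TargetConfig | None = None,
) -> list[TargetHit]:
    """Scan every miRNA against every transcript and score each window."""
    cfg = cfg or TargetConfig()
    hits: list[TargetHit] = []
    by_id = {t.id: t for t in transcripts}
    for mid, mseq in mirnas.items():
        for t in transcripts:
            for aln in scan_targets(mseq, t, mirna_id=mid):
                hits.append(score_and_filter(aln, by_id[t.id], cfg))
    return hits


TARGET_TABLE_COLUMNS = [
    "mirna_id",
    "target_id",
    "target_position",
    "orientation",
    "duplex_mfe_kcal_mol",
    "total_mismatch_score",
    "passed",
    "fail_reasons",
]


def report_targets(
    hits: list[TargetHit], path, include_failed: bool = False
) -> pd.DataFrame:
    """Write a target report TSV sorted by duplex energy (most stable first).

    By default only passing hits are written; with include_failed, failed
    rows carry their reason codes.
    """
    rows = []
    for h in sorted(hits, key=lambda h: (h.duplex_mfe, h.mirna_id, h.target_id)):
        if not h.passed and not include_failed:
            continue
        iv = h.alignment.target_interval
        rows.append(
            {
                "mirna_id": h.mirna_id,
                "target_id": h.target_id,
                "target_position": f"{iv.start_1based}-{iv.end_1based}",
                "orientation": h.alignment.orientation,
                "duplex_mfe_kcal_mol": f"{h.duplex_mfe:.1f}",
                "total_mismatch_score": h.total_mismatch_score,
                "passed": h.passed,
                "fail_reasons": ",".join(sorted(h.fail_reasons)),
            }
        )
    df = pd.DataFrame(rows, columns=TARGET_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df
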