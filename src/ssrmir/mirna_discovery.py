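"""Pre-miRNA candidate discovery over sliding 120-nt windows.

Each transcript is scanned in fixed-length windows on both strands; every
window is folded and screened against five criteria: (1) it folds into a
hairpin with the mature miRNA in one arm, (2) the mature has fewer than six
mismatches with the opposite arm (an unpaired mature position counts 1,
a G:U pair counts 0), (3) the folding energy lies in [-57, -32] kcal/mol on
the model scale, (4) the A+U content of the window lies in [30, 70]%, and
(5) the mature span contains no large loop or break (no single bulge or
interior loop larger than `max_defect` nt and no overlap with the hairpin
loop). Overlapping accepted windows collapse to the lowest-energy one;
multiple surviving candidates on one transcript are suffixed a, b, c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .io_formats import Interval, Transcript, dna_to_rna, revcomp
from .rna_fold import Hairpin, Structure, au_content, extract_hairpins, fold_mfe
from .ssr_mining import SSRHit

log = logging.getLogger("ssrmir")

REJECT_REASONS = (
    "NO_HAIRPIN",
    "MFE_RANGE",
    "AU_RANGE",
    "STAR_MISMATCH",
    "LOOP_BREAK",
    "NO_MATURE",
)


@dataclass
class MirnaConfig:
    """Filter constants for candidate screening (model kcal/mol scale)."""

    window_len: int = 120
    step: int = 20
    mfe_min: float = -57.0
    mfe_max: float = -32.0
    au_min: float = 30.0
    au_max: float = 70.0
    max_star_mismatch: int = 5  # "less than six mismatches"
    mature_lengths: tuple = (20, 21, 22)
    max_defect: int = 3


@dataclass
class PreMiRNACandidate:
    transcript_id: str
    window: Interval  # plus-strand transcript coordinates
    direction: str  # {"plus", "minus"}
    mfe: float
    au_pre: float
    mature: Interval | None = None  # plus-strand transcript coordinates
    mature_seq: str = ""  # RNA, 5'->3' on the candidate strand
    star_mismatches: float = 0.0
    au_mature: float = 0.0
    hairpin: Hairpin | None = None
    structure: Structure | None = None
    reject_reason: str | None = None
    ssr_motifs: list = field(default_factory=list)
    label: str = ""

    @property
    def accepted(self) -> bool:
        return self.reject_reason is None


def scan_windows(
    t: Transcript, window_len: int = 120, step: int = 20
) -> list[tuple[Interval, str]]:
    """Enumerate (window, direction) pairs over a transcript.

    Windows containing N are skipped; minus-direction entries denote the
    same plus-strand interval evaluated on the reverse complement.
    """
    if len(t) < window_len:
        log.info("transcript %s shorter than window (%d nt); skipped", t.id, len(t))
        return []
    out = []
    for start in range(0, len(t) - window_len + 1, step):
        iv = Interval(start, start + window_len)
        if "N" in t.seq[start : start + window_len]:
            log.debug("window %s:%d-%d contains N; skipped", t.id, start, iv.end)
            continue
        out.append((iv, "plus"))
        out.append((iv, "minus"))
    return out


@dataclass
class _MaturePlacement:
    start: int  # window-local
    length: int
    mismatches: int
    hairpin: Hairpin


def _placements(hp: Hairpin, cfg: MirnaConfig):
    """Enumerate candidate mature placements within the arms of a hairpin.

    Yields (placement, defect_ok). A placement is defect-compromised when it
    touches a bulge/interior loop larger than cfg.max_defect.
    """
    pairs = hp.pairs
    for arm in (hp.arm5, hp.arm3):
        for L in cfg.mature_lengths:
            for start in range(arm.start, arm.end - L + 1):
                end = start + L
                ok = True
                for d in hp.defects:
                    if d.size > cfg.max_defect:
                        f0, f1 = d.five
                        t0, t1 = d.three
                        if (start < f1 and f0 < end) or (start < t1 and t0 < end):
                            ok = False
                            break
                mm = sum(1 for p in range(start, end) if pairs[p] < 0)
                yield _MaturePlacement(start, L, mm, hp), ok


def evaluate_window(window_rna: str, cfg: MirnaConfig | None = None) -> PreMiRNACandidate:
    """Screen one window sequence (RNA, window-local coordinates).

    Returns a candidate whose `reject_reason` is None iff all five criteria
    hold; the mature placement reported is the surviving one with fewest
    mismatches (ties to the 5'-most start).
    """
    cfg = cfg or MirnaConfig()
    if len(window_rna) != cfg.window_len:
        raise ValueError(
            f"window length {len(window_rna)} != configured {cfg.window_len}"
        )
    structure = fold_mfe(window_rna)
    wl = cfg.window_len
    cand = PreMiRNACandidate(
        transcript_id="",
        window=Interval(0, wl),
        direction="plus",
        mfe=structure.energy,
        au_pre=au_content(window_rna),
        structure=structure,
    )
    if not (cfg.mfe_min <= structure.energy <= cfg.mfe_max):
        cand.reject_reason = "MFE_RANGE"
        return cand
    if not (cfg.au_min <= cand.au_pre <= cfg.au_max):
        cand.reject_reason = "AU_RANGE"
        return cand
    hairpins = extract_hairpins(structure)
    if not hairpins:
        cand.reject_reason = "NO_HAIRPIN"
        return cand
    best: _MaturePlacement | None = None
    any_geometric = False
    for hp in hairpins:
        for pl, ok in _placements(hp, cfg):
            any_geometric = True
            if not ok:
                continue
            if best is None or (pl.mismatches, pl.start) < (best.mismatches, best.start):
                best = pl
    if not any_geometric:
        cand.reject_reason = "NO_MATURE"
        return cand
    if best is None:
        cand.reject_reason = "LOOP_BREAK"
        return cand
    cand.hairpin = best.hairpin
    cand.mature = Interval(best.start, best.start + best.length)
    cand.mature_seq = window_rna[best.start : best.start + best.length]
    cand.star_mismatches = float(best.mismatches)
    cand.au_mature = au_content(cand.mature_seq)
    if best.mismatches > cfg.max_star_mismatch:
        cand.reject_reason = "STAR_MISMATCH"
    return cand


def _to_transcript_coords(
    cand: PreMiRNACandidate, t: Transcript, window: Interval, direction: str
) -> PreMiRNACandidate:
    """Map a window-local evaluation onto plus-strand transcript coordinates."""
    wl = len(window)
    cand = replace(cand)
    cand.transcript_id = t.id
    cand.label = t.id
    cand.direction = direction
    if cand.mature is not None:
        ms, me = cand.mature.start, cand.mature.end
        if direction == "plus":
            cand.mature = Interval(window.start + ms, window.start + me)
        else:
            cand.mature = Interval(
                window.start + wl - me, window.start + wl - ms, orientation="minus"
            )
    cand.window = Interval(
        window.start, window.end,
        orientation="plus" if direction == "plus" else "minus",
    )
    return cand


def scan_transcript(
    t: Transcript, cfg: MirnaConfig | None = None
) -> list[PreMiRNACandidate]:
    """Evaluate every window of a transcript in both directions."""
    cfg = cfg or MirnaConfig()
    out = []
    for window, direction in scan_windows(t, cfg.window_len, cfg.step):
        seq_dna = t.seq[window.start : window.end]
        if direction == "minus":
            seq_dna = revcomp(seq_dna)
        ev = evaluate_window(dna_to_rna(seq_dna), cfg)
        out.append(_to_transcript_coords(ev, t, window, direction))
    return out


def select_best(cands: list[PreMiRNACandidate]) -> list[PreMiRNACandidate]:
    """Collapse overlapping accepted windows to the lowest-energy one and
    label multiple survivors on a transcript with a/b/c suffixes."""
    accepted = [c for c in cands if c.accepted]
    by_transcript: dict[str, list[PreMiRNACandidate]] = {}
    for c in accepted:
        by_transcript.setdefault(c.transcript_id, []).append(c)
    kept: list[PreMiRNACandidate] = []
    for tid in sorted(by_transcript):
        group = sorted(by_transcript[tid], key=lambda c: (c.window.start, c.window.end))
        clusters: list[list[PreMiRNACandidate]] = []
        cluster_end = -1
        for c in group:
            if clusters and c.window.start < cluster_end:
                clusters[-1].append(c)
                cluster_end = max(cluster_end, c.window.end)
            else:
                clusters.append([c])
                cluster_end = c.window.end
        winners = [
            min(cl, key=lambda c: (c.mfe, c.window.start, c.direction != "plus"))
            for cl in clusters
        ]
        winners.sort(key=lambda c: c.window.start)
        if len(winners) > 1:
            for idx, c in enumerate(winners):
                c.label = f"{tid}{chr(ord('a') + idx)}"
        else:
            for c in winners:
                c.label = tid
        kept.extend(winners)
    return kept


def attach_ssrs(
    cands: list[PreMiRNACandidate],
    ssr_hits: list[SSRHit],
    ssr_bearing: bool = False,
) -> list[PreMiRNACandidate]:
    """Annotate candidates with the SSR motifs found on their transcript.

    In SSR-bearing mode, candidates on SSR-free transcripts are dropped.
    """
    motifs_by_tid: dict[str, list[str]] = {}
    for h in sorted(ssr_hits, key=lambda h: (h.transcript_id, h.interval.start)):
        lst = motifs_by_tid.setdefault(h.transcript_id, [])
        if h.motif not in lst:
            lst.append(h.motif)
    out = []
    for c in cands:
        c.ssr_motifs = list(motifs_by_tid.get(c.transcript_id, []))
        if ssr_bearing and not c.ssr_motifs:
            continue
        out.append(c)
    return out


def discover(
    transcripts: list[Transcript],
    cfg: MirnaConfig | None = None,
    ssr_hits: list[SSRHit] | None = None,
    ssr_bearing: bool = False,
    exclude_ids: set[str] | None = None,
) -> tuple[list[PreMiRNACandidate], dict]:
    """End-to-end discovery with a filter-funnel audit trail.

    `exclude_ids` emulates removing annotated transcripts so only putatively
    non-coding ones are screened. Returns (accepted candidates, funnel).
    """
    cfg = cfg or MirnaConfig()
    funnel = {"transcripts": len(transcripts)}
    pool = transcripts
    if ssr_bearing and ssr_hits is not None:
        with_ssr = {h.transcript_id for h in ssr_hits}
        pool = [t for t in pool if t.id in with_ssr]
        funnel["ssr_bearing"] = len(pool)
    if exclude_ids:
        pool = [t for t in pool if t.id not in exclude_ids]
        funnel["unannotated"] = len(pool)
    evaluated: list[PreMiRNACandidate] = []
    for t in pool:
        evaluated.extend(scan_transcript(t, cfg))
    funnel["windows_evaluated"] = len(evaluated)
    funnel["windows_accepted"] = sum(c.accepted for c in evaluated)
    kept = select_best(evaluated)
    if ssr_hits is not None:
        kept = attach_ssrs(kept, ssr_hits, ssr_bearing=ssr_bearing)
    funnel["candidates"] = len(kept)
    log.info(
        "discovery funnel: %s",
        " -> ".join(f"{k}={v}" for k, v in funnel.items()),
    )
    return kept, funnel
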