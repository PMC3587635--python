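"""Position of SSR tracts relative to pre-miRNA candidate windows.

Each (SSR, candidate) pair on a shared transcript is classified as
upstream, within, or downstream in the candidate's transcriptional
orientation: for a minus-direction candidate the transcript reads 3'->5'
on the plus strand, so plus-strand upstream and downstream swap. "Within"
means any overlap with the candidate window. The downstream bias is
quantified with a two-sided exact binomial test of downstream vs upstream
counts under a null of 0.5 (within-calls excluded from the test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .mirna_discovery import PreMiRNACandidate
from .ssr_mining import SSRHit

log = logging.getLogger("ssrmir")

CLASSES = ("upstream", "within", "downstream")


@dataclass(frozen=True)
class PositionCall:
    transcript_id: str
    ssr: SSRHit
    candidate: PreMiRNACandidate
    klass: str


def classify_position(ssr: SSRHit, cand: PreMiRNACandidate) -> PositionCall:
    """Classify one SSR relative to one candidate window (same transcript)."""
    if ssr.transcript_id != cand.transcript_id:
        raise ValueError(
            f"SSR on {ssr.transcript_id!r} vs candidate on "
            f"{cand.transcript_id!r}"
        )
    w = cand.window
    s = ssr.interval
    if s.end <= w.start:
        plus_side = "upstream"
    elif s.start >= w.end:
        plus_side = "downstream"
    else:
        plus_side = "within"
    if cand.direction == "minus" and plus_side != "within":
        plus_side = "downstream" if plus_side == "upstream" else "upstream"
    return PositionCall(
        transcript_id=ssr.transcript_id, ssr=ssr, candidate=cand, klass=plus_side
    )


def classify_all(
    ssr_hits: list[SSRHit], cands: list[PreMiRNACandidate]
) -> list[PositionCall]:
    """One call per (SSR, candidate) pair sharing a transcript."""
    by_tid: dict[str, list[PreMiRNACandidate]] = {}
    for c in cands:
        by_tid.setdefault(c.transcript_id, []).append(c)
    calls = []
    for h in ssr_hits:
        for c in by_tid.get(h.transcript_id, []):
            calls.append(classify_position(h, c))
    return calls


@dataclass
class BiasSummary:
    n_upstream: int
    n_within: int
    n_downstream: int
    proportions: tuple
    p_value: float

    @property
    def n_total(self) -> int:
        return self.n_upstream + self.n_within + self.n_downstream


def bias_summary(calls: list[PositionCall]) -> BiasSummary:
    """Counts, proportions and exact binomial p-value for downstream bias."""
    if not calls:
        raise ValueError("no position calls")
    n_up = sum(1 for c in calls if c.klass == "upstream")
    n_in = sum(1 for c in calls if c.klass == "within")
    n_down = sum(1 for c in calls if c.klass == "downstream")
    total = len(calls)
    if n_up + n_down == 0:
        log.warning("no upstream/downstream calls; binomial test undefined")
        p = 1.0
    else:
        p = float(
            stats.binomtest(n_down, n_up + n_down, 0.5, alternative="two-sided").pvalue
        )
    return BiasSummary(
        n_upstream=n_up,
        n_within=n_in,
        n_downstream=n_down,
        proportions=(n_up / total, n_in / total, n_down / total),
        p_value=p,
    )


def write_position_calls(calls: list[PositionCall], path) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": c.transcript_id,
            "ssr_motif": c.ssr.motif,
            "ssr_position": f"{c.ssr.interval.start_1based}-{c.ssr.interval.end_1based}",
            "candidate": c.candidate.label or c.candidate.transcript_id,
            "candidate_window": (
                f"{c.candidate.window.start_1based}-{c.candidate.window.end_1based}"
            ),
            "direction": c.candidate.direction,
            "klass": c.klass,
        }
        for c in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "ssr_motif", "ssr_position", "candidate",
            "candidate_window", "direction", "klass",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
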