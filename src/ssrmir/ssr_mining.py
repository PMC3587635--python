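"""Detection and summarisation of simple sequence repeats (microsatellites).

Only perfect (uninterrupted) tandem repeats of primitive 2-5 nt motifs with
at least five full iterations are reported, the convention used by classic
EST-SSR mining tools. Mononucleotide runs are excluded: a dimer whose two
bases are equal is non-primitive and is never reported, so homopolymers
cannot masquerade as dimers. When a tract satisfies several motif lengths
(ATATAT... as AT or ATAT) only the shortest-period description is kept.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_formats import Interval, Transcript, revcomp

LENGTH_CLASS = {2: "di", 3: "tri", 4: "tetra", 5: "penta"}


def _is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number repetition of a shorter one."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def canonical_class(motif: str) -> str:
    """Reverse-complement family label for a motif.

    A motif and its reverse complement belong to the same class (GA and TC
    are both "GA/TC"); rotational phases are NOT merged. Self-reverse-
    complement motifs (TA) are their own single-name class.
    """
    motif = motif.upper()
    if not motif or set(motif) - set("ACGT"):
        raise ValueError(f"invalid motif {motif!r}")
    rc = revcomp(motif)
    if rc == motif:
        return motif
    a, b = sorted((motif, rc))
    return f"{a}/{b}"


@dataclass(frozen=True)
class SSRHit:
    """One maximal perfect tandem repeat tract on a transcript."""

    transcript_id: str
    motif: str
    iterations: int
    interval: Interval
    canonical_class: str = ""

    def __post_init__(self) -> None:
        if len(self.interval) != len(self.motif) * self.iterations:
            raise ValueError("interval length != motif length x iterations")


def find_ssrs(
    t: Transcript,
    min_motif: int = 2,
    max_motif: int = 5,
    min_iterations: int = 5,
) -> list[SSRHit]:
    """Find every maximal perfect tandem tract of a primitive motif.

    Tracts are maximal character-wise; partial trailing motif copies are not
    counted as iterations and are excluded from the reported interval. Any
    tract containing N is skipped. Two hits with different motifs may
    overlap; hits with the same motif never do.
    """
    if min_motif < 1 or max_motif < min_motif:
        raise ValueError(
            f"invalid motif length bounds [{min_motif}, {max_motif}]"
        )
    seq = t.seq
    n = len(seq)
    hits: list[SSRHit] = []
    for k in range(max(min_motif, 2), max_motif + 1):
        j = k
        while j < n:
            if seq[j] != seq[j - k] or seq[j] == "N":
                j += 1
                continue
            # maximal run of period-k matches starting at j
            run_start = j
            while j < n and seq[j] == seq[j - k] and seq[j] != "N":
                j += 1
            tract_start = run_start - k
            tract_len = (j - run_start) + k
            iterations = tract_len // k
            motif = seq[tract_start : tract_start + k]
            if (
                iterations >= min_iterations
                and "N" not in motif
                and _is_primitive(motif)
            ):
                iv = Interval(tract_start, tract_start + iterations * k)
                hits.append(
                    SSRHit(
                        transcript_id=t.id,
                        motif=motif,
                        iterations=iterations,
                        interval=iv,
                        canonical_class=canonical_class(motif),
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, len(h.motif)))
    return hits


def find_ssrs_all(
    transcripts: list[Transcript], **kwargs
) -> list[SSRHit]:
    out: list[SSRHit] = []
    for t in transcripts:
        out.extend(find_ssrs(t, **kwargs))
    return out


@dataclass
class SSRSummary:
    count_by_length_class: dict = field(default_factory=dict)
    count_by_canonical_class: dict = field(default_factory=dict)
    iteration_histogram: dict = field(default_factory=dict)
    n_transcripts_with_ssr: int = 0
    n_transcripts_multi_motif: int = 0
    total_hits: int = 0
    density_per_mb: float = 0.0


def summarize_ssrs(hits: list[SSRHit], total_scanned_nt: int) -> SSRSummary:
    """Summary statistics for one scan: class counts, iteration histogram,
    per-transcript motif diversity and density (SSRs per Mb scanned)."""
    if total_scanned_nt <= 0:
        raise ValueError("total_scanned_nt must be positive")
    by_len = Counter(LENGTH_CLASS[len(h.motif)] for h in hits)
    by_class = Counter(h.canonical_class for h in hits)
    iters = Counter(h.iterations for h in hits)
    motifs_per_transcript: dict[str, set[str]] = {}
    for h in hits:
        motifs_per_transcript.setdefault(h.transcript_id, set()).add(h.motif)
    n_multi = sum(1 for ms in motifs_per_transcript.values() if len(ms) > 1)
    return SSRSummary(
        count_by_length_class={
            c: by_len.get(c, 0) for c in ("di", "tri", "tetra", "penta")
        },
        count_by_canonical_class=dict(by_class),
        iteration_histogram=dict(sorted(iters.items())),
        n_transcripts_with_ssr=len(motifs_per_transcript),
        n_transcripts_multi_motif=n_multi,
        total_hits=len(hits),
        density_per_mb=len(hits) / (total_scanned_nt / 1e6),
    )
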