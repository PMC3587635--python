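"""Input/output layer: FASTA ingest, TSV reports, GFF3 annotations.

Internal coordinates are 0-based half-open on the plus strand of the input
transcript. Every human-facing report converts to 1-based inclusive
("184-303" style). DNA is the storage alphabet; RNA (U) appears only in
mature-miRNA sequence output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger("ssrmir")

IUPAC_DNA = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on the plus strand of a transcript."""

    start: int
    end: int
    orientation: str = "plus"  # {"plus", "minus"}

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.orientation not in ("plus", "minus"):
            raise ValueError(f"invalid orientation {self.orientation!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        """1-based inclusive end (equals the 0-based exclusive end)."""
        return self.end


@dataclass
class Transcript:
    """One unigene: identifier plus nucleotide sequence (uppercase DNA)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        bad = set(self.seq) - IUPAC_DNA
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"transcript {self.id!r}: non-IUPAC character "
                f"{self.seq[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def rna(self) -> str:
        return dna_to_rna(self.seq)

    def subseq(self, iv: Interval) -> str:
        if iv.end > len(self.seq):
            raise ValueError(
                f"interval [{iv.start},{iv.end}) outside transcript "
                f"{self.id!r} of length {len(self.seq)}"
            )
        return self.seq[iv.start : iv.end]


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a unigene-style multi-FASTA into Transcript records.

    U is converted to T and lowercase to uppercase on ingest; the id is the
    token before the first whitespace, the remainder is kept as metadata.
    Duplicate ids and non-IUPAC characters are errors; an empty file yields
    an empty collection with a warning.
    """
    path = Path(path)
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip()
        transcripts.append(Transcript(id=rec.id, seq=str(rec.seq), description=desc))
    if not transcripts:
        log.warning("no FASTA records found in %s", path)
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            header = f">{t.id}" + (f" {t.description}" if t.description else "")
            fh.write(header + "\n")
            for i in range(0, len(t.seq), 70):
                fh.write(t.seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Tabular reports
# ---------------------------------------------------------------------------

SSR_TABLE_COLUMNS = [
    "transcript_id",
    "motif",
    "canonical_class",
    "iterations",
    "start_1based",
    "end_1based_inclusive",
    "tract_length",
]


def write_ssr_table(hits: Sequence, path: str | Path) -> pd.DataFrame:
    """Write detected SSR tracts as TSV, sorted by (transcript_id, start)."""
    rows = [
        {
            "transcript_id": h.transcript_id,
            "motif": h.motif,
            "canonical_class": h.canonical_class,
            "iterations": h.iterations,
            "start_1based": h.interval.start_1based,
            "end_1based_inclusive": h.interval.end_1based,
            "tract_length": len(h.interval),
        }
        for h in hits
    ]
    df = pd.DataFrame(rows, columns=SSR_TABLE_COLUMNS)
    df = df.sort_values(["transcript_id", "start_1based"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)
    return df


CANDIDATE_TABLE_COLUMNS = [
    "unigene_id",
    "ssr_motif",
    "pre_mirna_position",
    "delta_g",
    "direction",
    "mature_position",
    "mature_sequence",
    "au_content",
    "au_content_premirna",
    "transcript_id",
]


def _fmt_pos(iv: Interval) -> str:
    return f"{iv.start_1based}-{iv.end_1based}"


def write_candidate_table(cands: Sequence, path: str | Path) -> pd.DataFrame:
    """Write accepted pre-miRNA candidates in the standard report layout.

    The free-energy column is printed as a magnitude (unsigned); A+U content
    to 2 decimals; positions 1-based inclusive.
    """
    rows = []
    for c in cands:
        rows.append(
            {
                "unigene_id": c.label,
                "ssr_motif": ",".join(c.ssr_motifs),
                "pre_mirna_position": _fmt_pos(c.window),
                "delta_g": f"{round(abs(c.mfe), 2):g}",
                "direction": "Plus" if c.direction == "plus" else "Minus",
                "mature_position": _fmt_pos(c.mature),
                "mature_sequence": c.mature_seq,
                "au_content": f"{c.au_mature:.2f}",
                "au_content_premirna": f"{c.au_pre:.2f}",
                "transcript_id": c.transcript_id,
            }
        )
    df = pd.DataFrame(rows, columns=CANDIDATE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


@dataclass
class GffFeature:
    seqid: str
    ftype: str  # "SSR" | "pre_miRNA" | "miRNA"
    interval: Interval
    attributes: dict = field(default_factory=dict)
    score: str = "."
    seq_length: int | None = None  # transcript length for bounds checking


def _gff_escape(v) -> str:
    s = str(v)
    for c, r in ((";", "%3B"), ("=", "%3D"), (",", "%2C")):
        s = s.replace(c, r)
    return s


def write_gff3(features: Sequence[GffFeature], path: str | Path) -> None:
    """Write features as GFF3 (1-based inclusive; strand from orientation)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            if f.seq_length is not None and f.interval.end > f.seq_length:
                raise ValueError(
                    f"feature on {f.seqid} at [{f.interval.start},"
                    f"{f.interval.end}) exceeds length {f.seq_length}"
                )
            strand = "+" if f.interval.orientation == "plus" else "-"
            attrs = ";".join(
                f"{k}={_gff_escape(v)}" for k, v in f.attributes.items()
            )
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        "ssrmir",
                        f.ftype,
                        str(f.interval.start_1based),
                        str(f.interval.end_1based),
                        f.score,
                        strand,
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def _parse_pos(s: str) -> tuple[int, int]:
    """Parse a 1-based inclusive "start-end" report position to 0-based."""
    a, b = s.split("-")
    return int(a) - 1, int(b)


def read_ssr_table(path: str | Path) -> list:
    """Read back an SSR report TSV into SSRHit records."""
    from .ssr_mining import SSRHit

    df = pd.read_csv(path, sep="\t")
    hits = []
    for row in df.itertuples(index=False):
        start = int(row.start_1based) - 1
        end = int(row.end_1based_inclusive)
        hits.append(
            SSRHit(
                transcript_id=str(row.transcript_id),
                motif=row.motif,
                iterations=int(row.iterations),
                interval=Interval(start, end),
                canonical_class=row.canonical_class,
            )
        )
    return hits


def read_candidate_table(path: str | Path) -> list:
    """Read back a candidate report TSV into PreMiRNACandidate records
    (positions and direction only; structures are not round-tripped)."""
    from .mirna_discovery import PreMiRNACandidate

    df = pd.read_csv(path, sep="\t")
    cands = []
    for row in df.itertuples(index=False):
        ws, we = _parse_pos(str(row.pre_mirna_position))
        ms, me = _parse_pos(str(row.mature_position))
        direction = str(row.direction).lower()
        cands.append(
            PreMiRNACandidate(
                transcript_id=str(row.transcript_id),
                label=str(row.unigene_id),
                window=Interval(ws, we, orientation=direction),
                direction=direction,
                mfe=-float(row.delta_g),
                au_pre=float(row.au_content_premirna),
                au_mature=float(row.au_content),
                mature=Interval(ms, me),
                mature_seq=str(row.mature_sequence),
                ssr_motifs=(
                    str(row.ssr_motif).split(",") if str(row.ssr_motif) != "nan" else []
                ),
            )
        )
    return cands
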