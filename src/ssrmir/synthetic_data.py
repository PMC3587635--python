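"""Seeded synthetic transcriptomes with planted ground truth.

Generates unigene-like transcripts (length mixture mimicking a de novo
leaf-transcriptome assembly: mostly 100-500 nt with a long tail to 2 kb)
carrying planted features with exact recorded coordinates:

* SSR tracts (primitive 2-5 nt motifs, 5-16 iterations drawn from the
  iteration distribution observed in transcriptome SSR surveys), placed
  upstream / within / downstream of a hairpin at a configurable
  downstream fraction, and separated from other features by >= 10 nt;
* pre-miRNA hairpin windows: perfect inverted repeats degraded by a
  controlled number of arm mismatches, padded to the 120-nt scan window
  and calibrated by adaptive rejection sampling so that the pipeline's own
  filter constants classify them as compliant (with safety margins) or as
  decoys violating exactly one named criterion by a safe margin;
* antisense miRNA target sites with engineered mismatch patterns
  (compliant, cleavage-site, seed, consecutive-run, total-count
  violations), verified against the target filter at build time;
* per-transcript read counts (multinomial with lognormal expression
  heterogeneity) for RPKM exercises.

Everything is driven by a single integer-seeded numpy Generator, so a
given config yields byte-identical FASTA/TSV/JSON outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import Transcript, dna_to_rna, revcomp, write_fasta
from .mirna_discovery import MirnaConfig, evaluate_window
from .ssr_mining import _is_primitive, find_ssrs
from .target_prediction import TargetConfig, scan_targets, score_and_filter

DNA = "ACGT"

#: iteration counts and their frequencies in transcriptome SSR surveys
ITERATION_WEIGHTS = {
    5: 61.26, 6: 21.67, 7: 9.12, 8: 3.09, 9: 2.17,
    10: 1.46, 11: 1.02, 12: 0.20, 13: 0.03, 16: 0.03,
}

#: motif-length frequencies (di/tri/tetra/penta) typical of plant ESTs
MOTIF_LENGTH_WEIGHTS = {2: 44.7, 3: 53.5, 4: 1.5, 5: 0.3}

#: unigene length mixture: (lo, hi, weight)
LENGTH_MIXTURE = [
    (100, 500, 70.16), (500, 1000, 22.69), (1000, 1500, 5.48),
    (1500, 2000, 1.3), (2000, 2200, 0.38),
]

DECOY_KINDS = ("au_low", "au_high", "weak_stem", "many_mismatches")


@dataclass
class HairpinSpec:
    stem_len_range: tuple = (22, 32)
    loop_range: tuple = (6, 10)
    arm_mismatch_range: tuple = (0, 2)
    align_step: int = 20  # planted windows start on this grid
    direction_minus_fraction: float = 0.5
    mfe_margin: float = 4.0  # keep planted energies this far inside the band
    au_margin: float = 5.0
    verify: bool = True  # calibrate via the pipeline's own evaluator
    max_tries: int = 800


@dataclass
class SSRSpec:
    motif_length_weights: dict = field(
        default_factory=lambda: dict(MOTIF_LENGTH_WEIGHTS)
    )
    iteration_weights: dict = field(default_factory=lambda: dict(ITERATION_WEIGHTS))
    downstream_fraction: float = 0.7
    within_fraction: float = 0.0
    min_separation: int = 10
    hairpin_rate: float = 1.0  # SSR planted per hairpin transcript
    background_rate: float = 0.5  # SSR planted per background transcript


@dataclass
class TargetSpec:
    n_sites: int = 10
    patterns: tuple = ("compliant", "cleavage", "seed", "consecutive", "total_mm")
    mirna_len: int = 21
    mirna_gc: float = 0.6
    max_tries: int = 500


@dataclass
class CountSpec:
    N_total: int = 1_000_000
    dispersion: float = 0.5  # sd of log-expression heterogeneity


@dataclass
class SynthConfig:
    n_transcripts: int = 30
    length_range: tuple = (100, 2000)
    gc_background: float = 0.5
    n_compliant: int = 10  # transcripts carrying a compliant hairpin
    n_decoys: int = 8  # transcripts carrying a decoy window (kinds cycled)
    hairpin_spec: HairpinSpec = field(default_factory=HairpinSpec)
    ssr_spec: SSRSpec = field(default_factory=SSRSpec)
    target_spec: TargetSpec | None = None
    count_spec: CountSpec = field(default_factory=CountSpec)
    mirna_cfg: MirnaConfig = field(default_factory=MirnaConfig)
    target_cfg: TargetConfig = field(default_factory=TargetConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compliant + self.n_decoys > self.n_transcripts:
            raise ValueError("more planted transcripts than n_transcripts")


# ---------------------------------------------------------------------------
# low-level sequence builders
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(DNA[i] for i in rng.choice(4, size=n, p=p))


def _draw_length(rng: np.random.Generator, lo: int, hi: int) -> int:
    bins = [(max(a, lo), min(b, hi), w) for a, b, w in LENGTH_MIXTURE if a < hi and b > lo]
    if not bins:
        return int(rng.integers(lo, hi + 1))
    w = np.array([b[2] for b in bins])
    a, b, _ = bins[rng.choice(len(bins), p=w / w.sum())]
    return int(rng.integers(a, b))


def _weighted_choice(rng: np.random.Generator, weights: dict):
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _random_motif(rng: np.random.Generator, spec: SSRSpec) -> str:
    while True:
        k = _weighted_choice(rng, spec.motif_length_weights)
        motif = "".join(DNA[i] for i in rng.integers(0, 4, size=k))
        if _is_primitive(motif):
            return motif


def _non_pairing_base(rng: np.random.Generator, partner: str) -> str:
    """A DNA base whose RNA form neither WC- nor wobble-pairs with partner."""
    forbidden = {"A": "T", "T": "AG", "G": "CT", "C": "G"}[partner]
    choices = [b for b in DNA if b not in forbidden]
    return choices[int(rng.integers(len(choices)))]


def _scrub_tandem_repeats(
    seq: list, rng: np.random.Generator, protect: list, min_iterations: int = 4
) -> None:
    """Mutate background so no incidental SSR-like tract survives.

    Any perfect tandem tract with >= min_iterations full iterations that is
    not protected gets one mid-tract base replaced; repeats until clean.
    """

    def covered(a: int, b: int) -> bool:
        return any(a < pe and ps < b for ps, pe in protect)

    for _ in range(50):
        t = Transcript(id="tmp", seq="".join(seq))
        dirty = [
            h
            for h in find_ssrs(t, min_iterations=min_iterations)
            if not covered(h.interval.start, h.interval.end)
        ]
        if not dirty:
            return
        for h in dirty:
            mid = (h.interval.start + h.interval.end) // 2
            while covered(mid, mid + 1):
                mid += 1
            old = seq[mid]
            choices = [b for b in DNA if b != old]
            seq[mid] = choices[int(rng.integers(3))]
    raise RuntimeError("failed to scrub incidental tandem repeats")


# ---------------------------------------------------------------------------
# hairpin window builders
# ---------------------------------------------------------------------------


def _assemble_window(
    rng: np.random.Generator,
    stem_len: int,
    loop_len: int,
    n_mismatch: int,
    window_len: int,
    arm_gc: float = 0.5,
    pad_gc: float = 0.5,
) -> str:
    arm5 = _random_seq(rng, stem_len, gc=arm_gc)
    arm3 = list(revcomp(arm5))
    if n_mismatch > 0:
        positions = rng.choice(stem_len, size=min(n_mismatch, stem_len), replace=False)
        for p in sorted(int(x) for x in positions):
            partner = arm5[stem_len - 1 - p]
            arm3[p] = _non_pairing_base(rng, partner)
    core = arm5 + _random_seq(rng, loop_len, gc=pad_gc) + "".join(arm3)
    pad_total = window_len - len(core)
    if pad_total < 0:
        raise ValueError("stem+loop exceed window length")
    left = int(rng.integers(0, pad_total + 1))
    return (
        _random_seq(rng, left, gc=pad_gc)
        + core
        + _random_seq(rng, pad_total - left, gc=pad_gc)
    )


def _window_has_repeats(window: str) -> bool:
    return bool(find_ssrs(Transcript(id="w", seq=window), min_iterations=4))


def make_compliant_hairpin(
    rng: np.random.Generator,
    cfg: MirnaConfig | None = None,
    spec: HairpinSpec | None = None,
) -> tuple[str, dict]:
    """A 120-nt DNA window the candidate filter accepts with safety margins.

    Stem length adapts up/down until the model energy sits `mfe_margin`
    inside [mfe_min, mfe_max]; AU content must sit `au_margin` inside its
    band and the best mature placement must have at least two mismatches of
    slack under the star-mismatch cap.
    """
    cfg = cfg or MirnaConfig()
    spec = spec or HairpinSpec()
    stem = int(rng.integers(spec.stem_len_range[0], spec.stem_len_range[1] + 1))
    n_mm = int(rng.integers(spec.arm_mismatch_range[0], spec.arm_mismatch_range[1] + 1))
    for _ in range(spec.max_tries):
        loop = int(rng.integers(spec.loop_range[0], spec.loop_range[1] + 1))
        window = _assemble_window(rng, stem, loop, n_mm, cfg.window_len)
        ev = evaluate_window(dna_to_rna(window), cfg)
        if ev.mfe < cfg.mfe_min + spec.mfe_margin:
            stem = max(8, stem - 2)
            continue
        if ev.mfe > cfg.mfe_max - spec.mfe_margin:
            stem = min((cfg.window_len - min(spec.loop_range)) // 2, stem + 2)
            continue
        if (
            ev.reject_reason is None
            and cfg.au_min + spec.au_margin <= ev.au_pre <= cfg.au_max - spec.au_margin
            and ev.star_mismatches <= cfg.max_star_mismatch - 2
            and not _window_has_repeats(window)
        ):
            return window, {
                "kind": "compliant",
                "mfe": ev.mfe,
                "au_pre": ev.au_pre,
                "star_mismatches": ev.star_mismatches,
                "stem_len": stem,
                "arm_mismatches": n_mm,
            }
    raise RuntimeError("could not build a compliant hairpin window")


def make_decoy_hairpin(
    kind: str,
    rng: np.random.Generator,
    cfg: MirnaConfig | None = None,
    spec: HairpinSpec | None = None,
) -> tuple[str, dict]:
    """A 120-nt DNA window violating exactly one selection criterion.

    au_low / au_high: a stable hairpin inside the energy band whose window
    AU content is <= 20% / >= 80% (rejected AU_RANGE). weak_stem: an
    unstructured window with model energy above -25 kcal/mol (rejected
    MFE_RANGE). many_mismatches: a long stem degraded every third position
    so every possible mature placement carries >= 8 arm mismatches
    (rejected STAR_MISMATCH). Both scan orientations are verified rejected.
    """
    cfg = cfg or MirnaConfig()
    spec = spec or HairpinSpec()
    if kind not in DECOY_KINDS:
        raise ValueError(f"unknown decoy kind {kind!r}")

    def both_rejected(window: str):
        ev = evaluate_window(dna_to_rna(window), cfg)
        ev_rc = evaluate_window(dna_to_rna(revcomp(window)), cfg)
        return ev, (ev.reject_reason is not None and ev_rc.reject_reason is not None)

    if kind == "weak_stem":
        for _ in range(spec.max_tries):
            window = _random_seq(rng, cfg.window_len, gc=0.45)
            ev, rej = both_rejected(window)
            if rej and ev.mfe > -25.0 and ev.reject_reason == "MFE_RANGE":
                if not _window_has_repeats(window):
                    return window, {"kind": "decoy:weak_stem", "mfe": ev.mfe}
        raise RuntimeError("could not build weak_stem decoy")

    if kind == "au_low":
        # GC-rich sequence folds stably on its own; sample until the window
        # sits inside the energy band with AU <= 20%
        for _ in range(spec.max_tries):
            gc = 0.80 + 0.10 * rng.random()
            window = _random_seq(rng, cfg.window_len, gc=gc)
            ev, rej = both_rejected(window)
            if (
                rej
                and ev.reject_reason == "AU_RANGE"
                and ev.au_pre <= 20.0
                and cfg.mfe_min + spec.mfe_margin <= ev.mfe <= cfg.mfe_max - spec.mfe_margin
                and not _window_has_repeats(window)
            ):
                return window, {"kind": "decoy:au_low", "mfe": ev.mfe, "au_pre": ev.au_pre}
        raise RuntimeError("could not build au_low decoy")

    if kind == "au_high":
        # AU-only arms stack weakly, so a long explicit stem is needed
        stem = 40
        for _ in range(spec.max_tries):
            loop = int(rng.integers(spec.loop_range[0], spec.loop_range[1] + 1))
            try:
                window = _assemble_window(
                    rng, stem, loop, 0, cfg.window_len, arm_gc=0.08, pad_gc=0.08
                )
            except ValueError:
                stem -= 2
                continue
            ev, rej = both_rejected(window)
            if ev.mfe < cfg.mfe_min + spec.mfe_margin:
                stem = max(8, stem - 2)
                continue
            if ev.mfe > cfg.mfe_max - spec.mfe_margin:
                stem = min(52, stem + 2)
                continue
            if (
                rej
                and ev.reject_reason == "AU_RANGE"
                and ev.au_pre >= 80.0
                and not _window_has_repeats(window)
            ):
                return window, {"kind": "decoy:au_high", "mfe": ev.mfe, "au_pre": ev.au_pre}
        raise RuntimeError("could not build au_high decoy")

    # many_mismatches: long stem broken at 3 positions per 10 stem steps
    # (period-10 pattern: every 20-nt mature placement then contains >= 6
    # unpaired positions). A window that keeps its energy inside the band
    # while carrying that many arm mismatches is rare -- the refolded MFE
    # structure often absorbs or merges the designed defects -- so the
    # builder samples randomised stem/composition combinations and keeps
    # only windows the evaluator itself rejects with STAR_MISMATCH.
    for _ in range(spec.max_tries * 3):
        stem = int(rng.integers(42, 55))
        arm_gc = 0.60 + 0.15 * rng.random()
        pad_gc = 0.25 + 0.15 * rng.random()
        loop = int(rng.integers(spec.loop_range[0], spec.loop_range[1] + 1))
        arm5 = _random_seq(rng, stem, gc=arm_gc)
        arm3 = list(revcomp(arm5))
        for p in range(stem):
            if p % 10 in (2, 5, 8):
                arm3[p] = _non_pairing_base(rng, arm5[stem - 1 - p])
        core = arm5 + _random_seq(rng, loop, gc=pad_gc) + "".join(arm3)
        pad = cfg.window_len - len(core)
        if pad < 0:
            continue
        left = int(rng.integers(0, pad + 1))
        window = (
            _random_seq(rng, left, gc=pad_gc)
            + core
            + _random_seq(rng, pad - left, gc=pad_gc)
        )
        ev, rej = both_rejected(window)
        if (
            rej
            and ev.reject_reason == "STAR_MISMATCH"
            and ev.star_mismatches >= 6
            and not _window_has_repeats(window)
        ):
            return window, {
                "kind": "decoy:many_mismatches",
                "mfe": ev.mfe,
                "star_mismatches": ev.star_mismatches,
            }
    raise RuntimeError("could not build many_mismatches decoy")


# ---------------------------------------------------------------------------
# target site builder
# ---------------------------------------------------------------------------

#: 1-based miRNA positions mutated per pattern
TARGET_PATTERNS = {
    "compliant": (14, 18),
    "cleavage": (10,),
    "seed": (4,),
    "consecutive": (13, 14, 15),
    "total_mm": (8, 13, 16, 19),
}

EXPECTED_FAIL = {
    "compliant": frozenset(),
    "cleavage": frozenset({"CLEAVAGE"}),
    "seed": frozenset({"SEED"}),
    "consecutive": frozenset({"CONSECUTIVE"}),
    "total_mm": frozenset({"TOTAL_MM"}),
}


def make_target_site(
    rng: np.random.Generator,
    pattern: str,
    spec: TargetSpec | None = None,
    cfg: TargetConfig | None = None,
) -> tuple[str, str, dict]:
    """Build (miRNA RNA seq, site DNA seq, truth) for one mismatch pattern.

    The site is the plus-strand DNA a transcript must contain for the miRNA
    to bind antisense with mismatches exactly at the pattern's positions.
    Construction is verified against the target filter: the realised fail
    reasons must equal the pattern's expected set (empty for compliant).
    """
    spec = spec or TargetSpec()
    cfg = cfg or TargetConfig()
    if pattern not in TARGET_PATTERNS:
        raise ValueError(f"unknown target pattern {pattern!r}")
    positions = TARGET_PATTERNS[pattern]
    m = spec.mirna_len
    expected = set(EXPECTED_FAIL[pattern])
    for _ in range(spec.max_tries):
        q_dna = _random_seq(rng, m, gc=spec.mirna_gc)
        q = dna_to_rna(q_dna)
        site = list(revcomp(q_dna))  # perfect antisense site, plus strand
        for k in positions:  # miRNA position k faces site index m-k
            site[m - k] = _non_pairing_base(rng, q_dna[k - 1])
        site_dna = "".join(site)
        tmp = Transcript(id="site", seq=site_dna)
        aln = scan_targets(q, tmp, mirna_id="m")[0]
        hit = score_and_filter(aln, tmp, cfg)
        realised = set(hit.fail_reasons)
        if pattern == "compliant":
            ok = hit.passed and hit.duplex_mfe <= cfg.duplex_mfe_cutoff - 3.0
        else:
            ok = (not hit.passed) and realised == expected
        if ok:
            return q, site_dna, {
                "pattern": pattern,
                "expect_pass": pattern == "compliant",
                "expect_fail_reasons": sorted(expected),
                "duplex_mfe": hit.duplex_mfe,
                "total_mismatch_score": hit.total_mismatch_score,
            }
    raise RuntimeError(f"could not build target site for pattern {pattern!r}")


# ---------------------------------------------------------------------------
# transcript assembly and the top-level generator
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    transcripts: list
    counts: pd.DataFrame
    truth: dict
    mirnas: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.transcripts, outdir / "transcripts.fasta")
        self.counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        if self.mirnas:
            with open(outdir / "mirnas.fasta", "w") as fh:
                for mid, seq in self.mirnas.items():
                    fh.write(f">{mid}\n{seq}\n")


def _plant_ssr_tract(
    seq: list, tract: str, start: int, motif: str
) -> None:
    """Insert a tract and break both boundaries so it cannot extend."""
    k = len(motif)
    end = start + len(tract)
    seq[start:end] = list(tract)
    if start > 0 and seq[start - 1] == motif[-1]:
        seq[start - 1] = "C" if motif[-1] != "C" else "A"
    if end < len(seq) and seq[end] == motif[0]:
        seq[end] = "C" if motif[0] != "C" else "A"


def _build_hairpin_transcript(
    rng: np.random.Generator,
    tid: str,
    window: str,
    info: dict,
    config: SynthConfig,
) -> tuple[Transcript, dict]:
    cfg = config.mirna_cfg
    sspec = config.ssr_spec
    hspec = config.hairpin_spec
    wl = cfg.window_len
    lo, hi = config.length_range
    length = max(_draw_length(rng, lo, hi), wl + 2 * 130)
    direction = (
        "minus" if rng.random() < hspec.direction_minus_fraction else "plus"
    )
    step = hspec.align_step
    off_lo = (100 + step - 1) // step
    off_hi = (length - wl - 100) // step
    offset = int(rng.integers(off_lo, off_hi + 1)) * step
    planted_window = window if direction == "plus" else revcomp(window)

    seq = list(_random_seq(rng, length, gc=config.gc_background))
    protect = [(offset, offset + wl)]
    seq[offset : offset + wl] = list(planted_window)

    record = {
        "id": tid,
        "kind": info["kind"],
        "hairpins": [
            {
                "window_start": offset,
                "window_end": offset + wl,
                "direction": direction,
                "kind": info["kind"],
                "compliant": info["kind"] == "compliant",
                **{k: v for k, v in info.items() if k != "kind"},
            }
        ],
        "ssrs": [],
        "targets": [],
    }

    if rng.random() < sspec.hairpin_rate:
        motif = _random_motif(rng, sspec)
        iterations = _weighted_choice(rng, sspec.iteration_weights)
        tract = motif * iterations
        r = rng.random()
        if r < sspec.within_fraction:
            placement = "within"
        elif r < sspec.within_fraction + sspec.downstream_fraction:
            placement = "downstream"
        else:
            placement = "upstream"
        # map candidate-orientation placement onto the plus strand
        if placement == "within":
            side = "within"
        elif (placement == "downstream") == (direction == "plus"):
            side = "after"
        else:
            side = "before"
        gap = int(rng.integers(sspec.min_separation, 61))
        if side == "before":
            start = offset - gap - len(tract)
            if start < 0:
                raise ValueError(f"infeasible packing on transcript {tid}")
        elif side == "after":
            start = offset + wl + gap
            if start + len(tract) >= length:
                raise ValueError(f"infeasible packing on transcript {tid}")
        else:  # overlap the window edge by a couple of bases
            start = offset + wl - 2
            if start + len(tract) >= length:
                raise ValueError(f"infeasible packing on transcript {tid}")
        _plant_ssr_tract(seq, tract, start, motif)
        protect.append((start, start + len(tract)))
        record["ssrs"].append(
            {
                "motif": motif,
                "iterations": int(iterations),
                "start": start,
                "end": start + len(tract),
                "placement": placement,
            }
        )
        if side == "within" and record["hairpins"][0]["compliant"]:
            # the tract clipped the window pad; re-verify the compliance flag
            wseq = "".join(seq[offset : offset + wl])
            ws = wseq if direction == "plus" else revcomp(wseq)
            ev = evaluate_window(dna_to_rna(ws), cfg)
            record["hairpins"][0]["compliant"] = ev.reject_reason is None
    _scrub_tandem_repeats(seq, rng, protect)
    return Transcript(id=tid, seq="".join(seq)), record


def _build_background_transcript(
    rng: np.random.Generator, tid: str, config: SynthConfig, with_ssr: bool
) -> tuple[Transcript, dict]:
    lo, hi = config.length_range
    length = _draw_length(rng, lo, hi)
    seq = list(_random_seq(rng, length, gc=config.gc_background))
    record = {"id": tid, "kind": "background", "hairpins": [], "ssrs": [], "targets": []}
    protect: list = []
    if with_ssr:
        sspec = config.ssr_spec
        motif = _random_motif(rng, sspec)
        iterations = _weighted_choice(rng, sspec.iteration_weights)
        tract = motif * iterations
        if len(tract) + 2 * sspec.min_separation >= length:
            iterations = 5
            tract = motif * 5
        if len(tract) + 2 * sspec.min_separation < length:
            start = int(
                rng.integers(
                    sspec.min_separation, length - len(tract) - sspec.min_separation
                )
            )
            _plant_ssr_tract(seq, tract, start, motif)
            protect.append((start, start + len(tract)))
            record["ssrs"].append(
                {
                    "motif": motif,
                    "iterations": int(iterations),
                    "start": start,
                    "end": start + len(tract),
                    "placement": "standalone",
                }
            )
    _scrub_tandem_repeats(seq, rng, protect)
    return Transcript(id=tid, seq="".join(seq)), record


def generate(config: SynthConfig | None = None) -> SyntheticDataset:
    """Generate a synthetic transcriptome with its machine-readable truth."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    transcripts: list[Transcript] = []
    records: list[dict] = []
    mirnas: dict[str, str] = {}

    n_bg = config.n_transcripts - config.n_compliant - config.n_decoys
    bg_with_ssr = round(config.ssr_spec.background_rate * n_bg)

    idx = 0
    for _ in range(config.n_compliant):
        idx += 1
        if config.hairpin_spec.verify:
            window, info = make_compliant_hairpin(
                rng, config.mirna_cfg, config.hairpin_spec
            )
        else:
            # fast path: structural hairpin without fold calibration, for
            # interval-level exercises (positional analysis) where filter
            # compliance is irrelevant
            hs = config.hairpin_spec
            stem = int(rng.integers(hs.stem_len_range[0], hs.stem_len_range[1] + 1))
            loop = int(rng.integers(hs.loop_range[0], hs.loop_range[1] + 1))
            n_mm = int(
                rng.integers(hs.arm_mismatch_range[0], hs.arm_mismatch_range[1] + 1)
            )
            window = _assemble_window(
                rng, stem, loop, n_mm, config.mirna_cfg.window_len
            )
            info = {"kind": "unverified", "stem_len": stem, "arm_mismatches": n_mm}
        t, rec = _build_hairpin_transcript(rng, f"synth{idx:05d}", window, info, config)
        transcripts.append(t)
        records.append(rec)
    for i in range(config.n_decoys):
        idx += 1
        kind = DECOY_KINDS[i % len(DECOY_KINDS)]
        window, info = make_decoy_hairpin(kind, rng, config.mirna_cfg, config.hairpin_spec)
        t, rec = _build_hairpin_transcript(rng, f"synth{idx:05d}", window, info, config)
        transcripts.append(t)
        records.append(rec)
    for i in range(n_bg):
        idx += 1
        t, rec = _build_background_transcript(
            rng, f"synth{idx:05d}", config, with_ssr=i < bg_with_ssr
        )
        transcripts.append(t)
        records.append(rec)

    if config.target_spec is not None:
        tspec = config.target_spec
        for i in range(tspec.n_sites):
            idx += 1
            pattern = tspec.patterns[i % len(tspec.patterns)]
            q, site, info = make_target_site(rng, pattern, tspec, config.target_cfg)
            mid = f"mir{i + 1:03d}"
            mirnas[mid] = q
            flank5 = _random_seq(rng, int(rng.integers(40, 90)))
            flank3 = _random_seq(rng, int(rng.integers(40, 90)))
            seq = flank5 + site + flank3
            tid = f"synth{idx:05d}"
            transcripts.append(Transcript(id=tid, seq=seq))
            records.append(
                {
                    "id": tid,
                    "kind": "target",
                    "hairpins": [],
                    "ssrs": [],
                    "targets": [
                        {
                            "mirna_id": mid,
                            "start": len(flank5),
                            "end": len(flank5) + len(site),
                            "orientation": "plus",
                            **info,
                        }
                    ],
                }
            )

    # read counts: multinomial over lognormal expression x length
    cspec = config.count_spec
    lengths = np.array([len(t) for t in transcripts], dtype=float)
    expr = rng.lognormal(mean=0.0, sigma=cspec.dispersion, size=len(transcripts))
    p = lengths * expr
    p = p / p.sum()
    C = rng.multinomial(cspec.N_total, p)
    counts = pd.DataFrame(
        {"gene_id": [t.id for t in transcripts], "C": C, "L": [len(t) for t in transcripts]}
    )
    for rec, c, t in zip(records, C, transcripts):
        rec["length"] = len(t)
        rec["count"] = int(c)

    truth = {
        "seed": config.seed,
        "config": {
            "n_transcripts": config.n_transcripts,
            "n_compliant": config.n_compliant,
            "n_decoys": config.n_decoys,
            "downstream_fraction": config.ssr_spec.downstream_fraction,
        },
        "transcripts": records,
        "mirnas": mirnas,
    }
    return SyntheticDataset(
        transcripts=transcripts, counts=counts, truth=truth, mirnas=mirnas
    )


# ---------------------------------------------------------------------------
# recovery metrics against planted truth
# ---------------------------------------------------------------------------


def recovery_metrics(ds: SyntheticDataset, cfg: MirnaConfig | None = None) -> dict:
    """Score the scanning pipeline against the planted hairpin truth.

    Sensitivity: fraction of planted compliant windows overlapped by at
    least one accepted window evaluation. Decoy acceptance: fraction of
    planted decoy windows that the filter accepts when evaluated at exactly
    the planted interval (either orientation) -- neighbouring windows mixing
    decoy and background sequence are a different object and do not count
    as accepting the decoy.
    """
    from .mirna_discovery import scan_transcript

    cfg = cfg or MirnaConfig()
    truth = {r["id"]: r for r in ds.truth["transcripts"]}
    n_comp = n_rec = n_dec = n_dec_acc = 0
    for t in ds.transcripts:
        rec = truth[t.id]
        if not rec["hairpins"]:
            continue
        hp = rec["hairpins"][0]
        ws, we = hp["window_start"], hp["window_end"]
        evals = scan_transcript(t, cfg)
        if hp["compliant"]:
            n_comp += 1
            if any(c.accepted and c.window.start < we and ws < c.window.end for c in evals):
                n_rec += 1
        elif hp["kind"].startswith("decoy"):
            n_dec += 1
            exact = [
                c for c in evals if c.window.start == ws and c.window.end == we
            ]
            if any(c.accepted for c in exact):
                n_dec_acc += 1
    return {
        "n_compliant": n_comp,
        "n_recovered": n_rec,
        "sensitivity": n_rec / n_comp if n_comp else float("nan"),
        "n_decoys": n_dec,
        "n_decoys_accepted": n_dec_acc,
        "decoy_acceptance": n_dec_acc / n_dec if n_dec else float("nan"),
    }
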