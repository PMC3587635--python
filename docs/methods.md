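# Methods

`ssrmir` re-implements, as one tested pipeline, the in-silico route from a
plant transcriptome assembly (unigene FASTA) to a catalogue of
microsatellite-bearing pre-miRNA candidates: SSR mining, hairpin folding
and five-criterion candidate screening, antisense target prediction,
SSR-vs-candidate positional statistics, and RPKM expression binning. This
note records the models, the tunable parameters, and the design choices
made where the procedure was genuinely open.

## SSR mining

A simple sequence repeat is a perfect (uninterrupted) tandem repetition of
a primitive 2-5 nt motif with at least five full iterations — the
convention of classic EST-SSR mining scripts ("ag-5" = `agagagagag`).
Detection is a linear scan per motif length that finds maximal
character-level runs of period *k*; partial trailing copies are excluded.
Choices worth noting:

* Mononucleotide runs are out of scope, and a dimer with two equal bases
  ("AA") is rejected as non-primitive, so homopolymers are never reported.
* When a tract admits several motif lengths (`ATATAT…` as AT or ATAT) only
  the shortest-period description is reported, which keeps class summaries
  free of double counting. Hits with *different* motifs may overlap.
* Any tract containing N is skipped.
* Motif classes pair a motif with its reverse complement ("GA/TC",
  rendered lexicographically-smaller-first); rotational phases are not
  merged. Self-reverse-complement motifs (TA) form single-name classes.
* SSR density is reported as hits per Mb of the scanned nucleotides the
  caller supplies; no external density figure is asserted against it.

## RNA folding

`fold_mfe` is a Zuker-style dynamic program over nested secondary
structures with a frozen Turner-style nearest-neighbour parameter set:

* stacking free energies for the 21 Watson-Crick / G:U stack types
  (kcal/mol at 37 °C, constants in `rna_fold.py`);
* hairpin-loop penalties tabulated to size 9 with Jacobson-Stockmayer
  logarithmic extrapolation beyond; bulge and interior-loop size
  penalties likewise;
* the standard Ninio asymmetry penalty for interior loops (slope 0.6,
  cap 3.0 kcal/mol) — without it the model's nearly size-flat interior
  loop cost lets the optimiser merge small defects into large asymmetric
  loops, which is both unphysical and destabilising for tests that plant
  controlled defects;
* a linear multiloop penalty (closure 3.4, branch 0.4, unpaired 0.0);
* minimum hairpin loop 3 nt; lonely pairs permitted; interior loops
  capped at 30 unpaired nt; no dangles, no terminal-AU penalty, no
  special hairpin sequences, no asymmetric-loop stacking bonuses.

The model is deliberately self-contained: its energies are on the usual
kcal/mol scale and qualitatively reproduce the decisions an external
folder would make, but no downstream number is tied to any external
program's exact output — every energy filter is a threshold on this
model's scale. Determinism is guaranteed by a fixed traceback order
(paired state first, then the 5'-most branch). The inner recursion runs
as a numba-compiled kernel (~6 ms per 120-nt window), which makes
transcriptome-wide window scanning practical; `brute_force_mfe`
exhaustively enumerates every valid nested structure for short sequences
and scores them with an independent loop-decomposition scorer over the
same constants, serving as the oracle the DP is tested against.

`duplex_energy` scores a gap-free antisense miRNA:site alignment by
summing stack terms over steps where both facing positions pair (WC or
G:U); steps interrupted by a mismatch contribute nothing and there is no
initiation term, so a fully mismatched alignment scores exactly 0. An
optional per-mismatch penalty exists and defaults to 0.

A caveat that matters for interpreting the screens below: random 120-nt
sequence at 50% GC folds, under this model as under standard ones, to
roughly −0.25 to −0.4 kcal/mol per nt — i.e. inside the −57..−32 window
band — and chained short helices can present locally clean 20-nt arms.
Candidate screening on arbitrary transcripts therefore accepts a
non-trivial share of windows, which mirrors the permissive behaviour of
the published screening recipe (tens of candidates from a few hundred
transcripts) rather than a defect of this implementation.

## Candidate screening

Transcripts are scanned in 120-nt windows (the span every reported
candidate occupies) at a default step of 20 nt, which guarantees any
120-nt hairpin is fully contained in some window; each window is
evaluated in both orientations (the reverse complement is folded for the
minus direction, with results mapped back to plus-strand coordinates).
A window is accepted iff:

1. it folds into a hairpin with a 20-22 nt mature placement entirely in
   one arm;
2. that placement has fewer than six mismatches with the opposite arm —
   an unpaired mature position counts 1, a G:U pair counts 0 (wobbles are
   legitimate pairs in RNA helices; the screening rule names no wobble
   convention, so the package fixes one);
3. the window MFE lies in [−57, −32] kcal/mol;
4. the window A+U content lies in [30, 70]% (the A+U column reported per
   candidate is additionally computed on the mature sequence, which is
   the quantity the published tables actually print — both are emitted);
5. the mature span neither overlaps the hairpin loop nor touches a
   bulge/interior loop larger than `max_defect` = 3 nt ("no large loop or
   break"; the cutoff is configurable since no number is published, and
   3 nt matches common plant miRNA annotation practice).

Among placements the evaluator keeps the fewest-mismatch, 5'-most one;
among overlapping accepted windows on a transcript the lowest-energy one
survives, and multiple disjoint survivors are suffixed a, b, c in report
order. An SSR-bearing mode restricts the scan to transcripts carrying at
least one SSR, optionally minus an exclude-list of annotated ids,
reproducing the funnel transcripts → SSR-bearing → unannotated →
candidates, which every command logs.

## Target prediction

A 20-22 nt miRNA is aligned gap-free and antisense against every
equal-length window of both strands of each transcript; position *k* from
the miRNA 5' end faces site position *len−k*. Scoring: WC 0, G:U wobble
0.5, mismatch 1.0. A hit passes iff total score ≤ 3; the seed (positions
2-6) holds at most one wobble and no other mispair (the stricter
zero-mispair reading is available as `seed_policy="strict"`); positions
10-11 are perfectly Watson-Crick (predicted cleavage site); no more than
two consecutive non-WC positions (wobbles count toward runs); and the
duplex energy is ≤ −30 kcal/mol on the package's stack-table scale.
Alignments are gap-free because the screening rules are stated purely in
terms of mismatch counts.

## Positional analysis

Each (SSR, candidate) pair on a shared transcript receives exactly one
call — upstream, within, or downstream — in the candidate's
transcriptional orientation (minus-direction candidates swap the
plus-strand sides). "Within" means any overlap with the 120-nt window;
overlap is the only boundary rule that keeps the three classes mutually
exclusive and exhaustive. The downstream bias is quantified with a
two-sided exact binomial test of downstream vs upstream counts at null
0.5, within-calls excluded; the test is this package's addition (chosen
for small-count validity), since the original analysis asserted the bias
graphically.

## Expression

RPKM = 10⁹·C/(N·L) with C the reads uniquely aligned to the gene, N the
total uniquely aligned reads (defaulting to the column sum), L the gene
length in bases. Expression tiers: low [0, 100), moderate [100, 1000],
high (1000, 10000], very high above that. The published fine-grained
21-class binning is defined only by examples and is not reconstructed.

## Synthetic data

The generator emulates the statistical shape of a de novo plant leaf
transcriptome at desk scale: transcript lengths drawn from the published
assembly's length mixture (70% in 100-500 nt, tailing off to ~2 kb), 50%
GC background, SSR iteration counts drawn from the published iteration
distribution (61% five iterations, declining to 16), and motif lengths
weighted like the published di/tri/tetra/penta shares. Planted features
carry exact coordinates in a machine-readable truth table, and a single
integer-seeded generator makes every output byte-reproducible.

Key generator choices:

* **Hairpins** are perfect inverted repeats (stem 22-32 bp, loop 6-10 nt)
  degraded by 0-2 arm substitutions, padded to 120 nt, and placed at
  scan-step-aligned offsets so the scanning grid evaluates exactly the
  planted window. Compliant windows are calibrated by adaptive rejection
  sampling against the pipeline's own filter constants with safety
  margins (energy ≥ 4 kcal/mol inside the band, A+U ≥ 5 points inside,
  ≥ 2 mismatches of slack) — planting a "compliant" feature is only
  meaningful relative to the filter that defines compliance.
* **Decoys** violate exactly one named criterion by a safe margin and are
  verified rejected in both scan orientations: `au_low`/`au_high` are
  stable hairpins inside the energy band with A+U ≤ 20% / ≥ 80%;
  `weak_stem` is unstructured sequence above −25 kcal/mol;
  `many_mismatches` carries three broken stem positions per ten (so every
  20-nt mature placement contains at least six mismatches — under this
  energy model a window whose every placement carries eight or more
  mismatches cannot simultaneously stay inside the stability band, so six
  is the strongest violation the physics admits).
* **Target sites** are exact antisense complements with mismatches
  engineered at fixed miRNA positions per pattern (compliant 14/18;
  cleavage 10; seed 4; consecutive 13-15; total-count 8/13/16/19), each
  verified against the target filter at build time.
* **Background scrubbing** mutates any incidental tandem repeat of ≥ 4
  iterations outside planted features, so planted-truth recovery tests
  are exact; flanking bases adjacent to planted tracts are chosen so the
  tract cannot extend.
* **Counts** are multinomial over lognormal expression heterogeneity
  times length (N = 10⁶ by default).

What the generator does **not** emulate: sequencing error, assembly
artefacts, Ns, isoform redundancy, codon structure, real miRNA family
conservation, and realistic hairpin sequence composition beyond the
criteria themselves. Passing the recovery suites therefore demonstrates
that the pipeline's detectors and filters implement their stated rules
faithfully on data matching those rules' assumptions — not that the
biological precision/recall on a real transcriptome would be comparable.

## Recovery metrics

`recovery_metrics` scores the scanner against planted truth. Sensitivity
is overlap-based: a planted compliant window counts as recovered if any
accepted window evaluation overlaps it. Decoy acceptance is exact-window:
a decoy counts as accepted only if the filter accepts the planted 120-nt
interval itself in either orientation. Neighbouring windows that mix
decoy and background sequence are different folding problems — random
background legitimately reaches the energy band (see the folding caveat
above) — so overlap-based decoy counting would measure background
structure rather than the decoy filter.

## Problem sizes and numerics

Default exercise sizes were chosen so each suite completes in minutes on
one core: candidate-filter recovery runs 50 compliant + 50 decoy
transcripts; target truth 25 sites (5 patterns × 5); positional-bias
recovery 200 (SSR, hairpin) pairs with downstream fraction 0.7; the
folding oracle 100 random sequences of 8-20 nt (where exhaustive
enumeration is feasible). Energy comparisons use an absolute tolerance of
1e-6 kcal/mol; traceback tie-breaks are fixed (paired, then 5'-most);
report coordinates are 1-based inclusive while all internal arithmetic is
0-based half-open.

## Known limitations

* The energy model omits dangles, terminal-AU penalties, special loop
  sequences and coaxial stacking; its absolute energies are not
  comparable to any specific published folder, only its decisions are
  qualitatively similar.
* Only perfect SSRs are mined; no compound or mismatch-tolerant repeats.
* Target alignment is gap-free (no target bulges).
* The candidate screen, like the recipe it implements, is permissive on
  structured random sequence; on real data it is meant to be combined
  with the unannotated-transcript and SSR-bearing funnels.
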